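"""Schema-conforming synthetic clinical datasets with planted signal.

The real study data (145 root-canal-treated teeth, 97 fractured / 48 not)
are private, so this module generates stand-ins that conform to the same
17-item schema and reproduce the class composition, with controllable links
between both data types and the label:

* numeric effects — per-item mean shifts between classes, expressed in
  within-class standard-deviation units;
* categorical effects — per-item, per-class option-probability vectors;
* an optional interaction — the label depends on an exclusive-or of two
  designated options (tooth position x post type).  The interaction leaves
  every single-item marginal uninformative, so it is invisible to a model
  that treats the ordinal codes linearly but capturable through the
  embedding and fusion stages.

Base numeric distributions are fixture constants chosen to be clinically
plausible (ages 20-85, wall counts 0-4, thicknesses in mm); they make no
claim of matching the private data's joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np

from .schema import ClinicalRecord, Dataset, ItemSpec, default_schema

#: pinned seed of the frozen "study composition" fixture checked into the package
STUDY_FIXTURE_SEED = 1450

# item_id -> (mean, sd, lo, hi, integer-valued)
_NUMERIC_BASE: dict[int, tuple[float, float, float, float, bool]] = {
    11: (55.0, 12.0, 20.0, 85.0, True),   # age at treatment (years)
    12: (2.5, 1.0, 0.0, 4.0, True),       # remaining tooth walls (count)
    13: (60.0, 40.0, 0.0, 365.0, True),   # days until prosthetic installation
    14: (1.5, 0.8, 0.0, 3.0, True),       # tooth wear score
    15: (1.5, 0.8, 0.0, 3.0, True),       # periodontal score
    16: (1.5, 0.5, 0.3, 3.0, False),      # remaining canal wall thickness (mm)
    17: (2.0, 0.6, 0.5, 4.0, False),      # pericervical dentin thickness (mm)
}

# baseline option probabilities per categorical item (class-independent)
_CATEGORICAL_BASE: dict[int, tuple[float, ...]] = {
    1: (0.45, 0.55),                      # sex
    2: (0.30, 0.70),                      # previous dental fractures
    3: (0.40, 0.60),                      # previous prostheses
    4: (0.35, 0.65),                      # preoperative pain
    5: (0.30, 0.70),                      # percussion pain
    6: (0.25, 0.75),                      # endodontical retreatment
    7: (0.15, 0.20, 0.15, 0.10, 0.25, 0.15),  # tooth position
    8: (0.30, 0.15, 0.20, 0.25, 0.10),    # posts placement
    9: (0.55, 0.20, 0.20, 0.05),          # abutment / fixed prosthesis
    10: (0.80, 0.12, 0.08),               # apicoectomy / root amputation
}


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults reproduce the 97/48 composition."""

    n_positive: int = 97
    n_negative: int = 48
    numeric_effects: dict[int, float] = field(default_factory=dict)
    categorical_effects: dict[int, dict[str, tuple[float, ...]]] = field(default_factory=dict)
    interaction: bool = False
    interaction_items: tuple[int, int] = (7, 8)
    interaction_options: tuple[str, str] = ("Mandibular molars", "Casting post")
    interaction_strength: float = 0.9  # P(XOR satisfied | positive); negatives get 1 - q
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self, schema: list[ItemSpec]) -> None:
        if self.n_positive < 0 or self.n_negative < 0 or self.n_positive + self.n_negative == 0:
            raise ValueError("class sizes must be non-negative and not both zero")
        if not 0.0 <= self.interaction_strength <= 1.0:
            raise ValueError("interaction_strength must lie in [0, 1]")
        by_id = {s.item_id: s for s in schema}
        for item_id, table in self.categorical_effects.items():
            n_opt = len(by_id[item_id].options)
            for cls in ("pos", "neg"):
                probs = np.asarray(table[cls], dtype=float)
                if probs.shape != (n_opt,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                    raise ValueError(
                        f"item {item_id}/{cls}: option probabilities must be a "
                        f"non-negative length-{n_opt} vector summing to 1"
                    )


def _option_probs(spec: SyntheticSpec, item_id: int, label: int) -> np.ndarray:
    if item_id in spec.categorical_effects:
        key = "pos" if label == 1 else "neg"
        return np.asarray(spec.categorical_effects[item_id][key], dtype=float)
    return np.asarray(_CATEGORICAL_BASE[item_id], dtype=float)


def _draw_numeric(spec: SyntheticSpec, item_id: int, label: int, rng: np.random.Generator) -> float:
    mean, sd, lo, hi, is_int = _NUMERIC_BASE[item_id]
    shift = spec.numeric_effects.get(item_id, 0.0) * sd
    value = rng.normal(mean + (shift if label == 1 else 0.0), sd * spec.noise_scale)
    value = float(np.clip(value, lo, hi))
    return float(round(value)) if is_int else round(value, 3)


def generate(spec: SyntheticSpec, schema: Optional[list[ItemSpec]] = None) -> Dataset:
    """Generate ``n_positive + n_negative`` records, reproducible by seed."""
    schema = schema or default_schema()
    spec.validate(schema)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10]))
    labels = np.array([1] * spec.n_positive + [0] * spec.n_negative)
    labels = labels[rng.permutation(len(labels))]

    by_id = {s.item_id: s for s in schema}
    item_a, item_b = spec.interaction_items
    opt_a, opt_b = spec.interaction_options

    records = []
    for y in labels:
        cat: dict[int, str] = {}
        for s in schema:
            if s.kind != "categorical":
                continue
            probs = _option_probs(spec, s.item_id, int(y))
            cat[s.item_id] = s.options[rng.choice(len(s.options), p=probs)]
        if spec.interaction:
            q = spec.interaction_strength if y == 1 else 1.0 - spec.interaction_strength
            want_xor = rng.random() < q
            a_state = bool(rng.integers(2))  # coin: which side of the XOR carries the flag
            if want_xor:
                take_a, take_b = (True, False) if a_state else (False, True)
            else:
                take_a = take_b = a_state
            cat[item_a] = opt_a if take_a else _other_option(by_id[item_a], opt_a, spec, int(y), rng)
            cat[item_b] = opt_b if take_b else _other_option(by_id[item_b], opt_b, spec, int(y), rng)
        num = {
            s.item_id: _draw_numeric(spec, s.item_id, int(y), rng)
            for s in schema
            if s.kind == "numerical"
        }
        records.append(ClinicalRecord(cat, num, int(y)))
    return Dataset(records, schema)


def _other_option(
    item: ItemSpec, excluded: str, spec: SyntheticSpec, label: int, rng: np.random.Generator
) -> str:
    probs = _option_probs(spec, item.item_id, label).copy()
    probs[item.options.index(excluded)] = 0.0
    probs = probs / probs.sum()
    return item.options[rng.choice(len(item.options), p=probs)]


# ---------------------------------------------------------------------------
# Named study conditions

def null_spec(seed: int = 0) -> SyntheticSpec:
    """All planted effects zero: the label is independent of every item."""
    return SyntheticSpec(seed=seed)


def study_spec(seed: int = STUDY_FIXTURE_SEED) -> SyntheticSpec:
    """Moderate mixed-type signal at the study's 97/48 composition.

    Fractured teeth tend to have fewer remaining walls, thinner canal walls
    and thinner pericervical dentin, slightly higher age, and shifted odds
    of retreatment, percussion pain and rigid (casting/screw) posts.
    """
    return SyntheticSpec(
        numeric_effects={11: 0.4, 12: -0.8, 16: -0.9, 17: -0.7},
        categorical_effects={
            5: {"pos": (0.45, 0.55), "neg": (0.20, 0.80)},
            6: {"pos": (0.35, 0.65), "neg": (0.15, 0.85)},
            8: {
                "pos": (0.15, 0.15, 0.30, 0.20, 0.20),
                "neg": (0.45, 0.15, 0.10, 0.25, 0.05),
            },
        },
        seed=seed,
    )


def interaction_spec(seed: int = 0) -> SyntheticSpec:
    """Label driven mainly by a categorical option-pair exclusive-or.

    A weak numeric effect is added so the numerical branch carries some
    signal too; the categorical signal itself is non-linear in ordinal code
    space by construction.
    """
    return SyntheticSpec(
        numeric_effects={16: -0.5},
        interaction=True,
        interaction_strength=0.9,
        seed=seed,
    )


def make_separable_fixture(n: int, seed: int = 0) -> Dataset:
    """Balanced dataset where remaining canal wall thickness (item 16)
    perfectly separates the classes: positives in [0.3, 1.0] mm, negatives
    in [2.0, 3.0] mm.  Used for training sanity checks."""
    if n < 4 or n % 2:
        raise ValueError("n must be an even integer >= 4")
    spec = SyntheticSpec(n_positive=n // 2, n_negative=n // 2, seed=seed)
    ds = generate(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    records = []
    for r in ds.records:
        lo, hi = (0.3, 1.0) if r.label == 1 else (2.0, 3.0)
        num = dict(r.numerical_values)
        num[16] = round(float(rng.uniform(lo, hi)), 3)
        records.append(replace(r, numerical_values=num))
    return Dataset(records, ds.schema)


def load_study_fixture() -> Dataset:
    """The frozen 97/48 study-composition fixture shipped with the package."""
    from .schema import read_dataset

    path = resources.files("tsfnn.data").joinpath("study_fixture.csv")
    with resources.as_file(path) as p:
        return read_dataset(p)
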