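"""Front-end transforms for the two data types.

Numerical items are min-max normalized.  Two modes exist:

* ``standard``: ``y = (x - min) / (max - min)``, mapping the fitted range
  onto [0, 1]; out-of-range values at apply time are clamped.
* ``paper_literal``: ``y = x / (max - min)``, the formula as printed in the
  source method description.  It equals the standard form plus the constant
  ``min / (max - min)`` and only lands in [0, 1] when ``min == 0``; it is
  kept for bit-exact reproduction.

Degenerate items (``max == min``, e.g. a constant column inside a training
fold) map to 0 instead of raising, so leave-one-out never aborts.

Categorical items are globally ordinal-encoded: codes are assigned
sequentially starting at 1, walking items in schema order and options in
printed order, so the ten default items' thirty options span exactly 1..30.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .schema import ClinicalRecord, Dataset, ItemSpec, categorical_items, numerical_items


class PreprocessError(ValueError):
    pass


@dataclass
class NormalizationParams:
    """Per-item fitted min/max and the normalization mode."""

    min_value: dict[int, float]
    max_value: dict[int, float]
    mode: str = "standard"  # "standard" | "paper_literal"

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "paper_literal"):
            raise PreprocessError(f"unknown normalization mode {self.mode!r}")
        for item_id in self.min_value:
            if self.max_value[item_id] < self.min_value[item_id]:
                raise PreprocessError(f"item {item_id}: max < min")

    @property
    def item_ids(self) -> list[int]:
        return sorted(self.min_value)

    def degenerate_items(self) -> list[int]:
        return [i for i in self.item_ids if self.max_value[i] == self.min_value[i]]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mode": self.mode,
                    "min_value": {str(k): v for k, v in self.min_value.items()},
                    "max_value": {str(k): v for k, v in self.max_value.items()},
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            min_value={int(k): float(v) for k, v in payload["min_value"].items()},
            max_value={int(k): float(v) for k, v in payload["max_value"].items()},
            mode=payload["mode"],
        )


def fit_minmax(
    dataset: Dataset,
    item_ids: Sequence[int] | None = None,
    mode: str = "standard",
) -> NormalizationParams:
    """Fit per-item min and max over the supplied records only.

    Fitting on a training fold therefore never sees the held-out record.
    """
    if len(dataset) == 0:
        raise PreprocessError("cannot fit normalization on an empty dataset")
    if item_ids is None:
        item_ids = [s.item_id for s in numerical_items(dataset.schema)]
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    for item_id in item_ids:
        values = [r.numerical_values[item_id] for r in dataset.records]
        lo[item_id] = float(min(values))
        hi[item_id] = float(max(values))
    return NormalizationParams(lo, hi, mode)


def apply_minmax(value: float, item_id: int, params: NormalizationParams) -> float:
    """Normalize one value with the fitted parameters for ``item_id``."""
    if item_id not in params.min_value:
        raise PreprocessError(f"item {item_id} was not fitted")
    lo = params.min_value[item_id]
    hi = params.max_value[item_id]
    span = hi - lo
    if span == 0.0:
        return 0.0
    if params.mode == "paper_literal":
        return value / span
    return float(np.clip((value - lo) / span, 0.0, 1.0))


def normalize_numeric(dataset: Dataset, params: NormalizationParams) -> np.ndarray:
    """Matrix of normalized numerical items, one row per record."""
    return np.array(
        [
            [apply_minmax(r.numerical_values[i], i, params) for i in params.item_ids]
            for r in dataset.records
        ],
        dtype=float,
    )


@dataclass
class OrdinalCodebook:
    """Bijection from (item_id, option label) to global integer codes.

    Codes start at 1 and run contiguously across all categorical items, so
    two different items never share a code; with the default schema the
    range is exactly 1..30.
    """

    codes: dict[tuple[int, str], int]
    item_ids: list[int] = field(default_factory=list)

    @property
    def max_code(self) -> int:
        return max(self.codes.values())

    @property
    def min_code(self) -> int:
        return min(self.codes.values())

    def code(self, item_id: int, option: str) -> int:
        try:
            return self.codes[(item_id, option)]
        except KeyError:
            raise PreprocessError(
                f"unknown option {option!r} for item {item_id}"
            ) from None

    def save(self, path: str | Path) -> None:
        entries = [
            {"item_id": item_id, "option": option, "code": code}
            for (item_id, option), code in sorted(self.codes.items(), key=lambda kv: kv[1])
        ]
        Path(path).write_text(json.dumps({"codes": entries, "item_ids": self.item_ids}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "OrdinalCodebook":
        payload = json.loads(Path(path).read_text())
        codes = {(int(e["item_id"]), e["option"]): int(e["code"]) for e in payload["codes"]}
        return cls(codes, [int(i) for i in payload["item_ids"]])


def build_codebook(schema: Sequence[ItemSpec]) -> OrdinalCodebook:
    """Assign sequential global codes from the schema, deterministically."""
    codes: dict[tuple[int, str], int] = {}
    next_code = 1
    item_ids = []
    for spec in categorical_items(schema):
        item_ids.append(spec.item_id)
        for option in spec.options:
            codes[(spec.item_id, option)] = next_code
            next_code += 1
    if not codes:
        raise PreprocessError("schema has no categorical items")
    return OrdinalCodebook(codes, item_ids)


def encode_categorical(record: ClinicalRecord, codebook: OrdinalCodebook) -> np.ndarray:
    """Encode a record's categorical items as the vector of global codes."""
    return np.array(
        [codebook.code(i, record.categorical_values[i]) for i in codebook.item_ids],
        dtype=int,
    )


def encode_dataset(dataset: Dataset, codebook: OrdinalCodebook) -> np.ndarray:
    return np.array([encode_categorical(r, codebook) for r in dataset.records], dtype=int)
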