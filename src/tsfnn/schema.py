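"""Clinical item schema and CSV dataset I/O.

The default schema describes one root-canal-treated tooth by 17 items:
items 1-10 are categorical (dental history and status options with no
measurable ordering, e.g. sex, tooth position, post type) and items 11-17
are numerical (measurable quantities such as age at treatment or remaining
root canal wall thickness).  The binary outcome is whether the tooth later
developed a vertical root fracture (1 = fractured, the positive case).

Records are exchanged as plain CSV: one header row naming the 17 items,
one row per tooth, label column ``fractured`` last.  Missing values are a
hard error; categorical values must be members of the item's option list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

LABEL_COLUMN = "fractured"


class SchemaError(ValueError):
    """A table or config does not match the expected item schema."""


class ValidationError(ValueError):
    """A record violates the schema (unknown option, missing item, ...)."""


@dataclass(frozen=True)
class ItemSpec:
    """One clinical item: id, name, kind and (for categorical) its options."""

    item_id: int
    name: str
    kind: str  # "categorical" | "numerical"
    options: tuple[str, ...] = ()
    numeric_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numerical"):
            raise SchemaError(f"item {self.item_id}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.options:
                raise SchemaError(f"item {self.item_id}: categorical item needs options")
            if len(set(self.options)) != len(self.options):
                raise SchemaError(f"item {self.item_id}: duplicate option labels")
        elif self.options:
            raise SchemaError(f"item {self.item_id}: numerical item cannot have options")


def default_schema() -> list[ItemSpec]:
    """The 17-item schema, option labels verbatim, in table order.

    Ten categorical items (30 options in total) followed by seven numerical
    items.  Advisory numeric ranges are attached for validation warnings.
    """
    yn = ("Yes", "No")
    return [
        ItemSpec(1, "sex", "categorical", ("Male", "Female")),
        ItemSpec(2, "previous dental fractures", "categorical", yn),
        ItemSpec(3, "previous prostheses", "categorical", yn),
        ItemSpec(4, "preoperative pain", "categorical", yn),
        ItemSpec(5, "percussion pain", "categorical", yn),
        ItemSpec(6, "endodontical retreatment", "categorical", yn),
        ItemSpec(
            7,
            "tooth position",
            "categorical",
            (
                "Maxillary anterior teeth",
                "maxillary molars",
                "maxillary premolar",
                "Mandibular front teeth",
                "Mandibular molars",
                "Mandibular premolar",
            ),
        ),
        ItemSpec(
            8,
            "posts placement",
            "categorical",
            ("None", "Para post", "Casting post", "Fiber post", "Screw post"),
        ),
        ItemSpec(
            9,
            "abutment of removable dentures or fixed partial dental prostheses",
            "categorical",
            (
                "None",
                "Fixed partial dental prostheses",
                "Abutment of removable dentures",
                "Both of them",
            ),
        ),
        ItemSpec(
            10,
            "previous sapicoectomy or root amputation",
            "categorical",
            ("None", "Previous sapicoectomy", "Root amputation"),
        ),
        ItemSpec(11, "the age at the time of treatment", "numerical", numeric_range=(10.0, 100.0)),
        ItemSpec(12, "quantity of remaining tooth walls", "numerical", numeric_range=(0.0, 4.0)),
        ItemSpec(
            13,
            "duration from completion of root canal treatment until the date of prosthetic installation",
            "numerical",
            numeric_range=(0.0, 2000.0),
        ),
        ItemSpec(14, "tooth wear condition", "numerical", numeric_range=(0.0, 3.0)),
        ItemSpec(15, "periodontal condition", "numerical", numeric_range=(0.0, 3.0)),
        ItemSpec(16, "remaining root canal wall thickness", "numerical", numeric_range=(0.0, 5.0)),
        ItemSpec(17, "pericervical dentin thickness", "numerical", numeric_range=(0.0, 6.0)),
    ]


def categorical_items(schema: Sequence[ItemSpec]) -> list[ItemSpec]:
    return [s for s in schema if s.kind == "categorical"]


def numerical_items(schema: Sequence[ItemSpec]) -> list[ItemSpec]:
    return [s for s in schema if s.kind == "numerical"]


@dataclass(frozen=True)
class ClinicalRecord:
    """One tooth: categorical option choices, numeric measurements, outcome."""

    categorical_values: dict[int, str]
    numerical_values: dict[int, float]
    label: int

    def validate(self, schema: Sequence[ItemSpec], *, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}{where}")
        for spec in schema:
            if spec.kind == "categorical":
                if spec.item_id not in self.categorical_values:
                    raise ValidationError(f"missing item {spec.item_id} ({spec.name!r}){where}")
                value = self.categorical_values[spec.item_id]
                if value not in spec.options:
                    raise ValidationError(
                        f"item {spec.item_id} ({spec.name!r}): value {value!r} "
                        f"is not one of {list(spec.options)}{where}"
                    )
            else:
                if spec.item_id not in self.numerical_values:
                    raise ValidationError(f"missing item {spec.item_id} ({spec.name!r}){where}")
                value = self.numerical_values[spec.item_id]
                if value != value:  # NaN
                    raise ValidationError(f"item {spec.item_id} ({spec.name!r}): missing value{where}")
                if spec.numeric_range is not None:
                    lo, hi = spec.numeric_range
                    if not (lo <= value <= hi):
                        warnings.warn(
                            f"item {spec.item_id} ({spec.name!r}): value {value} outside "
                            f"advisory range [{lo}, {hi}]{where}",
                            stacklevel=2,
                        )


@dataclass
class Dataset:
    """An ordered list of validated records plus the schema they obey.

    Record order is stable and meaningful: leave-one-out fold indices refer
    to positions in this list.
    """

    records: list[ClinicalRecord]
    schema: list[ItemSpec] = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        for i, record in enumerate(self.records):
            record.validate(self.schema, row=i)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> ClinicalRecord:
        return self.records[i]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int]) -> "Dataset":
        ds = Dataset.__new__(Dataset)
        ds.records = [self.records[i] for i in indices]
        ds.schema = self.schema
        return ds

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {}
        for spec in self.schema:
            if spec.kind == "categorical":
                cols[spec.name] = [r.categorical_values[spec.item_id] for r in self.records]
            else:
                cols[spec.name] = [r.numerical_values[spec.item_id] for r in self.records]
        cols[LABEL_COLUMN] = [r.label for r in self.records]
        return pd.DataFrame(cols)


def read_dataset(path: str | Path, schema: Sequence[ItemSpec] | None = None) -> Dataset:
    """Read a record table from CSV, validating every row against the schema.

    Raises :class:`SchemaError` for unknown/missing columns and
    :class:`ValidationError` for out-of-vocabulary categorical values;
    non-numeric text in a numerical column is a parse error naming the item.
    """
    schema = list(schema) if schema is not None else default_schema()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = [s.name for s in schema] + [LABEL_COLUMN]
    unknown = [c for c in frame.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown column(s) {unknown}; expected {expected}")
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}")

    records = []
    for row_idx, row in frame.iterrows():
        cat: dict[int, str] = {}
        num: dict[int, float] = {}
        for spec in schema:
            raw = row[spec.name]
            if spec.kind == "categorical":
                cat[spec.item_id] = raw
            else:
                if raw == "":
                    raise ValidationError(
                        f"item {spec.item_id} ({spec.name!r}): empty value (row {row_idx})"
                    )
                try:
                    num[spec.item_id] = float(raw)
                except ValueError:
                    raise ValidationError(
                        f"item {spec.item_id} ({spec.name!r}): non-numeric value "
                        f"{raw!r} (row {row_idx})"
                    ) from None
        try:
            label = int(row[LABEL_COLUMN])
        except ValueError:
            raise ValidationError(
                f"label column: non-integer value {row[LABEL_COLUMN]!r} (row {row_idx})"
            ) from None
        records.append(ClinicalRecord(cat, num, label))
    return Dataset(records, schema)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset as CSV (header row, label column last), losslessly.

    Numeric values are rendered with ``repr`` so a read-back reproduces the
    floats bit-for-bit.
    """
    frame = dataset.to_frame()
    for spec in numerical_items(dataset.schema):
        frame[spec.name] = [repr(float(v)) for v in frame[spec.name]]
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Schema config files: a plain YAML mapping so alternative schemas can be
# supplied to the same pipeline.

def save_schema(schema: Sequence[ItemSpec], path: str | Path) -> None:
    payload = [
        {
            "item_id": s.item_id,
            "name": s.name,
            "kind": s.kind,
            **({"options": list(s.options)} if s.kind == "categorical" else {}),
            **({"numeric_range": list(s.numeric_range)} if s.numeric_range else {}),
        }
        for s in schema
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False, allow_unicode=True))


def load_schema(path: str | Path) -> list[ItemSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, list):
        raise SchemaError("schema config must be a list of item mappings")
    schema = []
    for entry in payload:
        schema.append(
            ItemSpec(
                item_id=int(entry["item_id"]),
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                options=tuple(entry.get("options", ())),
                numeric_range=tuple(entry["numeric_range"]) if "numeric_range" in entry else None,
            )
        )
    return schema
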