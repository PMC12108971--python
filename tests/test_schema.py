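"""Schema definition, record validation and CSV round-tripping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsfnn import (
    ClinicalRecord,
    Dataset,
    SchemaError,
    ValidationError,
    default_schema,
    load_schema,
    read_dataset,
    save_schema,
    write_dataset,
)
from tsfnn.schema import ItemSpec, categorical_items, numerical_items


class TestDefaultSchema:
    def test_seventeen_items_in_table_order(self, schema):
        assert len(schema) == 17
        assert [s.item_id for s in schema] == list(range(1, 18))
        assert all(s.kind == "categorical" for s in schema[:10])
        assert all(s.kind == "numerical" for s in schema[10:])

    def test_item_1_is_sex_with_two_options(self, schema):
        assert schema[0].name == "sex"
        assert schema[0].options == ("Male", "Female")

    def test_tooth_position_has_six_options(self, schema):
        item7 = schema[6]
        assert item7.name == "tooth position"
        assert len(item7.options) == 6

    def test_option_counts_per_item(self, schema):
        # six binary items, then 6/5/4/3-option items: 30 options in total
        counts = [len(s.options) for s in categorical_items(schema)]
        assert counts == [2, 2, 2, 2, 2, 2, 6, 5, 4, 3]
        assert sum(counts) == 30

    def test_exactly_seven_numerical_items(self, schema):
        assert len(numerical_items(schema)) == 7

    def test_malformed_item_specs_rejected(self):
        with pytest.raises(SchemaError):
            ItemSpec(1, "x", "categorical", ())  # no options
        with pytest.raises(SchemaError):
            ItemSpec(1, "x", "categorical", ("A", "A"))  # duplicates
        with pytest.raises(SchemaError):
            ItemSpec(1, "x", "numerical", ("A",))  # options on numerical


def _record(schema, label=1, overrides=None):
    cat = {s.item_id: s.options[0] for s in categorical_items(schema)}
    num = {s.item_id: (s.numeric_range[0] + s.numeric_range[1]) / 2 for s in numerical_items(schema)}
    for item_id, value in (overrides or {}).items():
        (cat if item_id <= 10 else num)[item_id] = value
    return ClinicalRecord(cat, num, label)


class TestValidation:
    def test_unlisted_option_rejected(self, schema):
        with pytest.raises(ValidationError, match="item 1"):
            Dataset([_record(schema, overrides={1: "Unknown"})], schema)

    def test_missing_item_rejected(self, schema):
        record = _record(schema)
        broken = ClinicalRecord(
            {k: v for k, v in record.categorical_values.items() if k != 5},
            record.numerical_values,
            1,
        )
        with pytest.raises(ValidationError, match="item 5"):
            Dataset([broken], schema)

    def test_nan_numeric_rejected(self, schema):
        with pytest.raises(ValidationError, match="item 16"):
            Dataset([_record(schema, overrides={16: float("nan")})], schema)

    def test_out_of_range_numeric_warns_but_passes(self, schema):
        with pytest.warns(UserWarning, match="advisory range"):
            ds = Dataset([_record(schema, overrides={11: 300.0})], schema)
        assert len(ds) == 1

    def test_bad_label_rejected(self, schema):
        record = _record(schema)
        with pytest.raises(ValidationError, match="label"):
            Dataset([ClinicalRecord(record.categorical_values, record.numerical_values, 2)], schema)


class TestCsvIO:
    def test_two_row_round_trip(self, schema, tmp_path):
        ds = Dataset([_record(schema, label=1), _record(schema, label=0, overrides={1: "Female"})], schema)
        path = tmp_path / "two.csv"
        write_dataset(ds, path)
        back = read_dataset(path, schema)
        assert len(back) == 2
        assert back.to_frame().equals(ds.to_frame())

    def test_empty_dataset_writes_header_only(self, schema, tmp_path):
        path = tmp_path / "empty.csv"
        write_dataset(Dataset([], schema), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].endswith("fractured")

    def test_study_fixture_is_header_plus_145_rows(self, study_fixture, tmp_path):
        path = tmp_path / "study.csv"
        write_dataset(study_fixture, path)
        assert len(path.read_text().strip().splitlines()) == 146

    def test_unknown_column_is_schema_error(self, schema, tmp_path):
        path = tmp_path / "bad.csv"
        write_dataset(Dataset([_record(schema)], schema), path)
        text = path.read_text().replace("sex", "gender")
        path.write_text(text)
        with pytest.raises(SchemaError, match="gender"):
            read_dataset(path, schema)

    def test_out_of_vocabulary_value_names_row_item_value(self, schema, tmp_path):
        path = tmp_path / "oov.csv"
        write_dataset(Dataset([_record(schema)], schema), path)
        path.write_text(path.read_text().replace("Male", "Unknown"))
        with pytest.raises(ValidationError, match="'Unknown'"):
            read_dataset(path, schema)

    def test_non_numeric_text_is_parse_error(self, schema, tmp_path):
        path = tmp_path / "text.csv"
        write_dataset(Dataset([_record(schema, overrides={11: 50.0})], schema), path)
        path.write_text(path.read_text().replace("50.0", "fifty"))
        with pytest.raises(ValidationError, match="non-numeric"):
            read_dataset(path, schema)

    def test_label_counts_preserved(self, study_fixture, tmp_path):
        path = tmp_path / "labels.csv"
        write_dataset(study_fixture, path)
        back = read_dataset(path)
        assert sum(back.labels) == sum(study_fixture.labels) == 97


@st.composite
def valid_datasets(draw):
    schema = default_schema()
    n = draw(st.integers(min_value=1, max_value=8))
    records = []
    for _ in range(n):
        cat = {
            s.item_id: draw(st.sampled_from(list(s.options)))
            for s in categorical_items(schema)
        }
        num = {
            s.item_id: float(
                draw(
                    st.floats(
                        min_value=s.numeric_range[0],
                        max_value=s.numeric_range[1],
                        allow_nan=False,
                        width=32,
                    )
                )
            )
            for s in numerical_items(schema)
        }
        records.append(ClinicalRecord(cat, num, draw(st.integers(0, 1))))
    return Dataset(records, schema)


@settings(max_examples=25, deadline=None)
@given(ds=valid_datasets())
def test_round_trip_identity_property(ds, tmp_path_factory):
    """read(write(D)) reproduces every value and label of any valid dataset."""
    path = tmp_path_factory.mktemp("rt") / "ds.csv"
    write_dataset(ds, path)
    back = read_dataset(path)
    assert len(back) == len(ds)
    for a, b in zip(back.records, ds.records):
        assert a.categorical_values == b.categorical_values
        assert a.label == b.label
        for item_id, value in b.numerical_values.items():
            assert a.numerical_values[item_id] == value  # bit-exact via repr round-trip


def test_schema_config_round_trip(schema, tmp_path):
    path = tmp_path / "schema.yaml"
    save_schema(schema, path)
    assert load_schema(path) == schema
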