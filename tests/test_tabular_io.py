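import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tiestar import (
    Dataset,
    FeatureSchema,
    discretize,
    impute_missing,
    read_dataset,
    write_dataset,
)
from conftest import make_dataset


def _write_csv(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


SCHEMA_YAML = """\
x1: {kind: continuous}
x2: {kind: ordinal, levels: [0, 1, 2]}
x3: {kind: binary, levels: [0, 1]}
"""


class TestReadDataset:
    def test_round_trip_preserves_values_kinds_outcome(self, tmp_path):
        ds = make_dataset(
            {"x1": [0.5, 1.5, 2.5, 3.5, 4.5], "x2": [0, 1, 2, 1, 0], "x3": [0, 1, 0, 1, 1]},
            [0, 1, 0, 1, 0],
            kinds={"x1": "continuous", "x3": "binary"},
        )
        write_dataset(ds, tmp_path / "d.csv", tmp_path / "s.yaml")
        back = read_dataset(tmp_path / "d.csv", tmp_path / "s.yaml", "outcome")
        pd.testing.assert_frame_equal(back.features, ds.features)
        assert [s.kind for s in back.schema] == [s.kind for s in ds.schema]
        np.testing.assert_array_equal(back.outcome, ds.outcome)

    def test_rows_with_missing_outcome_dropped_and_logged(self, tmp_path, caplog):
        csv = _write_csv(
            tmp_path,
            "x1,x2,x3,outcome\n1.0,0,0,1\n2.0,1,1,\n3.0,2,0,0\n4.0,1,1,0\n5.0,0,0,1\n",
        )
        schema = _write_csv(tmp_path, SCHEMA_YAML, "s.yaml")
        with caplog.at_level(logging.INFO, logger="tiestar"):
            ds = read_dataset(csv, schema, "outcome")
        assert ds.n == 4
        assert "dropped 1 rows" in caplog.text

    def test_nonbinary_outcome_rejected(self, tmp_path):
        csv = _write_csv(
            tmp_path, "x1,x2,x3,outcome\n1.0,0,0,0\n2.0,1,1,1\n3.0,2,0,2\n"
        )
        schema = _write_csv(tmp_path, SCHEMA_YAML, "s.yaml")
        with pytest.raises(ValueError, match="binary"):
            read_dataset(csv, schema, "outcome")

    def test_unknown_schema_column_rejected(self, tmp_path):
        csv = _write_csv(tmp_path, "x1,outcome\n1.0,0\n2.0,1\n")
        schema = _write_csv(tmp_path, SCHEMA_YAML, "s.yaml")
        with pytest.raises(ValueError, match="missing from data"):
            read_dataset(csv, schema, "outcome")

    def test_empty_file_rejected(self, tmp_path):
        csv = _write_csv(tmp_path, "x1,x2,x3,outcome\n")
        schema = _write_csv(tmp_path, SCHEMA_YAML, "s.yaml")
        with pytest.raises(ValueError, match="empty"):
            read_dataset(csv, schema, "outcome")


class TestDiscretize:
    def test_equal_frequency_thirds(self):
        ds = make_dataset(
            {"c": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, [0, 1, 0, 1, 0, 1], kinds={"c": "continuous"}
        )
        out = discretize(ds, bins=3)
        np.testing.assert_array_equal(out.features["c"].to_numpy(), [0, 0, 1, 1, 2, 2])
        assert out.schema_of("c").kind == "ordinal"

    def test_binary_column_untouched(self):
        ds = make_dataset({"b": [0, 1, 1, 0, 1, 0]}, [0, 1, 0, 1, 0, 1], kinds={"b": "binary"})
        out = discretize(ds, bins=3)
        np.testing.assert_array_equal(out.features["b"], ds.features["b"])
        assert out.schema_of("b").kind == "binary"

    def test_constant_column_collapses_with_warning(self):
        ds = make_dataset(
            {"c": [2.0] * 6, "d": [1, 2, 3, 4, 5, 6]},
            [0, 1, 0, 1, 0, 1],
            kinds={"c": "continuous", "d": "continuous"},
        )
        with pytest.warns(UserWarning, match="distinct"):
            out = discretize(ds, bins=3)
        assert out.features["c"].nunique() == 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=6, max_size=40
        )
    )
    def test_monotone_and_permutation_equivariant(self, values):
        import warnings

        values = np.asarray(values)
        ds = make_dataset({"c": values}, [0, 1] * (len(values) // 2) + [0] * (len(values) % 2),
                          kinds={"c": "continuous"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # collapse warnings are fine here
            codes = discretize(ds, bins=3).features["c"].to_numpy()
            perm = np.random.default_rng(0).permutation(len(values))
            permuted = discretize(
                make_dataset({"c": values[perm]}, np.zeros(len(values)),
                             kinds={"c": "continuous"}),
                bins=3,
            ).features["c"].to_numpy()
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(codes[order]) >= 0)  # larger value, same-or-larger level
        np.testing.assert_array_equal(permuted, codes[perm])

    def test_bins_below_two_rejected(self):
        ds = make_dataset({"c": [1.0, 2.0, 3.0]}, [0, 1, 0], kinds={"c": "continuous"})
        with pytest.raises(ValueError):
            discretize(ds, bins=1)


class TestImpute:
    def test_median_for_continuous_mode_for_discrete(self):
        ds = make_dataset(
            {
                "c": [1.0, np.nan, 3.0, 5.0],
                "o": [0, 2, 2, np.nan],
            },
            [0, 1, 0, 1],
            kinds={"c": "continuous"},
        )
        out = impute_missing(ds)
        assert out.features["c"].iloc[1] == 3.0
        assert out.features["o"].iloc[3] == 2.0
        assert not out.features.isna().any().any()

    def test_mode_ties_break_to_smaller_value(self):
        ds = make_dataset({"o": [0, 0, 1, 1, np.nan, 2]}, [0, 1, 0, 1, 0, 1])
        out = impute_missing(ds)
        assert out.features["o"].iloc[4] == 0.0


class TestValidation:
    def test_duplicate_names_rejected(self):
        schema = [FeatureSchema("a", "ordinal", (0, 1, 2))] * 2
        with pytest.raises(ValueError, match="duplicate"):
            Dataset(pd.DataFrame({"a": [0, 1]}), schema, np.array([0, 1]))

    def test_binary_schema_needs_two_levels(self):
        with pytest.raises(ValueError, match="2 levels"):
            FeatureSchema("b", "binary", (0, 1, 2))

    def test_outcome_must_be_01(self):
        schema = [FeatureSchema("a", "ordinal", (0, 1))]
        with pytest.raises(ValueError, match="0/1"):
            Dataset(pd.DataFrame({"a": [0, 1, 0]}), schema, np.array([0, 1, 2]))
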