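"""Preparation recipe: collapsing, encoding, variance filtering, standardizing."""

import numpy as np
import pandas as pd
import pytest

from sparserank import (
    Recipe,
    RecipeConfig,
    collapse_rare_levels,
    encode_categoricals,
    standardize,
    variance_filter,
)


class TestCollapseRareLevels:
    @pytest.mark.parametrize(
        "counts, expected_levels",
        [
            ({"A": 50, "B": 30, "C": 12, "D": 5, "E": 3}, {"A", "B", "C", "other"}),
            ({"A": 60, "B": 40}, {"A", "B"}),
            ({"A": 92, "B": 5, "C": 3}, {"A", "other"}),
        ],
    )
    def test_ten_percent_rule(self, counts, expected_levels):
        col = pd.Series([lvl for lvl, c in counts.items() for _ in range(c)])
        mapped, mm = collapse_rare_levels(col, 0.10)
        assert set(mapped.unique()) == expected_levels

    def test_other_collision_uses_other_merged(self):
        col = pd.Series(["other"] * 80 + ["B"] * 15 + ["C"] * 5)
        mapped, mm = collapse_rare_levels(col, 0.10)
        assert mm == {"C": "other_merged"}
        assert set(mapped.unique()) == {"other", "B", "other_merged"}


class TestEncodeCategoricals:
    def test_reference_is_most_frequent(self):
        df = pd.DataFrame({"g": ["A"] * 5 + ["B"] * 3 + ["C"] * 2})
        enc, covs, spec = encode_categoricals(df)
        assert spec["g"].reference == "A"
        assert list(enc.columns) == ["g=B", "g=C"]
        assert all(c.source == "g" for c in covs)

    def test_binary_categorical_one_dummy(self):
        df = pd.DataFrame({"g": ["y"] * 6 + ["n"] * 4})
        enc, _, _ = encode_categoricals(df)
        assert enc.shape[1] == 1

    def test_single_level_dropped_with_warning(self):
        df = pd.DataFrame({"g": ["only"] * 5})
        with pytest.warns(UserWarning, match="single level"):
            enc, covs, _ = encode_categoricals(df)
        assert enc.shape[1] == 0 and covs == []


class TestVarianceFilter:
    def test_constant_dropped_under_both_modes(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        for mode in ("zv", "nzv"):
            kept, dropped = variance_filter(X, ["c", "x"], mode)
            assert "c" in dropped and kept == ["x"]

    def test_96_4_binary_split(self):
        # freq ratio 24 > 19 and 2% unique < 10%: nzv drops, zv keeps
        v = np.array([0.0] * 96 + [1.0] * 4)
        kept_nzv, _ = variance_filter(v[:, None], ["b"], "nzv")
        kept_zv, _ = variance_filter(v[:, None], ["b"], "zv")
        assert kept_nzv == [] and kept_zv == ["b"]

    def test_none_mode_keeps_everything(self):
        X = np.column_stack([np.ones(20), np.zeros(20)])
        kept, dropped = variance_filter(X, ["a", "b"], "none")
        assert kept == ["a", "b"] and dropped == {}

    def test_zv_drops_subset_of_nzv_drops(self, rng):
        X = np.column_stack(
            [
                rng.standard_normal(200),
                (rng.random(200) < 0.02).astype(float),
                np.full(200, 3.0),
                rng.integers(0, 2, 200).astype(float),
            ]
        )
        ids = list("abcd")
        _, d_zv = variance_filter(X, ids, "zv")
        _, d_nzv = variance_filter(X, ids, "nzv")
        assert set(d_zv) <= set(d_nzv)


class TestStandardize:
    def test_mean_zero_unit_scale_and_roundtrip(self, rng):
        X = rng.normal(5, 3, size=(80, 4))
        Xs, (m, s), _ = standardize(X)
        np.testing.assert_allclose(Xs.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(0), 1, atol=1e-12)
        np.testing.assert_allclose(Xs * s + m, X, atol=1e-12)

    def test_constant_column_flagged(self):
        X = np.column_stack([np.full(10, 2.0), np.arange(10.0)])
        Xs, _, zero = standardize(X)
        assert zero[0] and not zero[1]
        np.testing.assert_allclose(Xs[:, 0], 0.0)


class TestRecipe:
    def test_transform_on_training_data_reproduces_design(self, tiny_frame):
        rec = Recipe(k=1, poly=2).fit(tiny_frame)
        X1, ids1 = rec.transform(tiny_frame)
        X2, ids2 = rec.transform(tiny_frame)
        assert ids1 == ids2
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_allclose(X1.mean(0), 0, atol=1e-10)

    def test_no_test_set_leakage(self, tiny_frame):
        """Perturbing held-out rows never changes the fitted statistics."""
        train = tiny_frame.iloc[:90]
        test = tiny_frame.iloc[90:].copy()
        rec = Recipe(k=1, poly=2).fit(train)
        X_before, _ = rec.transform(train)
        test["age"] = test["age"] * 100  # wild test values
        rec.transform(test)  # must not mutate the recipe
        X_after, _ = rec.transform(train)
        np.testing.assert_array_equal(X_before, X_after)

    def test_missing_values_hard_error(self, tiny_frame):
        bad = tiny_frame.copy()
        bad.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            Recipe().fit(bad)

    def test_missing_column_error_names_it(self, tiny_frame):
        rec = Recipe().fit(tiny_frame)
        with pytest.raises(ValueError, match="age"):
            rec.transform(tiny_frame.drop(columns=["age"]))

    def test_rare_level_collapsed_before_encoding(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "g": rng.choice(["A", "B", "C"], 200, p=[0.6, 0.35, 0.05]),
                "x": rng.standard_normal(200),
            }
        )
        rec = Recipe(k=0, poly=1).fit(df)
        assert "g=other" in rec.parent_columns_ or "g=C" not in rec.parent_columns_

    def test_filter_runs_on_expanded_terms(self):
        """A near-constant interaction of two healthy dummies is removed."""
        n = 400
        a = np.zeros(n)
        b = np.zeros(n)
        a[:60] = 1.0  # 15% ones each, 8 co-occurrences (2%)
        b[52:112] = 1.0
        df = pd.DataFrame({"a": a, "b": b})
        cfg = RecipeConfig(filter_mode="nzv")
        rec = Recipe(config=cfg, k=1, poly=2).fit(df)
        assert "a" in rec.term_ids_ and "b" in rec.term_ids_
        assert "a:b" in rec.dropped_
        rec_zv = Recipe(config=RecipeConfig(filter_mode="zv"), k=1, poly=2).fit(df)
        assert "a:b" in rec_zv.term_ids_
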