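"""Benchmark harness: dataset filters, shared splits, summaries, meta-model."""

import gzip

import numpy as np
import pandas as pd
import pytest

from sparserank import (
    DatasetMeta,
    filter_datasets,
    meta_analyze,
    read_pmlb,
    run_bakeoff,
    simulate,
    within_pct_of_best,
)


class TestFilterDatasets:
    @pytest.mark.parametrize(
        "meta, kept",
        [
            (DatasetMeta("a", "binary", 12_000, 10), False),  # too many rows
            (DatasetMeta("b", "continuous", 500, 60), False),  # too many features
            (DatasetMeta("c", "binary", 5000, 30), False),  # 150k cells
            (DatasetMeta("d", "categorical", 100, 5), False),  # endpoint type
            (DatasetMeta("fri_c0_100_5", "continuous", 100, 5), False),  # Friedman
            (DatasetMeta("e", "binary", 500, 10), True),
            (DatasetMeta("f", "continuous", 9000, 11, friedman=False), True),
        ],
    )
    def test_rules(self, meta, kept):
        assert (filter_datasets([meta]) == [meta]) is kept

    def test_cells_property(self):
        assert DatasetMeta("x", "binary", 123, 7).n_cells == 861


class TestReadPmlb:
    def test_reads_gzipped_tsv_with_target(self, tmp_path):
        df = pd.DataFrame({"x1": [1, 2], "target": [0, 1]})
        path = tmp_path / "toy.tsv.gz"
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
        out = read_pmlb(path)
        pd.testing.assert_frame_equal(out, df)

    def test_missing_target_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"x": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="target"):
            read_pmlb(path)


@pytest.fixture(scope="module")
def small_suite():
    return simulate.gen_benchmark_suite(n_datasets=3, n=150, seed=17)


class TestRunBakeoff:
    def test_arms_share_identical_splits_and_rerun_is_identical(self, small_suite):
        r1 = run_bakeoff(small_suite, arms=("srl", "lasso"), seed=3)
        r2 = run_bakeoff(small_suite, arms=("srl", "lasso"), seed=3)
        pd.testing.assert_frame_equal(
            r1.drop(columns=["runtime_s"]), r2.drop(columns=["runtime_s"])
        )
        # one row per dataset x algorithm, shared seed per dataset
        per_ds = r1.groupby("dataset")["seed"].nunique()
        assert (per_ds == 1).all()

    def test_srl_reduction_matches_lasso_arm_exactly(self, small_suite):
        arms = [("srl_reduced", {"gamma": 0.0, "k": 0, "poly": 1}), "lasso"]
        res = run_bakeoff(small_suite[:2], arms=arms, seed=11)
        wide = res.pivot(index="dataset", columns="algorithm", values="test_metric")
        np.testing.assert_allclose(wide["srl_reduced"], wide["lasso"], rtol=0, atol=0)

    def test_failing_arm_recorded_not_fatal(self, small_suite):
        def boom(train, test, endpoint, seed):
            raise RuntimeError("deliberate failure")

        with pytest.warns(UserWarning, match="failed"):
            res = run_bakeoff(small_suite[:1], arms=[("bad", boom), "lasso"], seed=0)
        bad = res[res["algorithm"] == "bad"]
        assert bad["test_metric"].isna().all()
        assert not res[res["algorithm"] == "lasso"]["test_metric"].isna().any()


class TestWithinPctOfBest:
    def test_worked_example(self):
        res = pd.DataFrame(
            {
                "dataset": ["d1", "d1"],
                "algorithm": ["rf", "srl"],
                "test_metric_clamped": [0.90, 0.87],
            }
        )
        out = within_pct_of_best(res).set_index("algorithm")
        assert out.loc["srl", "pct_best"] == 0.0
        assert out.loc["srl", "pct_within"] == 100.0  # 0.87 >= 0.855
        assert out.loc["rf", "pct_best"] == 100.0

    def test_ties_credit_everyone(self):
        res = pd.DataFrame(
            {
                "dataset": ["d1", "d1", "d2", "d2"],
                "algorithm": ["a", "b", "a", "b"],
                "test_metric_clamped": [0.8, 0.8, 0.6, 0.6],
            }
        )
        out = within_pct_of_best(res)
        assert (out["pct_best"] == 100.0).all()

    def test_best_counting(self):
        res = pd.DataFrame(
            {
                "dataset": ["d1", "d1", "d2", "d2", "d3", "d3"],
                "algorithm": ["srl", "rf"] * 3,
                "test_metric_clamped": [0.9, 0.5, 0.4, 0.8, 0.3, 0.9],
            }
        )
        out = within_pct_of_best(res).set_index("algorithm")
        assert out.loc["srl", "pct_best"] == pytest.approx(100 / 3)


class TestMetaAnalyze:
    def test_recovers_planted_offsets_on_one_table(self):
        tab = simulate.gen_meta_table(n_datasets=200, seed=23)
        mm = meta_analyze(tab, metric="test_metric", reference="srl")
        assert mm.offset("lasso") == pytest.approx(-0.05, abs=0.01)
        assert mm.offset("nn") == pytest.approx(-0.15, abs=0.01)
        assert mm.random_intercept_var == pytest.approx(0.15**2, rel=0.4)
        assert not mm.fallback_fixed_effects

    def test_reference_switch_shifts_estimates_by_contrast(self):
        tab = simulate.gen_meta_table(n_datasets=80, seed=24)
        m_srl = meta_analyze(tab, metric="test_metric", reference="srl")
        m_lasso = meta_analyze(tab, metric="test_metric", reference="lasso")
        contrast = m_srl.offset("lasso")
        assert m_lasso.offset("srl") == pytest.approx(-contrast, abs=1e-6)
        assert m_lasso.offset("nn") == pytest.approx(
            m_srl.offset("nn") - contrast, abs=1e-6
        )

    def test_identical_algorithms_give_zero_offsets(self):
        rng = np.random.default_rng(25)
        effects = 0.6 + 0.1 * rng.standard_normal(30)
        rows = [
            {"dataset": f"d{i}", "algorithm": alg, "test_metric": effects[i]}
            for i in range(30)
            for alg in ("srl", "lasso")
        ]
        mm = meta_analyze(pd.DataFrame(rows), metric="test_metric")
        assert mm.offset("lasso") == pytest.approx(0.0, abs=1e-8)
        intercept = mm.estimates.set_index("term").loc["(Intercept)", "estimate"]
        assert intercept == pytest.approx(effects.mean(), abs=1e-6)

    def test_fixed_effects_invariant_to_per_dataset_shifts(self):
        tab = simulate.gen_meta_table(n_datasets=60, seed=26)
        shifted = tab.copy()
        shift = {f"ds{d:03d}": 0.3 * np.sin(d) for d in range(60)}
        shifted["test_metric"] += shifted["dataset"].map(shift)
        a = meta_analyze(tab, metric="test_metric")
        b = meta_analyze(shifted, metric="test_metric")
        assert a.offset("nn") == pytest.approx(b.offset("nn"), abs=1e-3)

    def test_too_few_groups_rejected(self):
        tab = simulate.gen_meta_table(n_datasets=2, seed=0)
        with pytest.raises(ValueError):
            meta_analyze(tab, metric="test_metric")


class TestCollapseScope:
    def test_full_scope_merges_rare_levels_before_split(self):
        rng = np.random.default_rng(31)
        n = 200
        df = pd.DataFrame(
            {
                "g": rng.choice(["A", "B", "rare"], n, p=[0.55, 0.40, 0.05]),
                "x": rng.standard_normal(n),
                "target": rng.standard_normal(n),
            }
        )
        ds = [{"name": "d", "data": df, "endpoint": "continuous"}]
        full = run_bakeoff(ds, arms=("lasso",), seed=0, collapse_scope="full")
        train = run_bakeoff(ds, arms=("lasso",), seed=0, collapse_scope="train")
        assert len(full) == len(train) == 1  # both modes run end to end
        with pytest.raises(ValueError, match="collapse_scope"):
            run_bakeoff(ds, arms=("lasso",), collapse_scope="all")
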