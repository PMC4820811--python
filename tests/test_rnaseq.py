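"""Transcriptome stage: RPKM arithmetic, background subtraction, the
sigma-about-zero statistic, the three detection routes and their consensus,
and the sequencing-QC derivations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicscreen.rnaseq import (
    CountMatrix,
    CountMatrixError,
    compute_log2fc,
    compute_rpkm,
    condition_means,
    consensus_hits,
    detect_by_sigma,
    estimate_sigma_zero,
    load_qc_table1,
    qc_summary,
    route_count_test,
    route_subtractive,
    run_de_pipeline,
    sigma_to_fold,
    size_factors,
    subtract_background,
)
from omicscreen.simulate import SimConfig, simulate_rnaseq_counts
from tests.conftest import planted_effects


class TestRpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame(
            {"s1": [650]}, index=pd.Index(["g1"], name="feature_id")
        )
        # single-gene sample: force the intended total via a filler gene
        counts.loc["filler"] = [6_500_000 - 650]
        cm = CountMatrix(
            counts=counts,
            lengths=pd.Series([1000, 1000], index=counts.index),
            samples=pd.DataFrame(
                {"condition": ["control"], "replicate": [1]}, index=["s1"]
            ),
        )
        assert compute_rpkm(cm).loc["g1", "s1"] == pytest.approx(100.0)

    def test_zero_count_gives_zero_rpkm(self, tiny_count_matrix):
        cm = tiny_count_matrix
        cm.counts.loc["g1", "control_1"] = 0
        assert compute_rpkm(cm).loc["g1", "control_1"] == 0.0

    def test_scale_invariance_per_sample(self, tiny_count_matrix):
        base = compute_rpkm(tiny_count_matrix)
        scaled = tiny_count_matrix.counts.copy()
        scaled["mutant_1"] = scaled["mutant_1"] * 7
        cm2 = CountMatrix(
            counts=scaled,
            lengths=tiny_count_matrix.lengths,
            samples=tiny_count_matrix.samples,
        )
        pd.testing.assert_series_equal(
            compute_rpkm(cm2)["mutant_1"], base["mutant_1"]
        )

    def test_zero_total_sample_rejected(self, tiny_count_matrix):
        counts = tiny_count_matrix.counts.copy()
        counts["control_1"] = 0
        with pytest.raises(CountMatrixError, match="control_1"):
            CountMatrix(
                counts=counts,
                lengths=tiny_count_matrix.lengths,
                samples=tiny_count_matrix.samples,
            )


class TestConditionMeansAndSubtraction:
    def test_mean_of_two_replicates(self, tiny_count_matrix):
        expr = pd.DataFrame(
            {"control_1": [2.0], "control_2": [4.0]},
            index=tiny_count_matrix.counts.index[:1],
        )
        expr = expr.reindex(tiny_count_matrix.counts.index, fill_value=0.0)
        m = condition_means(expr, tiny_count_matrix, "control")
        assert m.iloc[0] == 3.0

    def test_unknown_condition_rejected(self, tiny_count_matrix):
        with pytest.raises(CountMatrixError, match="unknown condition"):
            tiny_count_matrix.condition_columns("treated")

    def test_matches_bruteforce_on_simulated_fixture(self):
        cm, _ = simulate_rnaseq_counts(SimConfig(n_genes=50, seed=1))
        rpkm = compute_rpkm(cm)
        cols = cm.condition_columns("wildtype")
        brute = rpkm[cols].sum(axis=1) / len(cols)
        pd.testing.assert_series_equal(
            condition_means(rpkm, cm, "wildtype"), brute
        )

    @pytest.mark.parametrize(
        "cond, ctl, expected", [(5.0, 2.0, 3.0), (1.0, 4.0, 0.0), (7.0, 0.0, 7.0)]
    )
    def test_subtraction_clamps_at_zero(self, cond, ctl, expected):
        out = subtract_background(
            pd.Series([cond], index=["g"]), pd.Series([ctl], index=["g"])
        )
        assert out["g"] == expected

    def test_index_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            subtract_background(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )


class TestLog2fc:
    def test_examples(self):
        lfc, valid = compute_log2fc(
            pd.Series([2.0, 0.0, 3.0], index=list("abc")),
            pd.Series([8.0, 5.0, 3.0], index=list("abc")),
        )
        assert lfc["a"] == pytest.approx(-2.0)
        assert not valid["b"] and np.isnan(lfc["b"])
        assert lfc["c"] == 0.0 and valid["c"]


class TestSigmaZero:
    def test_hand_examples(self):
        assert estimate_sigma_zero([1.0, -1.0]).sigma == pytest.approx(1.0)
        assert estimate_sigma_zero([3.0, 4.0]).sigma == pytest.approx(
            np.sqrt(12.5)
        )

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            estimate_sigma_zero([1.0])

    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=2, max_size=50
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rms_about_zero_dominates_sd_about_mean(self, xs):
        est = estimate_sigma_zero(xs)
        assert est.sigma >= est.sd_about_mean - 1e-12

    @pytest.mark.parametrize(
        "sigma, k, fold",
        [(0.2321, 3, 1.62), (0.1787, 3, 1.45), (0.9, 0, 1.0)],
    )
    def test_sigma_to_fold_correspondences(self, sigma, k, fold):
        assert sigma_to_fold(sigma, k) == pytest.approx(fold, abs=0.005)


class TestDetectBySigma:
    def test_hand_thresholds(self):
        lfc = pd.Series({"f1": 0.9, "f2": -0.8, "f3": 0.1})
        sigma = estimate_sigma_zero([0.2, -0.2])  # sigma = 0.2, threshold 0.6
        hits = detect_by_sigma(lfc, sigma, k=3)
        assert hits == {"f1": "up", "f2": "down"}

    def test_tie_at_threshold_is_not_a_hit(self):
        sigma = estimate_sigma_zero([0.2, -0.2])
        hits = detect_by_sigma(pd.Series({"f": 0.6}), sigma, k=3)
        assert hits == {}

    def test_invalid_features_never_flagged(self):
        sigma = estimate_sigma_zero([0.1, -0.1])
        assert detect_by_sigma(pd.Series({"f": np.nan}), sigma, k=3) == {}

    def test_k6_hits_nest_within_k3(self, default_rna_fixture):
        cm, _, _ = default_rna_fixture
        res = run_de_pipeline(cm)
        k3 = {f for f, d in res["sigma_k3"].items() if d != "none"}
        k6 = {f for f, d in res["sigma_k6"].items() if d != "none"}
        assert k6 <= k3

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            detect_by_sigma(pd.Series({"f": 1.0}), estimate_sigma_zero([1, 1]), k=0)

    def test_null_flag_rate_matches_gaussian_tail(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(0, 0.3, size=20_000))
        hits = detect_by_sigma(x, estimate_sigma_zero(x), k=3)
        rate = len(hits) / len(x)
        expected = 0.0027
        se = np.sqrt(expected * (1 - expected) / len(x))
        assert abs(rate - expected) < 3 * se


class TestRoutes:
    def test_identical_conditions_give_no_subtractive_hits(self):
        rng = np.random.default_rng(1)
        n = 100
        base = rng.poisson(200, size=(n, 2))
        counts = pd.DataFrame(
            np.hstack([base, base, base]),
            index=pd.Index([f"g{i}" for i in range(n)], name="feature_id"),
            columns=[f"{c}_{r}" for c in ("control", "wildtype", "mutant") for r in (1, 2)],
        )
        cm = CountMatrix(
            counts=counts,
            lengths=pd.Series(1000, index=counts.index),
            samples=pd.DataFrame(
                {
                    "condition": ["control"] * 2 + ["wildtype"] * 2 + ["mutant"] * 2,
                    "replicate": [1, 2] * 3,
                },
                index=counts.columns,
            ),
        )
        assert route_subtractive(cm) == {}
        assert route_count_test(cm) == {}

    def test_planted_down_feature_flagged_down(self):
        effects = (("gene_00003", -2.0),)
        cfg = SimConfig(
            n_genes=300, seed=2, dispersion=0.01, size_factor_sd=0.0, effect_table=effects
        )
        cm, _ = simulate_rnaseq_counts(cfg)
        assert route_subtractive(cm).get("gene_00003") == "down"
        assert route_count_test(cm).get("gene_00003") == "down"

    def test_size_factors_track_column_scaling(self):
        cm, _ = simulate_rnaseq_counts(SimConfig(n_genes=200, seed=3, size_factor_sd=0.0))
        sf = size_factors(cm.counts)
        scaled = cm.counts.copy()
        col = scaled.columns[0]
        scaled[col] = scaled[col] * 2
        sf2 = size_factors(scaled)
        assert sf2[col] / sf[col] == pytest.approx(2.0, rel=0.05)
        # normalized counts of the scaled column are invariant
        norm1 = cm.counts[col] / sf[col]
        norm2 = scaled[col] / sf2[col]
        assert np.allclose(norm1, norm2, rtol=0.05)

    def test_count_route_recall_and_fdr_on_planted_fixture(self):
        recalls, fdrs = [], []
        for seed in range(5):
            effects = planted_effects(2000, 20, 1.5, seed=seed + 50)
            cfg = SimConfig(n_genes=2000, seed=seed, effect_table=effects)
            cm, _ = simulate_rnaseq_counts(cfg)
            hits = route_count_test(cm)
            planted = {f for f, _ in effects}
            tp = len(set(hits) & planted)
            recalls.append(tp / len(planted))
            fdrs.append((len(hits) - tp) / max(len(hits), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdrs) <= 0.1

    def test_subtractive_type_I_error_calibrated(self):
        # all-null simulation: t-test flag rate (before the fold filter)
        # close to alpha
        cfg = SimConfig(n_genes=2000, seed=9, responsive_fraction=1.0)
        cm, _ = simulate_rnaseq_counts(cfg)
        rpkm = compute_rpkm(cm)
        from scipy import stats

        ctl_mean = condition_means(rpkm, cm, "control")
        mut = np.log2(
            rpkm[cm.condition_columns("mutant")].sub(ctl_mean, axis=0).clip(lower=0) + 0.5
        )
        wt = np.log2(
            rpkm[cm.condition_columns("wildtype")].sub(ctl_mean, axis=0).clip(lower=0) + 0.5
        )
        _, p = stats.ttest_ind(mut, wt, axis=1)
        rate = np.mean(p <= 0.05)
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < 4 * se


class TestConsensus:
    def test_intersection_with_directions(self):
        routes = {
            "r1": {"A": "down", "B": "down", "C": "down"},
            "r2": {"B": "down", "C": "down", "D": "down"},
            "r3": {"B": "down", "C": "down"},
        }
        assert consensus_hits(routes) == {"B": "down", "C": "down"}

    def test_direction_conflict_excluded(self):
        routes = {"r1": {"A": "up"}, "r2": {"A": "down"}}
        assert consensus_hits(routes) == {}

    def test_empty_route_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_hits({})


class TestQc:
    def test_published_worked_examples(self):
        per_sample, _ = qc_summary(load_qc_table1())
        cells = per_sample.set_index("sample_id")
        assert cells.loc["CNT-A4", "pct_mapped_wo_dup"] == pytest.approx(84.63, abs=0.005)
        assert cells.loc["MUT-A2", "pct_properly_paired"] == pytest.approx(80.30, abs=0.005)

    def test_simple_percentage(self):
        rows = pd.DataFrame(
            {
                "sample_id": ["s"],
                "total_reads": [10.0],
                "mapped_reads": [8.0],
                "mapped_wo_dup": [5.0],
                "properly_paired": [4.0],
            }
        )
        per_sample, totals = qc_summary(rows)
        assert per_sample.loc[0, "pct_mapped_wo_dup"] == pytest.approx(50.0)
        assert totals.loc[0, "sample_id"] == "combined-total"

    def test_hierarchy_violation_names_sample(self):
        rows = pd.DataFrame(
            {
                "sample_id": ["bad"],
                "total_reads": [10.0],
                "mapped_reads": [11.0],
                "mapped_wo_dup": [5.0],
                "properly_paired": [4.0],
            }
        )
        with pytest.raises(ValueError, match="bad"):
            qc_summary(rows)

    def test_sequenced_bases_and_coverage(self):
        per_sample, _ = qc_summary(load_qc_table1())
        cells = per_sample.set_index("sample_id")
        # 20.71e6 properly paired reads x 100 bp = 2,071 Mb; /65 Mb ~ 31.9x
        assert cells.loc["CNT-A4", "sequenced_mb"] == pytest.approx(2071.0, abs=0.5)
        assert cells.loc["CNT-A4", "coverage_x"] == pytest.approx(31.86, abs=0.05)
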