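"""Tests for the combined-metric bioequivalence engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dermapk.bioequiv import (
    _verdict,
    be_ratio,
    combined_mean_from_phase_means,
    combined_metric,
    compare_groups,
    phase_summary,
    totals_to_frame,
    ReplicateTotal,
)
from dermapk.reference_data import EN_SC_SUMMARY

from oracles import exhaustive_bootstrap_ratio_ci


def frame(product, uptake, clearance):
    rows = []
    for i, v in enumerate(uptake):
        rows.append(ReplicateTotal(f"s{i}", product, "uptake", v))
    for i, v in enumerate(clearance):
        rows.append(ReplicateTotal(f"c{i}", product, "clearance", v))
    return totals_to_frame(rows)


class TestPhaseSummary:
    def test_constant_sample_has_point_interval(self):
        df = frame("P", [2.0] * 14, [2.0] * 14)
        for method in ("bootstrap", "log-t"):
            s = phase_summary(df, "P", "uptake", method=method, seed=0)
            assert (s.mean, s.ci_low, s.ci_high) == (2.0, 2.0, 2.0)
            assert s.n == 14

    def test_minimum_replicates_enforced(self):
        df = frame("P", [1.0, 2.0], [1.0] * 5)
        with pytest.raises(ValueError, match="at least 3"):
            phase_summary(df, "P", "uptake")

    def test_log_t_interval_is_asymmetric_around_mean(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(np.log(2), 0.8, 14))
        df = frame("P", x, x)
        s = phase_summary(df, "P", "uptake", method="log-t")
        # log-normal data: upper tail further from the arithmetic mean
        assert s.ci_high - s.mean != pytest.approx(s.mean - s.ci_low, rel=0.2)

    def test_log_t_interval_covers_median_at_nominal_rate(self):
        # 90% interval on the log scale is exact for the log-normal median
        rng = np.random.default_rng(0)
        sigma = np.sqrt(np.log(1 + 0.4**2))
        hits = 0
        for _ in range(400):
            x = np.exp(rng.normal(np.log(2.0), sigma, 14))
            df = frame("P", x, x)
            s = phase_summary(df, "P", "uptake", method="log-t")
            hits += s.ci_low <= 2.0 <= s.ci_high
        assert 0.85 <= hits / 400 <= 0.95


class TestCombinedMetric:
    def test_published_phase_means_combine_by_equal_weight(self):
        p = EN_SC_SUMMARY["Perrigo"]
        combined = combined_mean_from_phase_means(
            p["uptake"]["mean"], p["clearance"]["mean"]
        )
        assert combined == pytest.approx(2.075)

    def test_constant_amounts_combine_to_same_value(self):
        df = frame("P", [3.0] * 5, [3.0] * 5)
        assert combined_metric(df, "P").combined_mean == 3.0

    def test_unequal_phase_sizes_pool_all_observations(self):
        uptake = [1.0, 2.0, 3.0]
        clearance = [4.0, 5.0]
        df = frame("P", uptake, clearance)
        c = combined_metric(df, "P")
        assert c.combined_mean == pytest.approx(np.mean(uptake + clearance))
        assert c.n == 5

    def test_missing_phase_rejected(self):
        df = totals_to_frame([ReplicateTotal("s1", "P", "uptake", 1.0)])
        with pytest.raises(ValueError, match="clearance"):
            combined_metric(df, "P")


class TestBeRatio:
    def test_identical_pooled_samples_are_equivalent(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(np.log(2), np.sqrt(np.log(1 + 0.3**2)), 28))
        res = be_ratio(x, x, seed=0)
        assert res.ratio == pytest.approx(1.0)
        assert res.verdict == "equivalent"
        assert res.point_within_limits

    def test_reciprocal_point_estimates(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(1, 3, 20)
        b = rng.uniform(1, 3, 20)
        fwd = be_ratio(a, b, seed=1).ratio
        rev = be_ratio(b, a, seed=1).ratio
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_seeded_bootstrap_matches_exhaustive_enumeration(self):
        a = np.array([1.8, 2.4, 2.0, 2.6, 2.2])
        b = np.array([2.1, 1.9, 2.5, 2.0, 2.3])
        exact_lo, exact_hi = exhaustive_bootstrap_ratio_ci(a, b)
        res = be_ratio(a, b, seed=0, n_boot=40_000)
        assert res.ci_low == pytest.approx(exact_lo, abs=0.02)
        assert res.ci_high == pytest.approx(exact_hi, abs=0.02)

    def test_raw_and_log_scales_agree_for_equivalent_products(self):
        rng = np.random.default_rng(10)
        sigma = np.sqrt(np.log(1 + 0.4**2))
        a = np.exp(rng.normal(np.log(2), sigma, 28))
        b = np.exp(rng.normal(np.log(2), sigma, 28))
        raw = be_ratio(a, b, scale="raw", seed=0).ratio
        logr = be_ratio(a, b, scale="log", seed=0).ratio
        assert abs(raw / logr - 1) < 0.05

    def test_widening_ci_never_restores_equivalence(self):
        limits = (0.8, 1.25)
        rank = {"equivalent": 0, "inconclusive": 1, "not-equivalent": 1}
        for lo, hi in [(0.9, 1.1), (0.82, 1.2), (0.85, 1.24)]:
            base = rank[_verdict((lo, hi), limits)]
            for pad in (0.05, 0.2, 0.6):
                widened = rank[_verdict((lo - pad, hi + pad), limits)]
                assert widened >= base

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            be_ratio(np.ones(5), np.zeros(5), seed=0)

    def test_t_interval_on_log_scale(self):
        rng = np.random.default_rng(12)
        a = np.exp(rng.normal(0.1, 0.3, 20))
        b = np.exp(rng.normal(0.0, 0.3, 20))
        res = be_ratio(a, b, scale="log", method="t")
        assert res.ci_low < res.ratio < res.ci_high


class TestCompareGroups:
    def test_identical_groups_give_unit_pvalues(self):
        df = pd.DataFrame({"y": [5.0] * 12, "g": ["a", "b", "c"] * 4})
        rep = compare_groups(df, "y", "g")
        assert rep["anova_p"] == 1.0
        assert all(p == 1.0 for p in rep["pairwise_p"].values())

    def test_huge_separation_is_significant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "y": np.concatenate([rng.normal(0, 1, 14), rng.normal(10, 1, 14)]),
                "g": ["a"] * 14 + ["b"] * 14,
            }
        )
        rep = compare_groups(df, "y", "g")
        assert rep["significant"]
        assert rep["pairwise_p"][("a", "b")] < 0.001

    def test_bonferroni_battery_controls_family_error(self):
        # null simulation: 3 equal groups; family-wise error of the corrected
        # pairwise tests must stay at/below alpha up to Monte-Carlo error
        rng = np.random.default_rng(1)
        n_rep, hits = 500, 0
        for _ in range(n_rep):
            df = pd.DataFrame({"y": rng.normal(0, 1, 42), "g": ["a", "b", "c"] * 14})
            rep = compare_groups(df, "y", "g")
            hits += any(p < 0.05 for p in rep["pairwise_p"].values())
        mc_slack = 2 * np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= 0.05 + mc_slack

    def test_two_way_design(self):
        rng = np.random.default_rng(3)
        rows = []
        for prod in ("A", "B"):
            for phase in ("uptake", "clearance"):
                for _ in range(6):
                    rows.append({"y": rng.normal(2.0, 0.3), "prod": prod, "phase": phase})
        rep = compare_groups(
            pd.DataFrame(rows), "y", "prod", factor2="phase", design="two-way"
        )
        assert set(rep["anova_p"]) == {"prod", "phase", "interaction"}
        assert not rep["significant"]["prod"]

    def test_degenerate_input_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "b"]})
        with pytest.raises(ValueError):
            compare_groups(df, "y", "g")
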