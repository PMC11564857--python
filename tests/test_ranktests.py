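"""Rank machinery, Mann-Whitney modes, per-tract and single-ROI comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

import tractstats as ts
from tractstats.ranktests import tie_term


def naive_midranks(values):
    """O(n^2) pairwise-counting oracle: rank = #less + (#equal + 1) / 2."""
    a = np.asarray(values, dtype=float)
    return np.array([
        np.sum(a < v) + (np.sum(a == v) + 1) / 2.0 for v in a
    ])


class TestMidranks:
    @pytest.mark.parametrize("values,expected", [
        ([3, 1, 2], [3, 1, 2]),
        ([5, 5, 7], [1.5, 1.5, 3]),
    ])
    def test_examples(self, values, expected):
        assert np.allclose(ts.midranks(values), expected)

    @settings(max_examples=100, derandomize=True)
    @given(hst.lists(hst.integers(min_value=-5, max_value=5), min_size=1, max_size=50))
    def test_matches_pairwise_counting_oracle(self, values):
        ranks = ts.midranks(values)
        assert np.allclose(ranks, naive_midranks(values))
        n = len(values)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ts.midranks([1.0, np.nan, 2.0])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = ts.mann_whitney(x, x, mode="asymptotic")
        assert res.U == pytest.approx(len(x) ** 2 / 2)
        assert res.p == 1.0

    def test_separated_pairs_exact(self):
        res = ts.mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.U == 0
        assert res.p == pytest.approx(2 / 6)

    def test_degenerate_constant_data_flagged(self):
        res = ts.mann_whitney([5.0] * 4, [5.0] * 5)
        assert res.p == 1.0 and res.degenerate

    def test_exact_matches_scipy_enumeration(self, rng):
        """Exact p equals scipy's exact enumeration on tie-free draws."""
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(0.5, size=5)
            ours = ts.mann_whitney(x, y, mode="exact")
            ref = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_with_ties_matches_scipy_permutation(self, rng):
        """Tied exact p equals a scipy permutation test over all splits."""
        for _ in range(5):
            x = np.round(rng.normal(size=4), 0)
            y = np.round(rng.normal(size=4), 0)
            if np.unique(np.concatenate([x, y])).size == 1:
                continue
            ours = ts.mann_whitney(x, y, mode="exact")

            def stat(a, b):
                return st.mannwhitneyu(a, b, alternative="two-sided").statistic

            ref = st.permutation_test(
                (x, y), stat, permutation_type="independent",
                alternative="two-sided", n_resamples=np.inf)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        for _ in range(30):
            x = np.round(rng.normal(size=12), 1)
            y = np.round(rng.normal(0.4, size=15), 1)
            ours = ts.mann_whitney(x, y, mode="asymptotic")
            ref = st.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
            assert ours.U == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_asymptotic_agreement_tie_free(self, rng):
        """The two modes agree within 0.02 for tie-free samples at n = 10 + 10."""
        for _ in range(200):
            x = rng.normal(size=10)
            y = rng.normal(rng.uniform(-1, 1), size=10)
            pe = ts.mann_whitney(x, y, mode="exact").p
            pa = ts.mann_whitney(x, y, mode="asymptotic").p
            assert abs(pe - pa) <= 0.02

    @settings(max_examples=60, derandomize=True)
    @given(
        hst.lists(hst.floats(-100, 100), min_size=2, max_size=12),
        hst.lists(hst.floats(-100, 100), min_size=2, max_size=12),
    )
    def test_u_statistics_sum_to_n1_n2(self, x, y):
        u1 = ts.mann_whitney(x, y, mode="asymptotic").U
        u2 = ts.mann_whitney(y, x, mode="asymptotic").U
        assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_auto_mode_switches_on_combined_size(self):
        small = ts.mann_whitney([1, 2, 3], [4, 5, 6])
        large = ts.mann_whitney(list(range(10)), list(range(10, 20)))
        assert small.mode == "exact" and large.mode == "asymptotic"

    def test_tie_term(self):
        assert tie_term([1, 1, 2, 3, 3, 3]) == (8 - 2) + (27 - 3)


def _panel_from_matrix(values, groups, metric="DKI_FA"):
    n, t = values.shape
    return pd.DataFrame({
        "subject_id": np.repeat([f"s{i}" for i in range(n)], t),
        "group": np.repeat(groups, t),
        "metric": metric,
        "tract_id": np.tile(np.arange(t), n),
        "value": values.ravel(),
    })


class TestCompareTracts:
    def test_identical_groups_single_tract_not_significant(self):
        values = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        groups = [ts.ATHLETE] * 3 + [ts.CONTROL] * 3
        out = ts.compare_tracts(_panel_from_matrix(values, groups))
        assert len(out) == 1
        assert out.loc[0, "p"] == 1.0
        assert not out.loc[0, "significant_0.05"]

    def test_subject_and_tract_order_invariance(self, small_null_cohort):
        panel, _ = small_null_cohort
        shuffled = panel.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = ts.compare_tracts(panel).sort_values(["metric", "tract_id"]).reset_index(drop=True)
        b = ts.compare_tracts(shuffled).sort_values(["metric", "tract_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_injected_tracts_dominate_significant_set(self):
        """20 strongly shifted tracts should account for the significant set."""
        cfg = ts.SimulationConfig.null(
            n_group1=20, n_group2=20, metrics=("DKI_FA",), seed=31)
        cfg = cfg.replace(effect_delta={"DKI_FA": 2.0},
                          affected_tracts={"DKI_FA": tuple(range(20))},
                          effect_sign={"DKI_FA": +1})
        panel, _ = ts.generate_cohort(cfg)
        out = ts.compare_tracts(panel)
        hits = set(out.loc[out["significant_0.05"], "tract_id"])
        assert len(hits & set(range(20))) >= 18
        assert len(hits - set(range(20))) <= 8

    def test_null_false_positive_rate_nominal(self):
        """Per-tract rejection fraction near alpha under the null."""
        flags = []
        cfg = ts.SimulationConfig.null(n_group1=20, n_group2=21,
                                       inter_tract_rho=0.0,
                                       metrics=("DTI_MD",))
        for s in range(40):
            panel, _ = ts.generate_cohort(cfg.replace(seed=900 + s))
            out = ts.compare_tracts(panel, alphas=(0.05,))
            flags.append(out["significant_0.05"].to_numpy())
        rate = np.concatenate(flags).mean()
        assert 0.03 <= rate <= 0.07


class TestSingleRoi:
    def test_constant_subject_roi_equals_value(self):
        values = np.full((4, 72), 0.5)
        values[0] = 0.7
        groups = [ts.ATHLETE] * 2 + [ts.CONTROL] * 2
        roi = ts.subject_roi_means(_panel_from_matrix(values, groups))
        assert roi.loc[roi["subject_id"] == "s0", "roi_value"].item() == pytest.approx(0.7)

    def test_roi_mean_matches_streaming_sum_oracle(self, rng):
        values = rng.normal(size=(6, 72))
        groups = [ts.ATHLETE] * 3 + [ts.CONTROL] * 3
        panel = _panel_from_matrix(values, groups)
        roi = ts.subject_roi_means(panel).set_index("subject_id")["roi_value"]
        for i in range(6):
            total = 0.0
            for v in values[i]:
                total += v
            assert roi[f"s{i}"] == pytest.approx(total / 72)

    def test_partial_coverage_subject_dropped(self):
        values = np.random.default_rng(0).normal(size=(6, 10))
        groups = [ts.ATHLETE] * 3 + [ts.CONTROL] * 3
        panel = _panel_from_matrix(values, groups)
        panel = panel[~((panel["subject_id"] == "s0") & (panel["tract_id"] == 3))]
        roi = ts.subject_roi_means(panel)
        assert "s0" not in set(roi["subject_id"])

    def test_strong_dki_fa_effect_direction(self, default_cohort):
        """Athlete single-ROI DKI FA median exceeds the control median."""
        panel, _ = default_cohort
        roi = ts.single_wm_roi(panel).set_index("metric")
        assert roi.loc["DKI_FA", "median_g1"] > roi.loc["DKI_FA", "median_g2"]
        assert roi.loc["DKI_FA", "p"] < 0.05
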