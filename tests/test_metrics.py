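"""Bias / precision / accuracy statistics, paired tests, and adjustment rules."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
from statsmodels.stats.multitest import multipletests

import egfrval as ev
from egfrval.metrics import (
    BootstrapSpec,
    PairedSeries,
    apply_bh_family,
    subgroup_table_frame,
    within_tolerance,
)
from .conftest import make_series


class TestSignedBias:
    def test_identity_is_zero(self, identity_series, fast_boot):
        assert ev.signed_bias(identity_series, fast_boot).median_bias == 0.0

    def test_constant_shift(self, fast_boot):
        m = np.linspace(30, 100, 15)
        assert ev.signed_bias(make_series(m + 2.0, m), fast_boot).median_bias == pytest.approx(2.0)

    def test_hand_example(self, fast_boot):
        r = ev.signed_bias(make_series([50, 60, 70], [48, 57, 75]), fast_boot)
        assert r.median_bias == pytest.approx(2.0)
        assert r.ci_low <= r.median_bias <= r.ci_high

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            make_series([], [])


class TestPrecisionIqr:
    def test_constant_differences_zero(self, fast_boot):
        m = np.linspace(30, 100, 12)
        assert ev.precision_iqr(make_series(m + 3.0, m), fast_boot).iqr == 0.0

    def test_linear_interpolation_estimator(self, fast_boot):
        m = np.full(5, 50.0)
        r = ev.precision_iqr(make_series(m + np.array([1, 2, 3, 4, 5.0]), m), fast_boot)
        assert r.iqr == pytest.approx(2.0)

    def test_scale_homogeneity(self, rng, fast_boot):
        m = np.full(40, 80.0)
        d = rng.normal(0, 5, 40)
        i1 = ev.precision_iqr(make_series(m + d, m), fast_boot).iqr
        i3 = ev.precision_iqr(make_series(m + 3 * d, m), fast_boot).iqr
        assert i3 == pytest.approx(3 * i1)

    def test_too_short_rejected(self, fast_boot):
        with pytest.raises(ValueError):
            ev.precision_iqr(make_series([50.0], [49.0]), fast_boot)


class TestAccuracyPx:
    def test_identity_is_100(self, identity_series, fast_boot):
        assert ev.accuracy_px(identity_series, 30, fast_boot).proportion_pct == 100.0

    def test_boundary_inclusive(self, fast_boot):
        s = make_series([130.0, 130.0, 130.0, 130.0], [100.0, 100.0, 100.0, 100.0])
        assert ev.accuracy_px(s, 30, fast_boot).proportion_pct == 100.0

    def test_hand_count(self, fast_boot):
        # 85 and 115 sit exactly on the inclusive 15% boundary; 131 is out
        s = make_series([85, 115, 131, 100], [100, 100, 100, 100])
        assert ev.accuracy_px(s, 15, fast_boot).proportion_pct == pytest.approx(75.0)

    def test_vectorized_matches_row_loop(self, rng, fast_boot):
        m = rng.uniform(20, 120, 200)
        e = m * np.exp(rng.normal(0, 0.25, 200))
        s = make_series(e, m)
        for x in (15.0, 20.0, 30.0):
            manual = 100.0 * sum(abs(ei - mi) <= x / 100 * mi for ei, mi in zip(e, m)) / len(m)
            assert ev.accuracy_px(s, x, fast_boot).proportion_pct == pytest.approx(manual)

    def test_px_monotone_in_tolerance(self, rng, fast_boot):
        m = rng.uniform(20, 120, 150)
        s = make_series(m * np.exp(rng.normal(0, 0.2, 150)), m)
        p15, p20, p30 = (ev.accuracy_px(s, x, fast_boot).proportion_pct for x in (15, 20, 30))
        assert p15 <= p20 <= p30


class TestBootstrapBehaviour:
    def test_ci_contains_point_estimate_and_shrinks(self, rng):
        boot = BootstrapSpec(replicates=500, seed=3)
        widths = {}
        for n in (50, 500):
            m = rng.uniform(30, 110, n)
            s = make_series(m * np.exp(rng.normal(0, 0.2, n)), m)
            r = ev.signed_bias(s, boot)
            assert r.ci_low <= r.median_bias <= r.ci_high
            p = ev.precision_iqr(s, boot)
            assert p.ci_low <= p.iqr <= p.ci_high
            widths[n] = r.ci_high - r.ci_low
        assert widths[500] < widths[50]

    def test_identical_seed_reproduces_ci(self, identity_series):
        m = np.linspace(20, 120, 60)
        s = make_series(m + np.sin(m), m)
        r1 = ev.signed_bias(s, BootstrapSpec(replicates=300, seed=11))
        r2 = ev.signed_bias(s, BootstrapSpec(replicates=300, seed=11))
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestIqrDifferenceTest:
    def test_identical_series_p_one(self, rng):
        m = rng.uniform(30, 110, 80)
        a = make_series(m * np.exp(rng.normal(0, 0.2, 80)), m, "a")
        r = ev.iqr_difference_test(a, a, BootstrapSpec(replicates=200, seed=5))
        assert r.p_raw == 1.0 and r.statistic == 0.0

    def test_doubled_spread_detected(self, rng):
        m = rng.uniform(30, 110, 200)
        d = rng.normal(0, 8, 200)
        a = make_series(m + d, m, "a")
        b = make_series(m + 2 * d, m, "b")
        r = ev.iqr_difference_test(a, b, BootstrapSpec(replicates=2000, seed=5))
        assert r.p_raw < 0.05
        assert r.statistic < 0  # a is tighter than b

    def test_single_replicate_floor(self, rng):
        m = rng.uniform(30, 110, 30)
        a = make_series(m + rng.normal(0, 3, 30), m, "a")
        r = ev.iqr_difference_test(a, a, BootstrapSpec(replicates=1, seed=1))
        assert r.p_raw == 1.0


class TestMcNemar:
    @staticmethod
    def _series_pair(rng, n=40, sa=0.12, sb=0.3):
        m = rng.uniform(30, 110, n)
        a = make_series(m * np.exp(rng.normal(0, sa, n)), m, "a")
        b = make_series(m * np.exp(rng.normal(0, sb, n)), m, "b")
        return a, b

    def test_continuity_corrected_hand_value(self):
        # discordant counts 10 and 2 -> (|10-2|-1)^2/12
        m = np.full(12, 100.0)
        a = make_series(np.where(np.arange(12) < 10, 100.0, 200.0), m, "a")
        b = make_series(np.where(np.arange(12) < 10, 200.0, 100.0), m, "b")
        r = ev.accuracy_mcnemar(a, b, 30, method="chi2")
        assert r.statistic == pytest.approx(49 / 12, abs=1e-9)
        assert r.p_raw == pytest.approx(0.0433, abs=5e-4)

    def test_no_discordance_p_one(self, identity_series):
        r = ev.accuracy_mcnemar(identity_series, identity_series, 30)
        assert r.p_raw == 1.0 and "no discordant" in r.note

    def test_symmetry(self, rng):
        a, b = self._series_pair(rng)
        r1 = ev.accuracy_mcnemar(a, b, 30)
        r2 = ev.accuracy_mcnemar(b, a, 30)
        assert r1.p_raw == pytest.approx(r2.p_raw) and r1.statistic == pytest.approx(r2.statistic)

    def test_exact_variant_matches_statsmodels(self, rng):
        for _ in range(20):
            a, b = self._series_pair(rng, n=18)
            wa, wb = within_tolerance(a, 30), within_tolerance(b, 30)
            n11 = int(np.sum(wa & wb)); n10 = int(np.sum(wa & ~wb))
            n01 = int(np.sum(~wa & wb)); n00 = int(np.sum(~wa & ~wb))
            if n10 + n01 == 0:
                continue
            ours = ev.accuracy_mcnemar(a, b, 30, method="exact").p_raw
            ref = sm_mcnemar([[n11, n10], [n01, n00]], exact=True).pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_chi2_variant_matches_statsmodels(self, rng):
        for _ in range(10):
            a, b = self._series_pair(rng, n=300)
            ours = ev.accuracy_mcnemar(a, b, 20, method="chi2")
            wa, wb = within_tolerance(a, 20), within_tolerance(b, 20)
            n10 = int(np.sum(wa & ~wb))
            n01 = int(np.sum(~wa & wb))
            ref = sm_mcnemar([[0, n10], [n01, 0]], exact=False, correction=True)
            assert ours.p_raw == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestWilcoxonSignedRank:
    def test_identical_p_one(self, rng):
        m = rng.uniform(30, 110, 50)
        a = make_series(m + 1.0, m, "a")
        r = ev.wilcoxon_signed_rank(a, a)
        assert r.p_raw == 1.0

    def test_location_shift_detected(self, rng):
        m = rng.uniform(30, 110, 200)
        noise = rng.normal(0, 4, 200)
        a = make_series(m + noise + 3.0, m, "a")
        b = make_series(m + noise, m, "b")
        assert ev.wilcoxon_signed_rank(a, b).p_raw < 0.001

    def test_symmetric_null_large_n(self, rng):
        m = rng.uniform(30, 110, 400)
        sym = rng.normal(0, 5, 400)
        a = make_series(m + sym, m, "a")
        b = make_series(m, m, "b")
        assert ev.wilcoxon_signed_rank(a, b).p_raw > 0.05


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        assert ev.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        assert ev.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_relabeling_symmetry(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 7)
        assert ev.wilcoxon_rank_sum(x, y) == pytest.approx(ev.wilcoxon_rank_sum(y, x))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ev.wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert ev.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_example(self):
        np.testing.assert_allclose(ev.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_never_below_raw_and_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            adj = ev.bh_adjust(p)
            assert np.all(adj >= p - 1e-15)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(adj, ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ev.bh_adjust([0.5, 1.2])

    def test_family_annotation_order_preserved(self, rng):
        m = rng.uniform(30, 110, 60)
        a = make_series(m + rng.normal(0, 3, 60), m, "a")
        b = make_series(m + rng.normal(2, 3, 60), m, "b")
        c = make_series(m + rng.normal(-2, 6, 60), m, "c")
        fam = [ev.wilcoxon_signed_rank(a, b), ev.wilcoxon_signed_rank(a, c), ev.wilcoxon_signed_rank(b, c)]
        out = apply_bh_family(fam)
        assert [t.pair for t in out] == [t.pair for t in fam]
        assert all(t.p_adjusted >= t.p_raw for t in out)


class TestRecCurve:
    def test_identity_flat_100(self, identity_series):
        c = ev.rec_curve(identity_series, np.arange(1, 61))
        assert np.all(c.fraction_within == 100.0)

    def test_matches_accuracy_point_estimates(self, rng, fast_boot):
        m = rng.uniform(30, 110, 120)
        s = make_series(m * np.exp(rng.normal(0, 0.2, 120)), m)
        c = ev.rec_curve(s, [15.0, 20.0, 30.0])
        for g, f in zip(c.tolerance_grid, c.fraction_within):
            assert f == pytest.approx(ev.accuracy_px(s, g, fast_boot).proportion_pct)

    def test_single_subject_step(self):
        s = make_series([125.0], [100.0])
        c = ev.rec_curve(s, [24.9, 25.0, 25.1])
        np.testing.assert_allclose(c.fraction_within, [0.0, 100.0, 100.0])

    def test_non_decreasing(self, rng):
        m = rng.uniform(30, 110, 200)
        s = make_series(m * np.exp(rng.normal(0.1, 0.3, 200)), m)
        c = ev.rec_curve(s, np.arange(1, 81))
        assert np.all(np.diff(c.fraction_within) >= 0)

    def test_empty_grid_rejected(self, identity_series):
        with pytest.raises(ValueError):
            ev.rec_curve(identity_series, [])


class TestSubgroupTable:
    @staticmethod
    def _cohort(rng, n=120, shift=0.0):
        m = rng.uniform(30, 110, n)
        flag = rng.random(n) < 0.5
        e = m * np.exp(rng.normal(0, 0.2, n) + np.where(flag, shift, 0.0))
        return pd.DataFrame({"subject_id": [str(i) for i in range(n)], "mgfr": m, "egfr_x": e, "flag": flag})

    def test_single_stratum_skipped(self, rng, fast_boot):
        df = self._cohort(rng)
        df["flag"] = True
        rows = ev.subgroup_bias_table(df, {"x": "egfr_x"}, ["flag"], boot=fast_boot)
        assert rows == []

    def test_shape_one_row_per_flag_equation_pair(self, rng, fast_boot):
        df = self._cohort(rng)
        df["flag2"] = ~df["flag"]
        df["egfr_y"] = df["egfr_x"] * 1.01
        rows = ev.subgroup_bias_table(df, {"x": "egfr_x", "y": "egfr_y"}, ["flag", "flag2"], boot=fast_boot)
        assert len(rows) == 4
        frame = subgroup_table_frame(rows)
        assert set(frame["condition"]) == {"flag", "flag2"} and len(frame) == 4

    def test_configured_shift_detected(self, fast_boot):
        rng = np.random.default_rng(42)
        df = self._cohort(rng, n=400, shift=-0.15)
        rows = ev.subgroup_bias_table(df, {"x": "egfr_x"}, ["flag"], boot=fast_boot)
        assert rows[0].p_value < 0.05
        assert rows[0].eligible

    def test_small_stratum_flagged_ineligible(self, rng, fast_boot):
        df = self._cohort(rng, n=60)
        df["rare"] = np.arange(60) < 10
        rows = ev.subgroup_bias_table(df, {"x": "egfr_x"}, ["rare"], min_size=25, boot=fast_boot)
        assert rows[0].eligible is False and np.isfinite(rows[0].p_value)


class TestSampleSize:
    def test_ci_width_hand_value(self):
        assert ev.sample_size_proportion(0.5, 0.1, alpha=0.05, method="ci_width") == 97

    def test_margin_halving_quadruples(self):
        n1 = ev.sample_size_proportion(0.3, 0.1, method="ci_width")
        n2 = ev.sample_size_proportion(0.3, 0.05, method="ci_width")
        assert n2 == pytest.approx(4 * n1, rel=0.02)

    def test_test_variant_near_planning_value(self):
        # planning figure of ~106 subjects for P20 accuracy 0.715 at 15%
        # absolute margin, alpha 5%, power 90%; the exact software variant
        # is not fully specified, so only proximity is asserted
        n = ev.sample_size_proportion(0.715, 0.15, alpha=0.05, power=0.90, method="test")
        assert 95 <= n <= 115

    def test_excessive_margin_rejected(self):
        with pytest.raises(ValueError):
            ev.sample_size_proportion(0.9, 0.15)
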