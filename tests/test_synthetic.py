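"""Ground-truth generator and panel simulator."""

import numpy as np
import pytest

from infodbn import (
    GroundTruth,
    fold,
    inject_missingness,
    make_ground_truth,
    simulate_panel,
    with_variance_fractions,
)
from infodbn.errors import InfeasibleGraphError, ParameterError


class TestMakeGroundTruth:
    def test_forced_arc_classes_p2_feedback(self):
        gt = make_ground_truth(p=2, n_feedback=1, n_unidirectional=0, seed=1)
        folded = fold(gt.dag)
        assert folded.feedback == frozenset({("C01", "C02")})
        assert folded.autoloops == frozenset({"C01", "C02"})
        assert not folded.unidirectional

    def test_forced_arc_classes_p3_unidirectional(self):
        gt = make_ground_truth(p=3, n_feedback=0, n_unidirectional=2, seed=7)
        folded = fold(gt.dag)
        assert len(folded.unidirectional) == 2
        assert not folded.feedback
        assert len(folded.autoloops) == 3

    def test_large_truth_is_stable_var1(self):
        """Spectral radius of the folded coefficient matrix stays below 1."""
        gt = make_ground_truth(p=12, n_feedback=8, n_unidirectional=10, seed=3)
        eigvals = np.linalg.eigvals(gt.coefficient_matrix())
        assert np.max(np.abs(eigvals)) < 1
        folded = fold(gt.dag)
        assert len(folded.feedback) == 8
        assert len(folded.unidirectional) == 10

    def test_deterministic_given_seed(self):
        a = make_ground_truth(5, 2, 3, seed=11)
        b = make_ground_truth(5, 2, 3, seed=11)
        assert a.dag == b.dag
        assert np.array_equal(a.coefficient_matrix(), b.coefficient_matrix())

    @pytest.mark.parametrize(
        "p,fb,uni",
        [(2, 2, 0), (3, 2, 2), (2, 0, 2), (1, 0, 0)],
    )
    def test_infeasible_requests_rejected(self, p, fb, uni):
        with pytest.raises((InfeasibleGraphError, ParameterError)):
            make_ground_truth(p, fb, uni, seed=0)

    def test_variance_fraction_calibration_sets_positive_sds(self, default_gt):
        gts = with_variance_fractions(default_gt, 0.12, 0.49)
        assert np.all(np.atleast_1d(gts.state_sd) > 0)
        assert np.all(np.atleast_1d(gts.county_sd) > 0)
        # requested ratio of components holds exactly per condition
        within = np.diag(gts.stationary_cov())
        total = np.atleast_1d(gts.state_sd) ** 2 + np.atleast_1d(gts.county_sd) ** 2 + within
        np.testing.assert_allclose(np.atleast_1d(gts.state_sd) ** 2 / total, 0.12, atol=1e-9)
        np.testing.assert_allclose(np.atleast_1d(gts.county_sd) ** 2 / total, 0.49, atol=1e-9)

    def test_text_roundtrip(self, spatial_gt):
        back = GroundTruth.from_text(spatial_gt.to_text())
        assert back.dag == spatial_gt.dag
        np.testing.assert_allclose(back.coefficient_matrix(), spatial_gt.coefficient_matrix())
        np.testing.assert_allclose(
            np.atleast_1d(back.county_sd), np.atleast_1d(spatial_gt.county_sd)
        )


class TestSimulatePanel:
    def _lag1_autocorr(self, panel):
        """Pooled lag-1 autocorrelation, demeaned by the global condition mean
        (valid here: the fixtures have no county-level baselines, so per-county
        demeaning would only add O(1/T) small-sample bias)."""
        out = []
        for c in panel.conditions:
            grand = panel.frame[c].mean()
            num = den = 0.0
            for _county, grp in panel.frame.groupby("county"):
                x = grp.sort_values("week")[c].to_numpy() - grand
                num += float(x[:-1] @ x[1:])
                den += float(x @ x)
            out.append(num / den)
        return np.array(out)

    def test_white_noise_truth_has_no_autocorrelation(self):
        gt = make_ground_truth(3, 0, 0, auto_range=(1e-6, 2e-6), seed=5)
        panel = simulate_panel(gt, 5, 10, 100, seed=6)
        assert np.all(np.abs(self._lag1_autocorr(panel)) < 0.05)

    def test_ar_08_truth_recovers_theoretical_autocorrelation(self):
        """With self-coefficient 0.8 and no cross arcs, rho(1) ~ 0.8."""
        gt = make_ground_truth(3, 0, 0, auto_range=(0.8, 0.8), seed=5)
        panel = simulate_panel(gt, 5, 10, 100, seed=6)
        assert np.all(np.abs(self._lag1_autocorr(panel) - 0.8) < 0.05)

    def test_bit_identical_given_seed(self, default_gt):
        a = simulate_panel(default_gt, 2, 3, 30, seed=9)
        b = simulate_panel(default_gt, 2, 3, 30, seed=9)
        assert a.frame.equals(b.frame)

    def test_values_nonnegative_and_clipping_negligible(self, spatial_panel):
        vals = spatial_panel.values
        assert np.all(vals >= 0)
        assert spatial_panel.clip_fraction < 0.001

    def test_stationarity_of_long_series(self, small_gt):
        """First- and second-half county means agree within 3 standard errors."""
        panel = simulate_panel(small_gt, 1, 2, 600, seed=13)
        for _county, grp in panel.frame.groupby("county"):
            for c in panel.conditions:
                x = grp.sort_values("week")[c].to_numpy()
                h1, h2 = x[:300], x[300:]
                se = np.sqrt(h1.var() / 30 + h2.var() / 30)  # ~10x autocorr inflation
                assert abs(h1.mean() - h2.mean()) < 3 * se

    def test_unstable_truth_refused(self):
        gt = make_ground_truth(2, 1, 0, seed=1)
        for c in gt.conditions:
            gt.params[c].coefficients[c] = 1.2
        with pytest.raises(Exception, match="spectral|magnitude"):
            simulate_panel(gt, 1, 2, 10, seed=0)


class TestInjectMissingness:
    def test_single_mode_hits_rate(self, small_panel):
        holed = inject_missingness(small_panel, 0.10, "single", seed=5)
        frac = holed.frame[holed.conditions].isna().to_numpy().mean()
        assert 0.095 <= frac <= 0.105

    def test_batch4_runs_have_length_four(self, small_panel):
        holed = inject_missingness(small_panel, 0.20, "batch4", seed=5)
        for _county, grp in holed.frame.groupby("county"):
            grp = grp.sort_values("week")
            for c in holed.conditions:
                miss = grp[c].isna().to_numpy()
                # maximal runs of missingness
                runs = []
                length = 0
                for i, m in enumerate(miss):
                    if m:
                        length += 1
                    elif length:
                        runs.append((i - length, length))
                        length = 0
                if length:
                    runs.append((len(miss) - length, length))
                for start, ln in runs:
                    truncated = start + ln == len(miss)
                    assert ln == 4 or (truncated and ln < 4)

    def test_batch4_hits_rate(self, small_panel):
        holed = inject_missingness(small_panel, 0.20, "batch4", seed=5)
        frac = holed.frame[holed.conditions].isna().to_numpy().mean()
        assert 0.195 <= frac <= 0.205

    def test_identical_masks_for_identical_seeds(self, small_panel):
        a = inject_missingness(small_panel, 0.02, "single", seed=5)
        b = inject_missingness(small_panel, 0.02, "single", seed=5)
        assert a.frame[a.conditions].isna().equals(b.frame[b.conditions].isna())

    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1, 1.5])
    def test_rate_outside_unit_interval_rejected(self, small_panel, rate):
        with pytest.raises(ParameterError):
            inject_missingness(small_panel, rate, "single", seed=0)
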