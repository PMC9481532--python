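"""Locked ensembles: upsampling, windows, latency, binned tests, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import arousalseq as aq
from arousalseq.core import (
    DegenerateSignalError,
    EmptyEnsembleError,
    InvalidConfigError,
    ROITimeseries,
    SampledSeries,
)
from arousalseq.hrf import HRFParams, model_values
from arousalseq.locked import LockedEnsemble


def _roi(values, tr=1.0, start=0.0):
    return ROITimeseries(name="roi", series=SampledSeries(values, start=start, dt=tr))


class TestUpsample:
    def test_factor_one_is_identity(self):
        roi = _roi([1.0, 2.0, 5.0])
        assert aq.upsample(roi, 1) is roi

    def test_linear_values(self):
        roi = _roi([0.0, 4.0], tr=1.0)
        up = aq.upsample(roi, 4)
        np.testing.assert_allclose(up.values, [0, 1, 2, 3, 4])
        assert up.series.dt == 0.25

    def test_original_grid_preserved_bit_exact(self):
        rng = np.random.default_rng(0)
        roi = _roi(rng.normal(size=50), tr=0.247)
        up = aq.upsample(roi, 4)
        assert np.array_equal(up.values[::4], roi.values)

    def test_up_then_down_is_identity(self):
        rng = np.random.default_rng(1)
        roi = _roi(rng.normal(size=30), tr=0.367)
        up = aq.upsample(roi, 3)
        down = up.values[::3]
        assert np.array_equal(down, roi.values)

    def test_invalid_factor_rejected(self):
        with pytest.raises(InvalidConfigError):
            aq.upsample(_roi([0, 1]), 0)


class TestExtractWindows:
    def test_on_grid_event_aligns_exactly(self):
        n = 400
        roi = _roi(np.arange(n, dtype=float), tr=0.25)
        ens = aq.extract_windows(roi, [50.0], pre=10, post=20)
        # event at sample 200; window starts 40 samples earlier
        assert ens.matrix[0, 0] == 160.0
        assert ens.times[0] == -10.0 and ens.times[-1] == 20.0

    def test_off_grid_event_snaps_to_nearest_sample(self):
        roi = _roi(np.arange(4000, dtype=float), tr=0.06175)
        ens = aq.extract_windows(roi, [100 * 0.06175 + 0.03], pre=1, post=1)
        # 0.03 s offset at 0.06175 s step rounds to sample 100... or 101
        center = ens.matrix[0, ens.times.size // 2]
        assert center in (100.0, 101.0)
        assert abs(center * 0.06175 - (100 * 0.06175 + 0.03)) <= 0.06175 / 2 + 1e-12

    def test_edge_events_dropped(self):
        roi = _roi(np.zeros(100), tr=1.0)
        ens = aq.extract_windows(roi, [5.0, 50.0], pre=10, post=20)
        assert ens.n_events == 1
        with pytest.raises(EmptyEnsembleError):
            aq.extract_windows(roi, [5.0], pre=10, post=20)

    def test_mean_peak_at_true_hrf_peak(self, noiseless_cohort):
        ens, truth = noiseless_cohort
        m = ens["mid"].matrix.mean(axis=0)
        t_peak = ens["mid"].times[np.argmax(m)]
        assert t_peak == pytest.approx(6.0, abs=2 * ens["mid"].step)


class TestBaselineCenter:
    def test_constant_rows_become_zero(self):
        times = np.arange(-10, 21, 1.0)
        ens = LockedEnsemble(np.full((3, times.size), 7.0), times)
        out = aq.baseline_center(ens)
        assert np.allclose(out.matrix, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        times = np.arange(-10, 21, 0.5)
        ens = LockedEnsemble(rng.normal(size=(5, times.size)), times)
        once = aq.baseline_center(ens)
        twice = aq.baseline_center(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-12)

    def test_window_means_are_zero(self):
        rng = np.random.default_rng(1)
        times = np.arange(-10, 21, 0.25)
        ens = aq.baseline_center(LockedEnsemble(rng.normal(size=(8, times.size)), times))
        mask = (times >= -10) & (times <= -7)
        np.testing.assert_allclose(ens.matrix[:, mask].mean(axis=1), 0.0, atol=1e-10)


class TestMeanSem:
    def test_identical_rows_zero_sem(self):
        times = np.arange(-10, 21, 1.0)
        ens = LockedEnsemble(np.tile(np.sin(times), (4, 1)), times)
        _, sem = aq.ensemble_mean_sem(ens)
        assert np.allclose(sem, 0.0)

    def test_two_row_hand_arithmetic(self):
        times = np.arange(3.0)
        ens = LockedEnsemble(np.array([[0.0, 0, 0], [2.0, 2, 2]]), times)
        m, sem = aq.ensemble_mean_sem(ens)
        np.testing.assert_allclose(m, 1.0)
        np.testing.assert_allclose(sem, 1.0)  # std([0,2], ddof=1)/sqrt(2) = 1

    def test_matches_column_oracle(self):
        rng = np.random.default_rng(2)
        times = np.arange(-10, 21, 0.5)
        mat = rng.normal(size=(12, times.size))
        m, sem = aq.ensemble_mean_sem(LockedEnsemble(mat, times))
        for j in range(times.size):
            col = mat[:, j]
            assert m[j] == pytest.approx(col.mean())
            assert sem[j] == pytest.approx(col.std(ddof=1) / np.sqrt(12))


class TestLatency20:
    def _axis(self, step=0.05):
        return np.arange(-10, 20 + step / 2, step)

    def test_linear_ramp_crosses_at_two_seconds(self):
        t = self._axis(0.001)
        y = np.clip(t / 10.0, 0, None)  # 0 until t=0, then ramp to 1 at t=10
        y[t > 10] = 1.0
        assert aq.latency20(y, t) == pytest.approx(2.0, abs=0.001)

    def test_step_function_latency_at_step(self):
        t = self._axis()
        y = (t >= 5.0).astype(float)
        assert aq.latency20(y, t) == pytest.approx(5.0, abs=0.05)

    def test_double_gaussian_matches_closed_form_crossing(self):
        from scipy.optimize import brentq

        params = HRFParams(a1=1.0, mu1=6.0, sigma1=2.0, a2=-0.4, mu2=13.0, sigma2=3.0)
        step = 0.06175
        t = np.arange(-10, 20 + step / 2, step)
        y = model_values(params, t)
        lat = aq.latency20(y, t)
        peak = np.max(y)
        # analytic 20% crossing by root-finding on the model itself
        root = brentq(lambda x: model_values(params, np.array([x]))[0] - 0.2 * peak,
                      -6.9, 6.0)
        assert lat == pytest.approx(root, abs=step)

    def test_negative_deflection_uses_absolute_polarity(self):
        t = self._axis()
        y = -np.exp(-0.5 * ((t - 8) / 2) ** 2)
        lat = aq.latency20(y, t, polarity="absolute")
        assert 0 < lat < 8

    def test_positive_polarity_rejects_pure_negative(self):
        t = self._axis()
        y = -np.exp(-0.5 * ((t - 8) / 2) ** 2)
        with pytest.raises(DegenerateSignalError):
            aq.latency20(y, t, polarity="positive")

    def test_flat_signal_degenerate(self):
        t = self._axis()
        with pytest.raises(DegenerateSignalError):
            aq.latency20(np.zeros_like(t), t)

    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-10.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, gain, offset):
        t = np.arange(-10, 20.01, 0.05)
        y = model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), t)
        base = aq.latency20(y, t)
        assert aq.latency20(gain * y + offset, t) == pytest.approx(base, abs=1e-9)


class TestBootstrapLatency:
    def _ens(self, jitter, n=20, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(-10, 20.01, 0.25)
        rows = np.stack([
            model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), times)
            + jitter * rng.normal(size=times.size) for _ in range(n)
        ])
        return LockedEnsemble(rows, times)

    def test_identical_rows_zero_width_ci(self):
        ens = self._ens(jitter=0.0)
        est = aq.bootstrap_latency(ens, n=200, seed=1)
        assert est.ci_lo == est.ci_hi == est.latency

    def test_deterministic_per_seed(self):
        ens = self._ens(jitter=0.3)
        a = aq.bootstrap_latency(ens, n=200, seed=42)
        b = aq.bootstrap_latency(ens, n=200, seed=42)
        assert (a.ci_lo, a.ci_hi, a.latency) == (b.ci_lo, b.ci_hi, b.latency)

    def test_ci_ordering(self):
        ens = self._ens(jitter=0.4, seed=3)
        est = aq.bootstrap_latency(ens, n=300, seed=3)
        assert est.ci_lo <= est.ci_hi


class TestBinnedTest:
    def _times(self):
        return np.arange(-10, 20.01, 0.25)

    def test_constant_offset_bin_significant(self):
        times = self._times()
        rng = np.random.default_rng(0)
        mat = rng.normal(0, 0.1, (20, times.size))
        mask = (times >= 5) & (times < 6)
        mat[:, mask] += 5.0
        res = aq.binned_test(LockedEnsemble(mat, times))
        i = np.argmin(np.abs(res["bin_centers"] - 5.5))
        assert res["significant"][i]

    def test_paired_identical_ensembles_nothing_significant(self):
        times = self._times()
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(10, times.size))
        ens = LockedEnsemble(mat, times)
        res = aq.binned_test(ens, other=ens)
        assert not res["significant"].any()

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(2)
        times = self._times()
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            mat = rng.normal(size=(15, times.size))
            res = aq.binned_test(LockedEnsemble(mat, times))
            hits += int(res["significant"].any())
        # familywise alpha 0.05 across 30 bins; binomial slack on 100 sims
        assert hits <= 10

    def test_unequal_rows_rejected_in_paired_mode(self):
        times = self._times()
        a = LockedEnsemble(np.zeros((4, times.size)), times)
        b = LockedEnsemble(np.zeros((5, times.size)), times)
        with pytest.raises(InvalidConfigError):
            aq.binned_test(a, other=b)


class TestPCAModes:
    def test_two_orthogonal_modes_explain_everything(self):
        times = np.arange(-10, 20.01, 0.25)
        m1 = np.sin(2 * np.pi * times / 30)
        m2 = np.cos(2 * np.pi * times / 30)
        means = np.vstack([m1, m2, m1 + 0.5 * m2])
        modes = aq.pca_modes(means, times, baseline_window=(-10, -7))
        assert modes.variance_fractions[:2].sum() == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_roi_single_mode(self):
        times = np.arange(-10, 20.01, 0.5)
        m = model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), times)
        modes = aq.pca_modes(np.vstack([m, m]), times)
        assert modes.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_match_covariance_eigen_oracle(self):
        rng = np.random.default_rng(3)
        times = np.arange(-10, 20.01, 0.5)
        means = rng.normal(size=(6, times.size))
        modes = aq.pca_modes(means, times)
        mask = (times >= -10) & (times <= -7)
        centered = means - means[:, mask].mean(axis=1, keepdims=True)
        eig = np.sort(np.linalg.eigvalsh(centered @ centered.T))[::-1]
        np.testing.assert_allclose(modes.variance_fractions, eig / eig.sum(), atol=1e-10)

    def test_fractions_sum_to_one_components_orthogonal(self):
        rng = np.random.default_rng(4)
        times = np.arange(-10, 20.01, 0.5)
        modes = aq.pca_modes(rng.normal(size=(5, times.size)), times)
        assert modes.variance_fractions.sum() == pytest.approx(1.0)
        gram = modes.components @ modes.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_single_roi_rejected(self):
        times = np.arange(-10, 20.01, 0.5)
        with pytest.raises(InvalidConfigError):
            aq.pca_modes(np.zeros((1, times.size)), times)
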