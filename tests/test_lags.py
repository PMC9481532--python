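"""Cross-correlation lags, bootstrap CIs, sequence, breathhold correction."""

import numpy as np
import pytest

import arousalseq as aq
from arousalseq.core import (
    DegenerateCorrelationError,
    InvalidConfigError,
    NoPositivePeakError,
)
from arousalseq.hrf import HRFParams, model_values
from arousalseq.locked import LockedEnsemble


def brute_force_xcorr(x, y, max_shift):
    """Exhaustive per-shift Pearson oracle (loops over shifts and samples)."""
    n = len(x)
    best = None
    for k in range(-max_shift, max_shift + 1):
        if k >= 0:
            xa, ya = x[k:], y[:n - k] if k else y
        else:
            xa, ya = x[:n + k], y[-k:]
        if np.std(xa) == 0 or np.std(ya) == 0:
            continue
        r = np.corrcoef(xa, ya)[0, 1]
        if best is None or r > best[1] + 1e-12 or (
                abs(r - best[1]) <= 1e-12 and (abs(k) < abs(best[0]) or
                                               (abs(k) == abs(best[0]) and k < best[0]))):
            best = (k, r)
    return best


def _bump(times, center, width=2.0):
    return np.exp(-0.5 * ((times - center) / width) ** 2)


class TestXcorrLag:
    def test_self_correlation_zero_lag_unit_r(self):
        t = np.arange(-10, 20.01, 0.25)
        x = _bump(t, 5.0)
        est = aq.xcorr_lag(x, x, step=0.25)
        assert est.lag == 0.0
        assert est.r == pytest.approx(1.0)

    def test_shifted_bump_recovers_shift(self):
        t = np.arange(-10, 20.01, 0.05)
        ref = _bump(t, 5.0)
        shifted = _bump(t, 5.5)  # ROI response 0.5 s later
        est = aq.xcorr_lag(shifted, ref, step=0.05)
        assert est.lag == pytest.approx(0.5, abs=0.05)

    def test_antisymmetry_on_smooth_unimodal_signals(self):
        t = np.arange(-10, 20.01, 0.05)
        a, b = _bump(t, 4.0), _bump(t, 5.2)
        ab = aq.xcorr_lag(a, b, step=0.05).lag
        ba = aq.xcorr_lag(b, a, step=0.05).lag
        assert ab == pytest.approx(-ba, abs=0.05)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = 120
        # smooth random pairs: cumulative sums of white noise, lightly smoothed
        kernel = np.hanning(9) / np.hanning(9).sum()
        x = np.convolve(np.cumsum(rng.normal(size=n)), kernel, mode="same")
        y = np.convolve(np.cumsum(rng.normal(size=n)), kernel, mode="same")
        est = aq.xcorr_lag(x, y, step=1.0, max_lag=30, refine=False)
        k, r = brute_force_xcorr(x, y, 30)
        assert est.lag == k
        assert est.r == pytest.approx(r, abs=1e-10)
        # sub-sample refinement stays within half a step of the grid argmax
        refined = aq.xcorr_lag(x, y, step=1.0, max_lag=30)
        assert abs(refined.lag - k) <= 0.5

    def test_zero_variance_degenerate(self):
        flat = np.zeros(100)
        with pytest.raises(DegenerateCorrelationError):
            aq.xcorr_lag(flat, flat, step=1.0)

    def test_positive_only_with_anticorrelated_signals(self):
        t = np.arange(-10, 20.01, 0.25)
        x = _bump(t, 5.0)
        with pytest.raises(NoPositivePeakError):
            aq.xcorr_lag(x - x.mean(), -(x - x.mean()), step=0.25, max_lag=0.5,
                         positive_only=True)

    def test_noiseless_grid_recovery_exact_to_one_step(self):
        """Across true lags in [-1.2, 1.2] s on the fast-fMRI upsampled grid,
        noiseless recovery is exact to one interpolated step."""
        step = 0.06175
        t = np.arange(-10, 20, step)
        ref = model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), t)
        for true_lag in np.arange(-1.2, 1.21, 0.3):
            x = model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), t - true_lag)
            est = aq.xcorr_lag(x, ref, step=step)
            assert est.lag == pytest.approx(true_lag, abs=step)


class TestBootstrapLags:
    def _ensembles(self, lags, n_events=15, noise=0.0, seed=0, subjects=None):
        rng = np.random.default_rng(seed)
        step = 0.247 / 4
        times = np.arange(-10, 20 + step / 2, step)
        out = {}
        for i, lag in enumerate(lags):
            base = model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), times - lag)
            rows = base + noise * rng.normal(size=(n_events, times.size))
            out[f"roi{i}"] = LockedEnsemble(rows, times, subjects=subjects)
        return out

    def test_identical_rows_zero_width_cis(self):
        ens = self._ensembles([-0.3, 0.0, 0.4])
        res = aq.bootstrap_lags(ens, n=100, seed=0)
        for est in res.values():
            assert est.ci_lo == est.ci_hi == est.lag

    def test_deterministic_per_seed(self):
        ens = self._ensembles([-0.3, 0.0, 0.4], noise=0.3, seed=1)
        a = aq.bootstrap_lags(ens, n=100, seed=5)
        b = aq.bootstrap_lags(ens, n=100, seed=5)
        assert all(a[k] == b[k] for k in a)

    def test_point_lags_recover_truth(self):
        ens = self._ensembles([-0.6, 0.0, 0.9], n_events=40, noise=0.2, seed=2)
        res = aq.bootstrap_lags(ens, n=100, seed=0)
        step = 0.247 / 4
        rel = {k: res[k].lag - res["roi1"].lag for k in res}
        assert rel["roi0"] == pytest.approx(-0.6, abs=3 * step)
        assert rel["roi2"] == pytest.approx(0.9, abs=3 * step)

    def test_hierarchical_requires_subject_ids(self):
        ens = self._ensembles([0.0, 0.3])
        with pytest.raises(InvalidConfigError):
            aq.hierarchical_bootstrap_lags(ens, n=10, seed=0)

    def test_hierarchical_single_subject_falls_back_to_flat(self):
        subjects = ("s0",) * 15
        ens = self._ensembles([0.0, 0.3], subjects=subjects, noise=0.2, seed=3)
        flat = aq.bootstrap_lags(ens, n=100, seed=9)
        hier = aq.hierarchical_bootstrap_lags(ens, n=100, seed=9)
        assert all(flat[k] == hier[k] for k in flat)

    def test_hierarchical_deterministic(self):
        subjects = tuple(f"s{i % 3}" for i in range(15))
        ens = self._ensembles([0.0, 0.3], subjects=subjects, noise=0.2, seed=4)
        a = aq.hierarchical_bootstrap_lags(ens, n=50, seed=1)
        b = aq.hierarchical_bootstrap_lags(ens, n=50, seed=1)
        assert all(a[k] == b[k] for k in a)

    def test_between_subject_jitter_widens_hierarchical_cis(self):
        specs = tuple(aq.ROISpec(name=f"r{i}", lag=l) for i, l in
                      enumerate([-0.5, 0.0, 0.5]))
        ens, _ = aq.make_locked_cohort(
            n_subjects=5, events_per_subject=8, roi_specs=specs,
            noise_std=0.15, seed=6, between_subject_lag_sd=0.25)
        flat = aq.bootstrap_lags(ens, n=200, seed=2)
        hier = aq.hierarchical_bootstrap_lags(ens, n=200, seed=2)
        flat_w = np.mean([e.ci_hi - e.ci_lo for e in flat.values()])
        hier_w = np.mean([e.ci_hi - e.ci_lo for e in hier.values()])
        assert hier_w > flat_w


class TestSequence:
    def test_range_arithmetic(self):
        ests = {k: aq.LagEstimate(roi=k, lag=l, r=1.0)
                for k, l in [("a", -1.0), ("b", 0.0), ("c", 1.1)]}
        seq = aq.sequence(ests)
        assert seq.order == ("a", "b", "c")
        assert seq.lag_range == pytest.approx(2.1)

    def test_all_equal_lags_zero_range(self):
        ests = [aq.LagEstimate(roi=k, lag=0.5, r=1.0) for k in "ab"]
        assert aq.sequence(ests).lag_range == 0.0

    def test_reference_lag_is_zero(self):
        t = np.arange(-10, 20.01, 0.0625)
        ref = model_values(HRFParams(a1=1.0, mu1=5.0, sigma1=2.0), t)
        assert aq.xcorr_lag(ref, ref, step=0.0625).lag == 0.0


class TestBreathholdCorrection:
    def test_zero_breathhold_lags_leave_arousal_lags(self):
        ar = {k: aq.LagEstimate(roi=k, lag=l, r=0.9)
              for k, l in [("a", -0.4), ("b", 0.7)]}
        bh = {k: aq.LagEstimate(roi=k, lag=0.0, r=0.9) for k in ar}
        out = aq.hemodynamic_correct(ar, bh)
        assert out["a"].lag == pytest.approx(-0.4)
        assert out["b"].lag == pytest.approx(0.7)

    def test_near_cancellation(self):
        ar = {"a": aq.LagEstimate(roi="a", lag=1.0, r=0.9)}
        bh = {"a": aq.LagEstimate(roi="a", lag=0.99, r=0.9)}
        assert aq.hemodynamic_correct(ar, bh)["a"].lag == pytest.approx(0.01)

    def test_roi_mismatch_raises(self):
        ar = {"a": aq.LagEstimate(roi="a", lag=1.0, r=0.9)}
        with pytest.raises(KeyError):
            aq.hemodynamic_correct(ar, {})

    def test_vascular_delays_cancel_end_to_end(self):
        """True neural lags 0 but vascular delays vary: corrected lags ~ 0."""
        delays = [0.0, 0.25, 0.5]
        specs = tuple(
            aq.ROISpec(name=f"r{i}", lag=d, vascular_delay=d)
            for i, d in enumerate(delays)
        )
        # arousal ensembles where the apparent lag IS the vascular delay
        ens_ar, _ = aq.make_locked_cohort(
            n_subjects=1, events_per_subject=10, roi_specs=specs, noise_std=0.0, seed=0)
        s_bh = aq.make_breathhold_session(
            aq.BreathholdConfig(n_cycles=4, rois=specs, noise_std=0.0, seed=0))
        ens_bh = {}
        for roi in s_bh.rois:
            up = aq.upsample(roi, 4)
            ens_bh[roi.name] = aq.extract_windows(up, s_bh.truth.release_times,
                                                  pre=20, post=20)
        ar = aq.bootstrap_lags(ens_ar, n=20, seed=0)
        bh = aq.breathhold_lags(ens_bh, n=20, seed=0)
        corrected = aq.hemodynamic_correct(ar, bh)
        step = 0.247 / 4
        for est in corrected.values():
            assert abs(est.lag) <= 2 * step
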