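import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dianasim as ds
from dianasim.analysis import ZeroVarianceError, process_voxels


def pipeline_oracle(trace):
    """Hand-rolled percent-change -> linear detrend -> cyclic smooth.

    Independent arithmetic: explicit least-squares line fit and an explicit
    circular convolution loop with the 3-tap sigma-1 Gaussian.
    """
    trace = np.asarray(trace, dtype=float)
    pct = 100.0 * (trace - trace.mean()) / trace.mean()
    n = pct.size
    t = np.arange(n, dtype=float)
    design = np.stack([np.ones(n), t], axis=1)
    coef, *_ = np.linalg.lstsq(design, pct, rcond=None)
    detr = pct - design @ coef
    w1 = np.exp(-0.5)
    w = np.array([w1, 1.0, w1]) / (1 + 2 * w1)
    out = np.empty(n)
    for i in range(n):
        out[i] = w[0] * detr[(i - 1) % n] + w[1] * detr[i] + w[2] * detr[(i + 1) % n]
    return out


class TestPercentChange:
    def test_constant_is_zero(self):
        assert np.allclose(ds.percent_change(np.full(10, 7.0)), 0.0)

    def test_alternating_closed_form(self):
        out = ds.percent_change(np.array([99.0, 101.0] * 5))
        assert np.allclose(out, np.array([-1.0, 1.0] * 5))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ds.percent_change(np.array([1.0, -3.0, 1.0]))

    def test_explicit_baseline(self):
        out = ds.percent_change(np.array([100.0, 102.0]), baseline=100.0)
        assert np.allclose(out, [0.0, 2.0])


class TestDetrend:
    def test_ramp_removed(self):
        assert np.allclose(ds.detrend_linear(np.arange(20.0)), 0.0, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ds.detrend_linear(np.array([1.0, 2.0]))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=5, max_size=50))
    def test_output_orthogonal_to_line(self, values):
        out = ds.detrend_linear(np.asarray(values))
        t = np.arange(out.size)
        assert abs(out.sum()) < 1e-7
        assert abs(np.dot(out, t)) < 1e-5

    def test_spike_preserved(self):
        """A spike on a ramp survives detrending up to the O(1/n) tilt.

        Oracle: explicit least-squares fit of the spike-plus-ramp series.
        """
        n = 40
        trace = 0.3 * np.arange(n) + np.eye(n)[25] * 5.0
        design = np.stack([np.ones(n), np.arange(n, dtype=float)], axis=1)
        coef, *_ = np.linalg.lstsq(design, trace, rcond=None)
        oracle = trace - design @ coef
        assert np.allclose(ds.detrend_linear(trace), oracle, atol=1e-10)
        assert ds.detrend_linear(trace)[25] == pytest.approx(5.0, rel=0.1)


class TestCyclicSmoothing:
    def test_constant_unchanged(self):
        assert np.allclose(ds.smooth_temporal_cyclic(np.full(12, 3.3)), 3.3)

    def test_impulse_kernel_weights(self):
        imp = np.zeros(9)
        imp[4] = 1.0
        out = ds.smooth_temporal_cyclic(imp)
        w0 = 1.0 / (1.0 + 2.0 * np.exp(-0.5))
        w1 = np.exp(-0.5) * w0
        assert out[4] == pytest.approx(w0)
        assert out[3] == pytest.approx(w1)
        assert out[5] == pytest.approx(w1)
        assert w0 == pytest.approx(0.4519, abs=2e-4)

    def test_impulse_at_edge_wraps(self):
        imp = np.zeros(9)
        imp[0] = 1.0
        out = ds.smooth_temporal_cyclic(imp)
        assert out[-1] == pytest.approx(out[1])
        assert out[-1] > 0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=4, max_size=40))
    def test_mean_preserved(self, values):
        arr = np.asarray(values)
        assert ds.smooth_temporal_cyclic(arr).mean() == pytest.approx(arr.mean(), abs=1e-9)


class TestTrialAverage:
    def test_noiseless_pipeline_matches_hand_oracle(self, phantom, rois, split, plan, params):
        """The full per-measurement pipeline reproduces explicit arithmetic
        on the 40-vector with a 0.5% two-frame response."""
        resp = ds.DianaResponse()
        meas = [
            ds.synthesize_measurement(split, plan, gamma=resp, parity="on")
            for _ in range(2)
        ]
        avg = ds.trial_average(meas, rois.active_mask, parity="on")
        raw = np.ones(params.n_timepoints)
        raw[ds.response_bins(resp, params)] = 1.005
        oracle = pipeline_oracle(raw)
        assert np.allclose(avg.mean_trace, oracle, atol=1e-9)
        assert np.allclose(avg.ci99, 0.0, atol=1e-9)

    def test_mean_baseline_attenuates_peak(self, params):
        """Two 0.5% frames against a 40-frame mean baseline give ~0.475%
        before smoothing; the hand oracle quantifies the pipeline value."""
        resp = ds.DianaResponse()
        raw = np.ones(params.n_timepoints)
        raw[ds.response_bins(resp, params)] = 1.005
        pct = 100.0 * (raw - raw.mean()) / raw.mean()
        expected = 0.5 * (1 - 2 / 40) / (1 + 0.005 * 2 / 40)
        assert pct.max() == pytest.approx(expected, abs=1e-6)
        assert pct.max() == pytest.approx(0.4749, abs=1e-3)

    def test_noise_only_mean_within_ci_of_zero(self, split, plan, rois, noise):
        rng = np.random.default_rng(21)
        meas = (
            ds.synthesize_measurement(split, plan, noise=noise, parity="off", rng=rng)
            for _ in range(60)
        )
        avg = ds.trial_average(meas, rois.active_mask)
        covered = np.abs(avg.mean_trace) <= avg.ci99
        assert covered.mean() >= 0.95  # 99% CI coverage, Monte-Carlo slack

    def test_empty_roi_rejected(self, split, plan):
        with pytest.raises(ValueError, match="ROI"):
            ds.trial_average([], np.zeros((80, 80), dtype=bool))


class TestLongTimescale:
    def _block_scan(self, mini, p2p=0.011):
        beta = ds.HemodynamicModel(kind="block", peak_to_peak=p2p,
                                   block_s=mini["params"].measurement_s)
        exp = ds.experiment_bookkeeping(2, mini["params"])
        return ds.simulate_experiment(mini["split"], mini["plan"], exp, beta=beta, seed=0)

    def test_block_step_recovered(self, mini):
        meas = self._block_scan(mini)
        course = ds.long_timescale_course(
            meas, mini["rois"].active_mask, mini["rois"].control_mask,
            n_meas_per_scan=8,
        )
        assert course.block_amplitude() == pytest.approx(1.1, abs=1e-9)

    def test_drift_free_scan_unchanged(self, mini):
        meas = self._block_scan(mini, p2p=0.0)
        course = ds.long_timescale_course(
            meas, mini["rois"].active_mask, mini["rois"].control_mask, n_meas_per_scan=8
        )
        assert np.abs(course.active_pct).max() < 1e-9

    def test_degree6_drift_removed(self):
        """Multiplicative degree-6 drift common to both ROIs is fitted on the
        control trace and removed from the active trace to machine precision."""
        n = 320
        x = np.linspace(-1, 1, n)
        drift = 1.0 + 0.01 * (x**6 - 0.5 * x**3 + 0.2 * x)
        active = 100.0 * drift * 2.0
        control = 50.0 * drift * 2.0
        a_pct = ds.percent_change(active)
        c_pct = ds.percent_change(control)
        a_out, c_out = ds.detrend_polynomial(a_pct, c_pct, degree=6)
        assert np.abs(a_out).max() < 1e-8 * np.abs(a_pct).max()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            ds.detrend_polynomial(np.ones(5), np.ones(5), degree=6)


class TestTsnr:
    def test_alternating_closed_form(self):
        trace = np.array([99.0, 101.0] * 20)
        # mean 100, sample std sqrt(40/39)
        assert ds.tsnr(trace) == pytest.approx(100.0 / np.sqrt(40.0 / 39.0))
        assert ds.tsnr(trace) == pytest.approx(98.74, abs=0.01)

    def test_constant_trace_undefined(self):
        with pytest.raises(ZeroVarianceError):
            ds.tsnr(np.full(40, 5.0))

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        trace = 10.0 + rng.standard_normal(40)
        assert ds.tsnr(c * trace) == pytest.approx(ds.tsnr(trace), rel=1e-9)


class TestTsnrVsN:
    def test_full_pool_equals_grand_average(self):
        rng = np.random.default_rng(5)
        pool = 100.0 + rng.standard_normal((12, 40))
        table = ds.tsnr_vs_n(pool, [12], seed=0)
        assert table["tsnr_mean"].iloc[0] == pytest.approx(ds.tsnr(pool.mean(axis=0)))
        # draws differ only in summation order of the same 12 traces
        assert table["tsnr_std"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_n_exceeding_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            ds.tsnr_vs_n(np.ones((4, 40)) + np.random.default_rng(0).normal(size=(4, 40)), [5])

    def test_n1_matches_pool_mean(self):
        rng = np.random.default_rng(6)
        pool = 100.0 + rng.standard_normal((50, 40))
        table = ds.tsnr_vs_n(pool, [1], n_draws=80, seed=1)
        individual = [ds.tsnr(t) for t in pool]
        assert table["tsnr_mean"].iloc[0] == pytest.approx(
            np.mean(individual), rel=3 * np.std(individual) / np.sqrt(80) / np.mean(individual)
        )


class TestContrastMap:
    def test_block_step_separates_roi_support(self, mini):
        """A block step confined to the ROI dominates the t map: every ROI
        voxel is suprathreshold and false positives stay near the t tail."""
        beta = ds.HemodynamicModel(kind="block", peak_to_peak=0.05,
                                   block_s=mini["params"].measurement_s)
        exp = ds.experiment_bookkeeping(3, mini["params"])
        meas = ds.simulate_experiment(
            mini["split"], mini["plan"], exp, beta=beta,
            noise=ds.NoiseModel(sigma=0.001), seed=0,
        )
        t_map, mask = ds.on_off_contrast_map(meas)
        roi = mini["rois"].active_mask
        assert mask[roi].all()
        p_tail = stats.t.sf(2.5, len(meas) - 2)
        assert mask[~roi].mean() < 3 * p_tail + 2 / (~roi).sum()

    def test_antisymmetric_under_parity_swap(self, mini, noise):
        exp = ds.experiment_bookkeeping(1, mini["params"])
        meas = ds.simulate_experiment(
            mini["split"], mini["plan"], exp, noise=ds.NoiseModel(sigma=0.01), seed=2
        )
        t_map, _ = ds.on_off_contrast_map(meas)
        for m in meas:
            m.parity = "on" if m.parity == "off" else "off"
        t_swapped, _ = ds.on_off_contrast_map(meas)
        assert np.allclose(t_map, -t_swapped, atol=1e-10)

    def test_null_suprathreshold_fraction_matches_t_tail(self, phantom, split, plan, noise):
        """Pure-noise t-map: suprathreshold fraction near the t tail mass."""
        n_per = 24
        rng = np.random.default_rng(31)
        meas = []
        for i in range(2 * n_per):
            m = ds.synthesize_measurement(split, plan, noise=noise,
                                          parity="on" if i % 2 else "off", rng=rng)
            meas.append(m)
        t_map, mask = ds.on_off_contrast_map(meas)
        brain = phantom.image > 0.1 * phantom.image.max()
        frac = mask[brain].mean()
        p = stats.t.sf(2.5, 2 * n_per - 2)
        n_vox = brain.sum()
        tol = 4 * np.sqrt(p * (1 - p) / n_vox)
        assert frac == pytest.approx(p, abs=tol + 0.5 * p)

    def test_single_parity_rejected(self, mini):
        exp = ds.experiment_bookkeeping(1, mini["params"])
        meas = ds.simulate_experiment(mini["split"], mini["plan"], exp, seed=0)
        only_off = [m for m in meas if m.parity == "off"]
        with pytest.raises(ValueError, match="both"):
            ds.on_off_contrast_map(only_off)


class TestDetection:
    def test_monotone_in_n(self, split, plan, rois, noise):
        """Detection rate is non-decreasing in averaging depth."""
        table = ds.detectability_study(
            split, plan, [0.005], [4, 16], noise, rois.active_mask, n_seeds=10, seed=5
        )
        rates = table.sort_values("n_measurements")["detection_rate"].to_numpy()
        assert rates[0] <= rates[1]

    def test_zero_amplitude_rarely_detected(self, split, plan, rois, noise):
        table = ds.detectability_study(
            split, plan, [0.0], [16], noise, rois.active_mask, n_seeds=10, seed=6
        )
        assert table["detection_rate"].iloc[0] <= 0.1
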