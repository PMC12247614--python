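"""The three time-dependent terms of the k-space mixture model.

Every synthetic readout is ``k_rest + beta(t) * gamma(t) * k_active + noise``:

* ``gamma`` — the putative direct neuronal response: a brief multiplicative
  signal increase (default 0.5% for 10 ms, starting 50 ms after the stimulus
  ends), present only on stimulus-on measurements.
* ``beta`` — the hemodynamic background: constant, sinusoidal (0.5% peak-to-
  peak at 0.5/1/5 Hz), a square-wave on/off block, an HRF-convolved block
  paradigm, or an externally supplied coarse trace.  Coarse traces are
  low-pass filtered (5-tap Gaussian) and spline-interpolated to the 5 ms
  readout resolution before use.
* ``noise`` — additive circular complex Gaussian noise per k-space sample,
  calibrated so the reconstructed stimulus-off series reaches a target
  ROI-mean temporal SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .phantom import Phantom, ROISet
from .schedule import SamplingPlan, SequenceParams

BETA_KINDS = ("constant", "sinusoid", "block", "block_hrf", "resampled_trace")


@dataclass(frozen=True)
class DianaResponse:
    """Brief multiplicative signal increase locked to the stimulus.

    ``amplitude`` is fractional (0.005 = 0.5%).  The response occupies
    ``[stim_end + onset_after_stim_end, + duration)`` within the trial and is
    applied only on stimulus-on measurements.
    """

    amplitude: float = 0.005
    onset_after_stim_end_ms: float = 50.0
    duration_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")

    def window_ms(self, params: SequenceParams) -> tuple[float, float]:
        start = params.stim_end_ms + self.onset_after_stim_end_ms
        stop = start + self.duration_ms
        if stop > params.trial_ms:
            raise ValueError("response window extends past the trial")
        return start, stop


def gamma_eval(
    resp: DianaResponse | None,
    t_in_trial_ms: np.ndarray | float,
    params: SequenceParams,
    parity: str,
) -> np.ndarray:
    """Evaluate the neuronal response factor at within-trial times (ms)."""
    t = np.asarray(t_in_trial_ms, dtype=float)
    if parity not in ("on", "off"):
        raise ValueError("parity must be 'on' or 'off'")
    out = np.ones_like(t)
    if resp is None or parity == "off" or resp.amplitude == 0:
        return out
    start, stop = resp.window_ms(params)
    out[(t >= start) & (t < stop)] += resp.amplitude
    return out


def response_bins(resp: DianaResponse, params: SequenceParams) -> np.ndarray:
    """TR bins (0-based, keyed by bin start time) covered by the response."""
    start, stop = resp.window_ms(params)
    t = np.arange(params.n_timepoints) * params.tr_ms
    return np.nonzero((t >= start) & (t < stop))[0]


# ---------------------------------------------------------------------------
# Hemodynamic background

def gaussian_filter_coarse(trace: np.ndarray, width: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Normalized ``width``-tap Gaussian smoothing with reflective boundaries."""
    half = width // 2
    k = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (k / sigma) ** 2)
    w /= w.sum()
    return ndimage.correlate1d(np.asarray(trace, dtype=float), w, mode="reflect")


def double_gamma_hrf(t_s: np.ndarray, peak_s: float = 2.5, undershoot_ratio: float = 0.2) -> np.ndarray:
    """Gamma-variate HRF with a late undershoot; unit peak, rodent-fast."""
    shape = 5.0
    scale = peak_s / (shape - 1.0)
    t = np.asarray(t_s, dtype=float)
    g1 = np.where(t > 0, (t / scale) ** (shape - 1) * np.exp(-(t - peak_s) / scale), 0.0)
    g1 = np.where(t > 0, g1 * np.exp(-peak_s / scale) * np.exp(peak_s / scale), g1)
    scale2 = 3 * scale
    peak2 = (shape - 1) * scale2
    g2 = np.where(t > 0, (t / scale2) ** (shape - 1) * np.exp(-(t - peak2) / scale2), 0.0)
    h = g1 / g1.max() - undershoot_ratio * (g2 / g2.max() if g2.max() > 0 else g2)
    return h


@dataclass(eq=False)
class HemodynamicModel:
    """Multiplicative hemodynamic background ``beta(t)``.

    Kinds
    -----
    constant
        ``beta = 1`` (noise-only studies).
    sinusoid
        ``1 + p2p/2 * sin(2 pi f t + phase)``; phase drawn once per scan.
    block
        Square wave synchronized with measurement parity: 1 during
        stimulus-off measurements, ``1 + p2p`` during stimulus-on blocks.
    block_hrf
        Measurement-parity boxcar convolved with a gamma-variate HRF
        (peak ~2.5 s, 0.2 undershoot), optional slow oscillation, rescaled
        to the requested peak-to-peak; sampled at 0.4 s and then resampled
        like a measured trace.
    resampled_trace
        User-supplied coarse trace (default 0.4 s sampling): 5-tap Gaussian
        filtered, cubic-spline interpolated to readout resolution, rescaled
        to the requested peak-to-peak around 1.
    """

    kind: str = "constant"
    peak_to_peak: float = 0.005
    frequency_hz: float | None = None
    trace: np.ndarray | None = None
    trace_dt_s: float = 0.4
    block_s: float = 16.0
    duration_s: float = 128.0
    osc_hz: float = 0.2
    osc_frac: float = 0.0
    _spline: CubicSpline | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in BETA_KINDS:
            raise ValueError(f"unknown background kind {self.kind!r}")
        if self.peak_to_peak < 0:
            raise ValueError("peak_to_peak must be >= 0")
        if self.kind == "sinusoid" and (self.frequency_hz is None or self.frequency_hz < 0):
            raise ValueError("sinusoid background needs a frequency >= 0")
        if self.kind == "resampled_trace" and self.trace is None:
            raise ValueError("resampled_trace background needs a trace")

    # -- coarse trace construction -------------------------------------
    def _coarse(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "resampled_trace":
            x = np.asarray(self.trace, dtype=float)
            dt = self.trace_dt_s
        else:  # block_hrf
            dt = self.trace_dt_s
            t = np.arange(0.0, self.duration_s, dt)
            boxcar = ((t // self.block_s).astype(int) % 2).astype(float)
            h = double_gamma_hrf(np.arange(0.0, 6 * self.block_s, dt))
            h = h / h.sum()
            x = np.convolve(boxcar, h)[: t.size]
            if self.osc_frac > 0:
                x = x + self.osc_frac * (x.max() - x.min()) * np.sin(2 * np.pi * self.osc_hz * t)
        span = x.max() - x.min()
        if span > 0:
            x = 1.0 + (x - 0.5 * (x.max() + x.min())) * (self.peak_to_peak / span)
        else:
            x = np.ones_like(x)
        return np.arange(x.size) * dt, x

    def _get_spline(self) -> tuple[CubicSpline, float]:
        if self._spline is None:
            t, x = self._coarse()
            self._spline = CubicSpline(t, gaussian_filter_coarse(x), bc_type="not-a-knot")
            self._period = float(t.size * (t[1] - t[0]))
        return self._spline, self._period

    def resampled(self, dt_fine_s: float = 0.005) -> tuple[np.ndarray, np.ndarray]:
        """Filtered + spline-resampled background at fine resolution."""
        spline, period = self._get_spline()
        t = np.arange(0.0, period, dt_fine_s)
        return t, spline(t)


def beta_eval(
    model: HemodynamicModel | None,
    t_abs_s: np.ndarray | float,
    scan_phase: float = 0.0,
) -> np.ndarray:
    """Evaluate the background factor at absolute times (s from scan start)."""
    t = np.asarray(t_abs_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("absolute time must be >= 0")
    if model is None or model.kind == "constant":
        return np.ones_like(t)
    if model.kind == "sinusoid":
        out = 1.0 + 0.5 * model.peak_to_peak * np.sin(
            2 * np.pi * model.frequency_hz * t + scan_phase
        )
    elif model.kind == "block":
        # epsilon guards block-boundary rounding (readouts are ms apart)
        on = np.floor(t / model.block_s + 1e-9).astype(int) % 2
        out = 1.0 + model.peak_to_peak * on
    else:
        spline, period = model._get_spline()
        out = spline(np.mod(t, period))
    if np.any(out <= 0):
        raise ValueError("background factor must stay positive")
    return out


# ---------------------------------------------------------------------------
# Noise

@dataclass(frozen=True)
class NoiseModel:
    """Circular complex Gaussian k-space noise.

    ``sigma`` is the standard deviation of the real and imaginary parts of
    each k-space sample (under the orthonormal FT this is also the per-voxel
    image-component noise std).
    """

    sigma: float
    target_tsnr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def calibrate_noise_sigma(
    target_tsnr: float,
    phantom: Phantom,
    roi: ROISet,
    plan: SamplingPlan,
    seed: int = 0,
    n_replicates: int = 200,
    tol: float = 0.015,
    max_iter: int = 6,
) -> NoiseModel:
    """Find sigma so stimulus-off measurements reach a target ROI-mean tSNR.

    Starts from the high-SNR analytic guess ``sigma = roi_mean * sqrt(V) /
    tSNR`` (ROI averaging suppresses independent voxel noise by sqrt(V)),
    then refines by Monte-Carlo: simulate ``n_replicates`` off-parity
    measurements through the full synthesis + reconstruction path, measure
    the mean tSNR of the ROI-averaged series, and rescale sigma by the
    achieved/target ratio until within ``tol``.
    """
    from .analysis import tsnr
    from .engine import synthesize_measurement
    from .phantom import split_kspace

    if target_tsnr <= 0:
        raise ValueError("target tSNR must be positive")
    split = split_kspace(phantom, roi)
    roi_mean = float(phantom.image[roi.active_mask].mean())
    n_vox = roi.n_active
    sigma = roi_mean * np.sqrt(n_vox) / target_tsnr

    rng = np.random.default_rng(seed)
    achieved = np.nan
    for _ in range(max_iter):
        vals = []
        for _ in range(n_replicates):
            meas = synthesize_measurement(
                split, plan, gamma=None, beta=None,
                noise=NoiseModel(sigma=sigma),
                parity="off", rng=rng, keep_kspace=False,
            )
            trace = meas.images[:, roi.active_mask].mean(axis=1)
            vals.append(tsnr(trace))
        achieved = float(np.mean(vals))
        if abs(achieved / target_tsnr - 1.0) <= tol:
            break
        sigma *= achieved / target_tsnr
    return NoiseModel(sigma=sigma, target_tsnr=target_tsnr, seed=seed)
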