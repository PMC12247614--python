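"""Time-series processing: percent change, detrending, temporal smoothing,
trial averaging with confidence intervals, tSNR and its sqrt-N bootstrap,
on/off contrast maps, and the detectability study.

The per-measurement pipeline order is fixed: percent signal change (around
the within-measurement mean), linear detrend, cyclic 3-tap Gaussian temporal
smoothing, then ROI averaging; trial statistics (mean and 99% CI of the
mean) are computed across measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .engine import SyntheticMeasurement


class ZeroVarianceError(ValueError):
    """Raised when tSNR is requested for a temporally constant series."""


def percent_change(series: np.ndarray, axis: int = -1, baseline: np.ndarray | float | None = None) -> np.ndarray:
    """Convert a time series to percent signal change.

    The baseline defaults to the within-series mean along ``axis``; pass an
    explicit ``baseline`` to reference a known ground-truth level instead.
    """
    s = np.asarray(series, dtype=float)
    if baseline is None:
        m = s.mean(axis=axis, keepdims=True)
    else:
        m = np.asarray(baseline, dtype=float)
    if np.any(m <= 0):
        raise ValueError("baseline mean must be strictly positive")
    return 100.0 * (s - m) / m


def detrend_linear(trace: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares straight line along ``axis``."""
    t = np.asarray(trace, dtype=float)
    if t.shape[axis] < 3:
        raise ValueError("need at least 3 points to detrend")
    return signal.detrend(t, axis=axis, type="linear")


# 3-tap Gaussian, sigma = 1 sample: weights ~ [e^-1/2, 1, e^-1/2]
_SMOOTH_KERNEL = np.exp(-0.5 * np.array([1.0, 0.0, 1.0]))
_SMOOTH_KERNEL = _SMOOTH_KERNEL / _SMOOTH_KERNEL.sum()


def smooth_temporal_cyclic(trace: np.ndarray, axis: int = -1) -> np.ndarray:
    """Circular convolution with the normalized 3-tap Gaussian (sigma 1)."""
    t = np.asarray(trace, dtype=float)
    if t.shape[axis] < _SMOOTH_KERNEL.size:
        raise ValueError("trace shorter than the smoothing kernel")
    return ndimage.convolve1d(t, _SMOOTH_KERNEL, axis=axis, mode="wrap")


def process_voxels(images: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Full per-voxel pipeline for one measurement, then ROI average.

    ``images`` is ``(T, ny, nx)``; returns the 40-point percent trace.
    """
    vox = images[:, mask].T  # (V, T)
    vox = percent_change(vox, axis=-1)
    vox = detrend_linear(vox, axis=-1)
    vox = smooth_temporal_cyclic(vox, axis=-1)
    return vox.mean(axis=0)


@dataclass(frozen=True)
class TrialAverage:
    """Across-measurement mean percent trace with 99% CI half-widths."""

    mean_trace: np.ndarray
    ci99: np.ndarray
    n_measurements: int
    parity: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint": np.arange(self.mean_trace.size),
                "mean_pct": self.mean_trace,
                "ci99_halfwidth": self.ci99,
            }
        )


def trial_average(
    measurements: Iterable[SyntheticMeasurement],
    mask: np.ndarray,
    parity: str | None = None,
) -> TrialAverage:
    """Trial-averaged ROI percent-change trace across measurements.

    Each measurement is processed voxel-wise (percent change, linear
    detrend, cyclic smoothing) and ROI-averaged; the mean and the 99%
    Student-t confidence interval of the mean are taken across measurements.
    Measurements of the other parity are skipped when ``parity`` is given.
    """
    if not np.asarray(mask).any():
        raise ValueError("empty ROI")
    traces = [
        process_voxels(m.images, mask)
        for m in measurements
        if parity is None or m.parity == parity
    ]
    if len(traces) < 2:
        raise ValueError("need at least 2 measurements for a CI")
    arr = np.asarray(traces)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
    ci99 = stats.t.ppf(0.995, n - 1) * sem
    return TrialAverage(mean_trace=mean, ci99=ci99, n_measurements=n, parity=parity)


# ---------------------------------------------------------------------------
# Long-timescale (whole-scan) course

@dataclass(frozen=True)
class LongTimescaleCourse:
    """Scan-averaged percent traces after control-ROI polynomial detrending."""

    time_s: np.ndarray
    active_pct: np.ndarray
    control_pct: np.ndarray
    n_scans: int
    n_meas_per_scan: int

    def block_amplitude(self) -> float:
        """On-block elevation (%) relative to the off-block baseline.

        Off blocks are odd-numbered measurements.  Computed so that a pure
        multiplicative step of ``d`` percent is recovered exactly.
        """
        n_tp = self.active_pct.size // self.n_meas_per_scan
        meas_idx = np.arange(self.active_pct.size) // n_tp
        on = meas_idx % 2 == 1
        m_on = self.active_pct[on].mean()
        m_off = self.active_pct[~on].mean()
        return (m_on - m_off) / (1.0 + m_off / 100.0)


def detrend_polynomial(
    active_pct: np.ndarray, control_pct: np.ndarray, degree: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a polynomial to the control trace; subtract it from both traces.

    Models slow instrumental drift (e.g. shim heating) common to both ROIs;
    block-structured functional signal in the active ROI is untouched
    because the fit uses only the control data.
    """
    a = np.asarray(active_pct, dtype=float)
    c = np.asarray(control_pct, dtype=float)
    if a.size != c.size:
        raise ValueError("traces must have equal length")
    if a.size < degree + 1:
        raise ValueError("fewer points than polynomial degree + 1")
    x = np.linspace(-1.0, 1.0, a.size)
    coeffs = np.polynomial.polynomial.polyfit(x, c, degree)
    fit = np.polynomial.polynomial.polyval(x, coeffs)
    return a - fit, c - fit


def long_timescale_course(
    measurements: Iterable[SyntheticMeasurement],
    active_mask: np.ndarray,
    control_mask: np.ndarray,
    n_meas_per_scan: int = 8,
    degree: int = 6,
    frame_dt_s: float = 0.4,
) -> LongTimescaleCourse:
    """Whole-scan signal course in both ROIs, drift-corrected and averaged.

    Per scan: concatenate the per-frame ROI means of its measurements
    (8 x 40 points spanning 128 s), convert each ROI trace to percent change
    around its scan mean, fit a degree-6 polynomial to the *control* trace,
    subtract that fit from both, then average across scans.
    """
    active_scans: list[np.ndarray] = []
    control_scans: list[np.ndarray] = []
    buf_a: list[np.ndarray] = []
    buf_c: list[np.ndarray] = []
    for m in measurements:
        buf_a.append(m.roi_trace(active_mask))
        buf_c.append(m.roi_trace(control_mask))
        if len(buf_a) == n_meas_per_scan:
            a = percent_change(np.concatenate(buf_a))
            c = percent_change(np.concatenate(buf_c))
            a, c = detrend_polynomial(a, c, degree=degree)
            active_scans.append(a)
            control_scans.append(c)
            buf_a, buf_c = [], []
    if not active_scans:
        raise ValueError("no complete scan supplied")
    a = np.mean(active_scans, axis=0)
    c = np.mean(control_scans, axis=0)
    # each frame spans measurement_duration / n_timepoints (0.4 s by default)
    time_s = np.arange(a.size, dtype=float) * frame_dt_s
    return LongTimescaleCourse(
        time_s=time_s,
        active_pct=a,
        control_pct=c,
        n_scans=len(active_scans),
        n_meas_per_scan=n_meas_per_scan,
    )


# ---------------------------------------------------------------------------
# tSNR

def tsnr(trace: np.ndarray) -> float:
    """Temporal SNR: mean over sample standard deviation (ddof 1)."""
    t = np.asarray(trace, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    sd = t.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("temporal variance is zero; tSNR undefined")
    return float(t.mean() / sd)


def tsnr_vs_n(
    traces: np.ndarray,
    n_values: Sequence[int],
    n_draws: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean tSNR of N-measurement averages via random combinations.

    ``traces`` is the pool of raw ROI-mean traces, shape ``(pool, T)``.  For
    each N, ``n_draws`` random N-subsets are drawn (without replacement
    within a subset), their traces averaged, and the tSNR of each average
    computed; the table reports the mean and std over draws.
    """
    pool = np.asarray(traces, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        if n > pool.shape[0]:
            raise ValueError(f"N={n} exceeds pool size {pool.shape[0]}")
        vals = []
        for _ in range(n_draws):
            idx = rng.choice(pool.shape[0], size=n, replace=False)
            vals.append(tsnr(pool[idx].mean(axis=0)))
        rows.append({"n": n, "tsnr_mean": np.mean(vals), "tsnr_std": np.std(vals, ddof=1) if len(vals) > 1 else 0.0})
    return pd.DataFrame(rows)


def tsnr_loglog_slope(table: pd.DataFrame) -> float:
    """Slope of log tSNR vs log N (0.5 for white temporal noise)."""
    return float(np.polyfit(np.log(table["n"]), np.log(table["tsnr_mean"]), 1)[0])


# ---------------------------------------------------------------------------
# On/off contrast maps

def on_off_contrast_map(
    measurements: Iterable[SyntheticMeasurement], threshold: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise two-sample t map between stimulus-on and -off measurements.

    Each measurement contributes its temporal-mean image; the statistic is a
    pooled-variance two-sample t (on minus off), thresholded at
    ``t >= threshold`` with no smoothing or clustering.
    """
    on_imgs, off_imgs = [], []
    for m in measurements:
        (on_imgs if m.parity == "on" else off_imgs).append(m.images.mean(axis=0))
    if not on_imgs or not off_imgs:
        raise ValueError("need both stimulus-on and stimulus-off measurements")
    t_map, _ = stats.ttest_ind(np.asarray(on_imgs), np.asarray(off_imgs), axis=0, equal_var=True)
    t_map = np.nan_to_num(t_map, nan=0.0)
    return t_map, t_map >= threshold


# ---------------------------------------------------------------------------
# Detectability

def detect_response(avg: TrialAverage, resp_bins: np.ndarray, guard: int = 1) -> bool:
    """Peak-visibility criterion for a trial-averaged trace.

    Detected iff the mean trace at the known response bins exceeds the
    maximum 99%-CI upper envelope of all baseline bins (response bins plus a
    ``guard``-bin margin excluded, since smoothing leaks into neighbours).
    """
    T = avg.mean_trace.size
    excluded = set()
    for b in resp_bins:
        for g in range(-guard, guard + 1):
            excluded.add((b + g) % T)
    base = np.array([i for i in range(T) if i not in excluded])
    peak = avg.mean_trace[resp_bins].max()
    envelope = (avg.mean_trace[base] + avg.ci99[base]).max()
    return bool(peak > envelope)


def detectability_study(
    split,
    plan,
    amplitudes: Sequence[float],
    n_measurements: Sequence[int],
    noise,
    mask: np.ndarray,
    n_seeds: int = 20,
    seed: int = 0,
    onset_after_stim_end_ms: float = 50.0,
    duration_ms: float = 10.0,
) -> pd.DataFrame:
    """Detection rate of a brief response vs amplitude and averaging depth.

    For each (amplitude, N) cell and each replicate seed, N stimulus-on
    measurements are synthesized with calibrated noise, trial-averaged
    through the standard pipeline, and tested with :func:`detect_response`.
    """
    from .engine import synthesize_measurement
    from .signal_models import DianaResponse, response_bins

    params = plan.params
    rows = []
    for amp in amplitudes:
        resp = DianaResponse(
            amplitude=amp,
            onset_after_stim_end_ms=onset_after_stim_end_ms,
            duration_ms=duration_ms,
        ) if amp > 0 else None
        ref = DianaResponse(
            amplitude=max(amp, 1e-3),
            onset_after_stim_end_ms=onset_after_stim_end_ms,
            duration_ms=duration_ms,
        )
        bins = response_bins(ref, params)
        for n in n_measurements:
            hits = 0
            for k in range(n_seeds):
                rng = np.random.default_rng(np.random.SeedSequence((seed, int(amp * 1e6), n, k)))
                meas = (
                    synthesize_measurement(
                        split, plan, gamma=resp, beta=None, noise=noise,
                        parity="on", rng=rng,
                    )
                    for _ in range(n)
                )
                avg = trial_average(meas, mask, parity="on")
                hits += detect_response(avg, bins)
            rows.append(
                {"amplitude_pct": 100 * amp, "n_measurements": n, "detection_rate": hits / n_seeds}
            )
    return pd.DataFrame(rows)
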