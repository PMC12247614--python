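"""Line-by-line k-space synthesis and reconstruction.

For trial ``n`` (acquiring phase-encode row ``line_order[n]``) and
within-trial timepoint ``t``, the synthetic readout is

    k[t, row, :] = k_rest[row, :] + beta(t_abs) * gamma(t) * k_active[row, :] + noise

with ``beta`` evaluated at the absolute acquisition time of that readout
(5 ms resolution) and ``gamma`` depending only on the within-trial time.
Frames are reconstructed with the centered orthonormal inverse FFT and
magnitude is taken, as in-vivo pipelines do.

Because ``gamma`` is constant across all lines of a frame, a noiseless
constant-background measurement reconstructs *exactly* to
``rest_image + gamma(t) * roi_image``; image ghosting can only arise from
trial-to-trial (i.e. line-to-line) variation of ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .phantom import KSpaceSplit
from .schedule import ExperimentPlan, SamplingPlan
from .signal_models import DianaResponse, HemodynamicModel, NoiseModel, beta_eval, gamma_eval


@dataclass
class SyntheticMeasurement:
    """One reconstructed 40-frame measurement.

    ``images`` has shape ``(n_timepoints, n_pe, n_ro)`` (magnitude);
    ``kspace`` is kept only on request.  ``parity`` records whether the
    stimulus was on, ``t_start_s`` the measurement's offset on the scan's
    background clock.
    """

    images: np.ndarray
    parity: str
    t_start_s: float = 0.0
    kspace: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def roi_trace(self, mask: np.ndarray) -> np.ndarray:
        """ROI-averaged raw signal per frame."""
        return self.images[:, mask].mean(axis=1)


def synthesize_measurement(
    split: KSpaceSplit,
    plan: SamplingPlan,
    gamma: DianaResponse | None = None,
    beta: HemodynamicModel | None = None,
    noise: NoiseModel | None = None,
    parity: str = "off",
    t_offset_s: float = 0.0,
    scan_phase: float = 0.0,
    rng: np.random.Generator | int | None = None,
    keep_kspace: bool = False,
) -> SyntheticMeasurement:
    """Synthesize and reconstruct one measurement.

    ``t_offset_s`` places the measurement on the scan's continuous
    background clock; ``scan_phase`` is the per-scan random phase of
    sinusoidal backgrounds.
    """
    params = plan.params
    n_pe, n_ro = split.shape
    if n_pe != params.n_pe:
        raise ValueError("k-space split does not match the plan's matrix size")
    T = params.n_timepoints

    trials = np.arange(n_pe)
    tps = np.arange(T)
    # absolute acquisition time of every readout, shape (n_trials, T)
    t_abs = t_offset_s + plan.acquisition_time(trials[:, None], tps[None, :])
    g = gamma_eval(gamma, tps * params.tr_ms, params, parity)          # (T,)
    b = beta_eval(beta, t_abs, scan_phase)                             # (n_trials, T)
    mod = b * g[None, :]                                               # (n_trials, T)

    # scatter trial-ordered modulation onto PE rows: mod_rows[t, row]
    mod_rows = np.empty((T, n_pe), dtype=float)
    mod_rows[:, plan.line_order] = mod.T

    kspace = split.k_rest[None, :, :] + mod_rows[:, :, None] * split.k_active[None, :, :]
    if noise is not None and noise.sigma > 0:
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(noise.seed if rng is None else rng)
        kspace = kspace + noise.sigma * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )

    imgs = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(kspace, axes=(1, 2)), axes=(1, 2), norm="ortho"),
        axes=(1, 2),
    )
    return SyntheticMeasurement(
        images=np.abs(imgs),
        parity=parity,
        t_start_s=t_offset_s,
        kspace=kspace if keep_kspace else None,
        meta={"scan_phase": scan_phase},
    )


def iter_experiment(
    split: KSpaceSplit,
    plan: SamplingPlan,
    experiment: ExperimentPlan,
    gamma: DianaResponse | None = None,
    beta: HemodynamicModel | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    include_breaks_in_clock: bool = False,
) -> Iterator[SyntheticMeasurement]:
    """Generate a multi-scan session measurement by measurement.

    Within each scan the measurements alternate off, on, off, on, ... and
    share one continuous background clock (restarting at zero per scan; the
    10 s inter-measurement breaks are excluded from the clock by default).
    One background phase is drawn per scan; per-measurement noise streams
    derive reproducibly from the master seed.
    """
    params = plan.params
    master = np.random.SeedSequence(seed)
    phase_rng = np.random.default_rng(master.spawn(1)[0])
    step_s = params.measurement_s + (params.inter_meas_break_s if include_breaks_in_clock else 0.0)
    for s in range(experiment.n_scans):
        scan_phase = float(phase_rng.uniform(0.0, 2 * np.pi))
        for m in range(params.n_meas_per_scan):
            idx = s * params.n_meas_per_scan + m
            meas_rng = np.random.default_rng(np.random.SeedSequence((seed, 1, idx)))
            meas = synthesize_measurement(
                split,
                plan,
                gamma=gamma,
                beta=beta,
                noise=noise,
                parity=experiment.parities[idx],
                t_offset_s=m * step_s,
                scan_phase=scan_phase,
                rng=meas_rng,
            )
            meas.meta.update({"scan": s, "measurement": m, "index": idx})
            yield meas


def simulate_experiment(*args, **kwargs) -> list[SyntheticMeasurement]:
    """Materialized :func:`iter_experiment` (prefer the iterator for large runs)."""
    return list(iter_experiment(*args, **kwargs))
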