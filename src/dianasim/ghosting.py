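"""Image-space ghosting from trial-index-dependent background modulation.

With one phase-encode line acquired per trial, any background that varies
from trial to trial multiplies k-space rows by a line-dependent factor.  A
sinusoidal background of frequency ``f`` sampled once per ``trial``
(duration ``dt``) imprints ``f * dt`` cycles per line along the PE axis,
producing replica images (ghosts) displaced by ``+-f * dt * n_pe`` pixels.
When ``f * dt`` is an integer (e.g. 5 Hz with 200 ms trials) the modulation
is identical for every line and the ghosts land back on the source: no
artifact.  Frame-constant factors (the neuronal response) never ghost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .engine import synthesize_measurement
from .phantom import KSpaceSplit
from .schedule import SamplingPlan
from .signal_models import HemodynamicModel


def predict_ghost_shift(frequency_hz: float, plan: SamplingPlan) -> np.ndarray:
    """Predicted ghost displacements along PE, in pixels (``[-d, +d]``).

    ``d = (f * trial_duration * n_pe) mod n_pe``; a real sinusoid produces
    symmetric sidebands, so both signs are reported.  ``d == 0`` (frequency
    an integer multiple of the trial rate) means no ghost.
    """
    if frequency_hz < 0:
        raise ValueError("frequency must be >= 0")
    p = plan.params
    d = (frequency_hz * p.trial_ms / 1000.0 * p.n_pe) % p.n_pe
    return np.array([-d, d])


@dataclass(frozen=True)
class GhostReport:
    """Detected ghosts in a ROI-only (k_rest = 0) noiseless simulation."""

    ghost_map: np.ndarray
    predicted_shifts: np.ndarray
    measured_centroids: np.ndarray  # PE displacement of each detected component
    ghost_energy_ratio: float

    def to_dict(self) -> dict:
        return {
            "predicted_shifts_px": self.predicted_shifts.tolist(),
            "measured_centroids_px": self.measured_centroids.tolist(),
            "ghost_energy_ratio": self.ghost_energy_ratio,
        }


def ghost_map(
    split: KSpaceSplit,
    beta: HemodynamicModel | None,
    plan: SamplingPlan,
    roi_mask: np.ndarray,
    scan_phase: float = 0.0,
    rel_threshold: float = 0.05,
) -> GhostReport:
    """Ghost visualization: simulate with the static background removed.

    One noiseless measurement is synthesized from the ROI-only k-space
    (``k_rest`` zeroed, no neuronal response), reconstructed, and the frames
    averaged.  Components brighter than ``rel_threshold`` times the maximum
    of the out-of-ROI residual (true ROI footprint dilated by one pixel and
    masked out) are labelled; their PE-centroid displacements from the ROI
    centroid and the out-of-ROI energy fraction are reported.
    """
    roi_only = split.with_rest_zeroed()
    meas = synthesize_measurement(
        roi_only, plan, gamma=None, beta=beta, noise=None,
        parity="off", scan_phase=scan_phase,
    )
    mean_img = meas.images.mean(axis=0)

    footprint = ndimage.binary_dilation(roi_mask, iterations=1)
    residual = np.where(footprint, 0.0, mean_img)
    total_energy = float((mean_img**2).sum())
    ghost_energy = float((residual**2).sum())
    ratio = ghost_energy / total_energy if total_energy > 0 else 0.0

    n_pe = mean_img.shape[0]
    # intensity-weighted ROI centroid: ghosts are shifted copies of the ROI
    # *image*, so the mask centroid would carry the phantom's asymmetry
    roi_row = ndimage.center_of_mass(np.where(footprint, mean_img, 0.0))[0]
    centroids: list[float] = []
    peak = residual.max()
    if peak > 1e-9 * mean_img.max():
        labels, n = ndimage.label(residual >= rel_threshold * peak)
        for com in ndimage.center_of_mass(residual, labels, range(1, n + 1)):
            delta = com[0] - roi_row
            # report the wrapped displacement in (-n_pe/2, n_pe/2]
            delta = (delta + n_pe / 2) % n_pe - n_pe / 2
            centroids.append(float(delta))

    freq = beta.frequency_hz if (beta is not None and beta.kind == "sinusoid") else 0.0
    return GhostReport(
        ghost_map=mean_img,
        predicted_shifts=predict_ghost_shift(freq or 0.0, plan),
        measured_centroids=np.array(sorted(centroids)),
        ghost_energy_ratio=ratio,
    )


def ghost_interference_check(
    split: KSpaceSplit,
    plan: SamplingPlan,
    beta_variants: dict[str, HemodynamicModel | None],
    gamma,
    roi_mask: np.ndarray,
    n_scans: int = 23,
    seed: int = 0,
):
    """Bias of the trial-averaged response under each background variant.

    Runs a noiseless multi-scan session per variant (stimulus on during even
    measurements), trial-averages the stimulus-on measurements, and reports
    the maximum absolute deviation from the background-free trace at the
    response bins plus the CI half-width there (slow backgrounds should not
    bias the peak; paradigm-synchronized ones inflate the CI instead).
    """
    import pandas as pd

    from .analysis import trial_average
    from .engine import iter_experiment
    from .schedule import experiment_bookkeeping
    from .signal_models import response_bins

    params = plan.params
    experiment = experiment_bookkeeping(n_scans, params)
    bins = response_bins(gamma, params)

    ref = trial_average(
        iter_experiment(split, plan, experiment, gamma=gamma, beta=None, noise=None, seed=seed),
        roi_mask,
        parity="on",
    )
    rows = []
    for name, beta in beta_variants.items():
        avg = trial_average(
            iter_experiment(split, plan, experiment, gamma=gamma, beta=beta, noise=None, seed=seed),
            roi_mask,
            parity="on",
        )
        bias = np.abs(avg.mean_trace[bins] - ref.mean_trace[bins]).max()
        rows.append(
            {
                "background": name,
                "peak_pct": avg.mean_trace[bins].max(),
                "max_bias_pct": float(bias),
                "ci99_at_response_pct": float(avg.ci99[bins].max()),
            }
        )
    return pd.DataFrame(rows)
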