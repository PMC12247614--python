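"""Study configuration and end-to-end report generation.

A :class:`StudyConfig` describes the phantom, sequence, signal models and
study sizes; :func:`run_study` regenerates all study outputs (CSV traces and
tables, JSON summary, PNG figures, NIfTI stacks) deterministically from the
master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, ghosting
from .engine import iter_experiment, synthesize_measurement
from .phantom import ROISpec, build_phantom, save_image_nifti, split_kspace
from .schedule import (
    SequenceParams,
    build_sampling_plan,
    experiment_bookkeeping,
    scan_duration,
    stimulus_trace,
)
from .signal_models import (
    DianaResponse,
    HemodynamicModel,
    NoiseModel,
    calibrate_noise_sigma,
    response_bins,
)


@dataclass
class StudyConfig:
    """Fully serializable description of one simulation study."""

    shape: tuple[int, int] = (80, 80)
    roi: dict = field(default_factory=lambda: asdict(ROISpec()))
    sequence: dict = field(default_factory=lambda: asdict(SequenceParams()))
    response: dict = field(default_factory=lambda: asdict(DianaResponse()))
    target_tsnr: float = 350.0
    noise_study_n: tuple[int, ...] = (1, 30, 180, 360)
    ghost_frequencies_hz: tuple[float, ...] = (0.5, 1.0, 5.0)
    background_p2p: float = 0.005
    n_scans_background: int = 23
    seed: int = 0

    def sequence_params(self) -> SequenceParams:
        return SequenceParams(**self.sequence)

    def roi_spec(self) -> ROISpec:
        r = dict(self.roi)
        r["active_center"] = tuple(r["active_center"])
        r["control_center"] = tuple(r["control_center"])
        return ROISpec(**r)

    def diana_response(self) -> DianaResponse:
        return DianaResponse(**self.response)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["shape"] = list(self.shape)
        data["noise_study_n"] = list(self.noise_study_n)
        data["ghost_frequencies_hz"] = list(self.ghost_frequencies_hz)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        try:
            data["shape"] = tuple(data["shape"])
            data["noise_study_n"] = tuple(data["noise_study_n"])
            data["ghost_frequencies_hz"] = tuple(data["ghost_frequencies_hz"])
            return cls(**data)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"invalid study config: {exc}") from exc


def miniature_config() -> StudyConfig:
    """A 16x16, 8-timepoint configuration for fast smoke runs."""
    return StudyConfig(
        shape=(16, 16),
        roi=asdict(ROISpec(active_center=(8.0, 8.0), control_center=(4.0, 4.0), radius=1.4)),
        sequence=asdict(
            SequenceParams(n_pe=16, n_timepoints=8, stim_onset_ms=10.0, stim_dur_ms=5.0)
        ),
        response=asdict(DianaResponse(onset_after_stim_end_ms=5.0, duration_ms=5.0)),
        target_tsnr=100.0,
        noise_study_n=(2, 4),
        n_scans_background=2,
    )


def timing_report(params: SequenceParams) -> dict:
    """Schedule arithmetic: durations, DC-line timing, pair bookkeeping."""
    plan = build_sampling_plan(params)
    dur = scan_duration(params)
    return {
        "tr_ms": params.tr_ms,
        "trial_ms": params.trial_ms,
        "n_timepoints": params.n_timepoints,
        "n_pe": params.n_pe,
        "measurement_s": params.measurement_s,
        "scan_imaging_s": dur.imaging_s,
        "scan_total_s": dur.total_s,
        "dc_trial_index": plan.dc_trial_index,
        "dc_time_s": plan.dc_time_s,
        "stimulus_segments_ms": [
            params.stim_onset_ms,
            params.stim_dur_ms,
            params.trial_ms - params.stim_end_ms,
        ],
        "pairs_per_scan": params.n_meas_per_scan // 2,
    }


def run_study(config: StudyConfig, outdir) -> dict:
    """Run the full simulation study and write the report bundle.

    Outputs: phantom and mask NIfTIs, trial-average CSVs for the noise
    study, a tSNR-vs-N table, ghost reports + PNG panels, and a JSON summary
    of the headline numbers.  Idempotent for a fixed seed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.sequence_params()
    phantom, rois = build_phantom(config.shape, config.roi_spec(), seed=config.seed)
    split = split_kspace(phantom, rois)
    plan = build_sampling_plan(params)
    resp = config.diana_response()
    bins = response_bins(resp, params)

    save_image_nifti(out / "phantom.nii", phantom.image)
    save_image_nifti(out / "roi_active.nii", rois.active_mask.astype(float))
    save_image_nifti(out / "roi_control.nii", rois.control_mask.astype(float))

    summary: dict = {"seed": config.seed, "timing": timing_report(params)}

    # --- noise / detectability study (constant background) ---------------
    noise = calibrate_noise_sigma(
        config.target_tsnr, phantom, rois, plan, seed=config.seed, n_replicates=30
    )
    summary["noise_sigma"] = noise.sigma
    fig, axes = plt.subplots(1, len(config.noise_study_n), figsize=(4 * len(config.noise_study_n), 3))
    axes = np.atleast_1d(axes)
    peaks = {}
    rng_master = np.random.SeedSequence((config.seed, 7))
    for ax, n in zip(axes, config.noise_study_n):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7, n)))
        meas = (
            synthesize_measurement(split, plan, gamma=resp, beta=None, noise=noise,
                                   parity="on", rng=rng)
            for _ in range(max(n, 2))
        )
        avg = analysis.trial_average(meas, rois.active_mask, parity="on")
        avg.to_frame().to_csv(out / f"trial_average_n{n}.csv", index=False)
        peaks[str(n)] = float(avg.mean_trace[bins].max())
        t_ms = np.arange(params.n_timepoints) * params.tr_ms
        ax.fill_between(t_ms, avg.mean_trace - avg.ci99, avg.mean_trace + avg.ci99, alpha=0.3)
        ax.plot(t_ms, avg.mean_trace)
        ax.set_title(f"N = {n}")
        ax.set_xlabel("time in trial (ms)")
    axes[0].set_ylabel("signal change (%)")
    fig.tight_layout()
    fig.savefig(out / "trial_averages.png", dpi=120)
    plt.close(fig)

    summary["trial_average_peak_pct"] = peaks

    # --- tSNR vs N -------------------------------------------------------
    pool_n = max(16, 2 * max(config.noise_study_n) if max(config.noise_study_n) <= 64 else 64)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    traces = np.array(
        [
            synthesize_measurement(split, plan, noise=noise, parity="off", rng=rng)
            .roi_trace(rois.active_mask)
            for _ in range(pool_n)
        ]
    )
    n_vals = [n for n in (1, 2, 4, 8, 16, 32, 64) if n <= pool_n]
    table = analysis.tsnr_vs_n(traces, n_vals, seed=config.seed)
    table.to_csv(out / "tsnr_vs_n.csv", index=False)
    summary["tsnr_loglog_slope"] = analysis.tsnr_loglog_slope(table)

    # --- ghosting --------------------------------------------------------
    ghost_summary = {}
    fig, axes = plt.subplots(1, len(config.ghost_frequencies_hz) + 1, figsize=(12, 3))
    axes[0].imshow(phantom.image * rois.active_mask, cmap="gray")
    axes[0].set_title("ROI (truth)")
    for ax, f in zip(axes[1:], config.ghost_frequencies_hz):
        beta = HemodynamicModel(kind="sinusoid", peak_to_peak=config.background_p2p, frequency_hz=f)
        rep = ghosting.ghost_map(split, beta, plan, rois.active_mask)
        ghost_summary[f"{f}Hz"] = rep.to_dict()
        ax.imshow(rep.ghost_map, cmap="gray")
        ax.set_title(f"{f} Hz")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "ghost_maps.png", dpi=120)
    plt.close(fig)
    summary["ghosts"] = ghost_summary

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return summary
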