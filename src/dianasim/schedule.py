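"""Acquisition schedule for line-scan ("phase-and-repetition-loop swapped")
spoiled gradient-echo imaging.

One 200 ms trial acquires all 40 within-trial time points of a single
phase-encode line; the trial repeats once per line (descending, k-max to
k-min) to fill k-space, so one measurement of 40 fully sampled frames takes
``n_pe * trial_ms`` = 16 s at the defaults.  Eight measurements form a scan,
with the visual stimulus on during even-numbered measurements only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SequenceParams:
    """Nominal sequence timing and loop structure.

    Defaults reproduce the 17.2 T protocol: TR 5 ms, 40 time points per
    200 ms trial, 80 phase-encode lines (16 s per measurement), a 10 ms
    stimulus 50 ms into the trial, 8 measurements per scan and 3200 dummy
    TRs (16 s) of magnetization stabilisation before each scan.
    """

    tr_ms: float = 5.0
    n_timepoints: int = 40
    n_pe: int = 80
    stim_onset_ms: float = 50.0
    stim_dur_ms: float = 10.0
    n_meas_per_scan: int = 8
    n_dummy_tr: int = 3200
    inter_meas_break_s: float = 10.0  # bookkeeping only; excluded from clocks

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.n_timepoints < 1:
            raise ValueError("tr_ms and n_timepoints must be positive")
        if self.n_pe < 2 or self.n_pe % 2:
            raise ValueError("n_pe must be even and >= 2")
        if self.n_meas_per_scan % 2:
            raise ValueError("n_meas_per_scan must be even (on/off pairs)")
        if self.stim_onset_ms < 0 or self.stim_dur_ms <= 0:
            raise ValueError("stimulus timing must be non-negative")
        if self.stim_onset_ms + self.stim_dur_ms > self.trial_ms:
            raise ValueError("stimulus window exceeds the trial")

    @property
    def trial_ms(self) -> float:
        return self.tr_ms * self.n_timepoints

    @property
    def measurement_s(self) -> float:
        """Duration of one measurement (all PE lines) in seconds."""
        return self.n_pe * self.trial_ms / 1000.0

    @property
    def stim_end_ms(self) -> float:
        return self.stim_onset_ms + self.stim_dur_ms


@dataclass(frozen=True)
class SamplingPlan:
    """Which PE line each trial acquires, and when every readout happens.

    ``line_order[n]`` is the (0-based) PE row acquired during trial ``n``
    (0-based); lines run from k-max down to k-min.  ``dc_trial_index`` is the
    1-based trial at which the DC (k = 0) line is acquired.
    """

    params: SequenceParams
    line_order: np.ndarray
    dc_trial_index: int
    dummy_offset_s: float = 0.0

    def acquisition_time(self, trial: np.ndarray | int, timepoint: np.ndarray | int) -> np.ndarray:
        """Absolute time (s, from measurement start) of a readout, 0-based."""
        trial = np.asarray(trial)
        timepoint = np.asarray(timepoint)
        p = self.params
        return self.dummy_offset_s + (trial * p.trial_ms + timepoint * p.tr_ms) / 1000.0

    @property
    def dc_time_s(self) -> float:
        """Time into the measurement by which the DC trial completes."""
        return self.dummy_offset_s + self.dc_trial_index * self.params.trial_ms / 1000.0

    def to_frame(self) -> pd.DataFrame:
        """Readout table: trial, PE index, timepoint, absolute time (s)."""
        p = self.params
        trials = np.repeat(np.arange(p.n_pe), p.n_timepoints)
        tps = np.tile(np.arange(p.n_timepoints), p.n_pe)
        return pd.DataFrame(
            {
                "trial": trials,
                "pe_index": self.line_order[trials],
                "timepoint": tps,
                "time_s": self.acquisition_time(trials, tps),
            }
        )


def build_sampling_plan(params: SequenceParams, include_dummy_offset: bool = False) -> SamplingPlan:
    """Descending (k-max to k-min) one-line-per-trial sampling plan.

    Under the centered k-space layout (DC at row ``n_pe // 2``) the
    descending order visits the DC line at the ``n_pe / 2``-th trial
    (1-based): trial 40 of 80, i.e. 8 s into a default measurement.
    """
    line_order = np.arange(params.n_pe - 1, -1, -1)
    dc_row = params.n_pe // 2
    dc_trial_index = int(np.nonzero(line_order == dc_row)[0][0]) + 1
    offset = params.n_dummy_tr * params.tr_ms / 1000.0 if include_dummy_offset else 0.0
    return SamplingPlan(
        params=params,
        line_order=line_order,
        dc_trial_index=dc_trial_index,
        dummy_offset_s=offset,
    )


@dataclass(frozen=True)
class ScanDuration:
    total_s: float
    imaging_s: float
    dummy_s: float


def scan_duration(params: SequenceParams) -> ScanDuration:
    """Scan duration: dummy TRs plus ``n_meas_per_scan`` measurements.

    Defaults give 16 s of dummies + 128 s of imaging = 144 s (2 min 24 s).
    """
    dummy_s = params.n_dummy_tr * params.tr_ms / 1000.0
    imaging_s = params.n_meas_per_scan * params.measurement_s
    return ScanDuration(total_s=dummy_s + imaging_s, imaging_s=imaging_s, dummy_s=dummy_s)


def stimulus_trace(params: SequenceParams, parity: str) -> np.ndarray:
    """Per-TR binary stimulus schedule for one trial.

    ON exactly during ``[stim_onset, stim_onset + stim_dur)`` (TR bins keyed
    by their start time) for on-parity measurements; identically zero for
    off-parity measurements.
    """
    if parity not in ("on", "off"):
        raise ValueError("parity must be 'on' or 'off'")
    t = np.arange(params.n_timepoints) * params.tr_ms
    if parity == "off":
        return np.zeros(params.n_timepoints, dtype=int)
    return ((t >= params.stim_onset_ms) & (t < params.stim_end_ms)).astype(int)


@dataclass(frozen=True)
class ExperimentPlan:
    """Measurement-level bookkeeping for a multi-scan session."""

    n_scans: int
    params: SequenceParams
    parities: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("need at least one scan")
        # off, on, off, on, ... within every scan (stimulus off during odd-
        # numbered measurements, 1-based)
        per_scan = tuple("off" if m % 2 == 0 else "on" for m in range(self.params.n_meas_per_scan))
        object.__setattr__(self, "parities", per_scan * self.n_scans)

    @property
    def n_measurements(self) -> int:
        return self.n_scans * self.params.n_meas_per_scan

    @property
    def pairs(self) -> int:
        return self.n_scans * self.params.n_meas_per_scan // 2


def experiment_bookkeeping(n_scans: int, params: SequenceParams) -> ExperimentPlan:
    """On/off pair counting: 88 scans of 8 measurements -> 352 pairs."""
    return ExperimentPlan(n_scans=n_scans, params=params)
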