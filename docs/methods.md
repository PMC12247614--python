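# Methods

## Acquisition model

The simulated sequence is a spoiled gradient-echo acquisition in which the
phase-encode and repetition loops are swapped: a 200 ms trial (the
inter-stimulus interval) collects all 40 within-trial time points of one
phase-encode line at TR = 5 ms, and the trial repeats once per line to fill
an 80 x 80 matrix, so one *measurement* of 40 fully sampled frames spans
16 s. Eight measurements form a *scan* (128 s of imaging), preceded by 3200
dummy TRs (16 s) that stabilise the magnetization; the dummies shift the
clock but carry no signal, since synthesis starts from an equilibrium
baseline image. The stimulus is on during even-numbered measurements only
(off, on, off, on, ...), giving four on/off pairs per scan. The nominal 5 ms
TR is used throughout; a measured effective TR can be passed via
`SequenceParams(tr_ms=...)` but is not the default.

Lines are acquired in descending k-space order (k-max first). Under the
centered FFT layout (DC at row `n_pe // 2`) the DC line is therefore reached
at the 40th acquired trial, 8 s into the measurement — which is why the
whole-scan signal course is dominated by the background level around the
middle of each measurement. The sign of "k-max" (whether +k or −k comes
first) is not physically observable in this model beyond flipping the ghost
displacement sign; we take +k first and report ghost magnitudes.

All Fourier transforms are orthonormal (`norm="ortho"`) and centered. The
orthonormal choice makes Parseval's identity hold without scale factors, so
a k-space noise standard deviation maps 1:1 onto per-voxel image noise.

## Signal terms

**Neuronal response (`Gamma`).** A boxcar multiplicative increase of
fractional amplitude `a` (default 0.005), lasting 10 ms, starting 50 ms
after the stimulus ends; with the default 50 ms onset / 10 ms stimulus this
occupies 110–120 ms of the trial, i.e. frames 22–23 (0-based). Applied only
on stimulus-on measurements. A biphasic (undershooting) shape is not
modelled; the amplitude/onset/duration parameterization leaves that hook
open.

**Hemodynamic background (`beta`).** Multiplicative, strictly positive,
evaluated at the absolute acquisition time of every readout (5 ms
resolution). The clock runs continuously across a scan's eight measurements
and restarts per scan; the 10 s inter-measurement breaks are bookkeeping
metadata and excluded from the clock by default (toggleable), since the
background process has no memory across the break in this model. Variants:

* `constant` — exactly 1 (noise-only studies);
* `sinusoid` — `1 + p2p/2 * sin(2 pi f t + phase)`, one random phase per
  scan; defaults 0.5% peak-to-peak at 0.5, 1 or 5 Hz;
* `block` — square wave locked to measurement parity (exact step recovery
  studies);
* `block_hrf` — the measurement-parity boxcar convolved with a gamma-variate
  HRF (peak 2.5 s, undershoot ratio 0.2 — a rodent-fast response), optional
  0.1–0.3 Hz oscillation, rescaled to a requested peak-to-peak (1.5% for the
  short-TE spoiled-GRE-like background, 8% for the EPI-like one). The
  functional form is this package's own; it is validated only by
  peak-to-peak amplitude and timescale, not by shape;
* `resampled_trace` — any coarse trace (default 0.4 s sampling), low-pass
  filtered with a normalized 5-tap Gaussian kernel (sigma = 1 sample,
  symmetric-reflection boundaries) and interpolated to 5 ms with a
  not-a-knot cubic spline. "Filter width 5" is a tool-dialect phrase; the
  kernel used here is declared explicitly instead.

**Noise (`sigma`).** Independent circular complex Gaussian noise per k-space
sample (std `sigma` per real/imaginary component). Magnitude reconstruction
makes image noise Rician; at the SNR levels studied here the Gaussian
approximation inside the head is excellent, but calibration is still done
empirically: starting from the analytic guess
`sigma0 = roi_mean * sqrt(V) / tSNR_target`, stimulus-off measurements are
simulated through the full synthesis + reconstruction + ROI-averaging path
and `sigma` is rescaled by the achieved/target tSNR ratio (200 replicate
measurements per iteration, 1.5% stopping tolerance).

**Target tSNR = 350.** The study's absolute per-measurement ROI-mean tSNR is
a free condition of the synthetic study. 350 was fixed analytically, before
any detectability run, as the level at which the canonical
amplitude/averaging pairs separate the way the detectability analysis
expects: the per-bin trace noise after smoothing is
`0.595 * 100 / tSNR ≈ 0.17%`, so a single measurement cannot show a 0.5%
(pipeline-attenuated to ~0.35%) peak above the ~0.37% baseline-envelope
noise, while averaging N = 16 / 96 / 256 measurements brings the envelope
below the attenuated 0.5% / 0.2% / 0.1% peaks with margin. It is an ROI-mean
(not per-voxel) figure over a 37-voxel ROI, i.e. per-voxel tSNR ≈ 58.

## Phantom

A smooth composite of graded ellipses (head outline plus two internal
structures) with 5% smooth random texture, standing in for an averaged
stimulus-off baseline image; real baselines are magnitude averages, and this
synthetic baseline is real-valued by construction. Active and control ROIs
are translated copies of one disk footprint (radius 3.5 px, 37 voxels each),
guaranteeing matched voxel counts; the control ROI sits away from both the
active ROI and its sinusoid ghost positions. The radius is chosen so the
±8 px ghost of the 0.5 Hz background clears the dilated ROI footprint used
in ghost detection.

## Analysis pipeline

Per measurement and per voxel, in this fixed order: percent signal change
around the within-measurement 40-frame mean; least-squares linear detrend;
cyclic 3-tap Gaussian smoothing (weights `[e^-1/2, 1, e^-1/2]` normalized);
then ROI averaging. Trial statistics are the mean and the two-sided 99%
Student-t confidence interval of the mean across measurements (t rather than
normal for small-N validity).

The within-measurement mean baseline is a convention (no separate baseline
period exists in a 200 ms trial); it makes off-parity traces zero-mean and
attenuates a 2-frame peak by the factor `(1 - 2/40) / (1 + a*2/40)` — 0.475%
raw for a 0.5% response, ~0.347% after smoothing. Detection of a peak is
operationalized as: the mean trace at the known response bins exceeds the
maximum CI upper envelope over all baseline bins (response bins ± 1 guard
bin excluded, because smoothing leaks into neighbours). A detection *rate*
is the fraction of seeded replicates detected; the headline claims use 20
replicates and a 90% success threshold. These conventions — envelope
criterion, guard width, replicate count — are choices of this package.

Whole-scan ("long timescale") traces concatenate the per-frame ROI means of
a scan's eight measurements (320 points at 0.4 s effective spacing), convert
to percent change around the scan mean, fit a degree-6 polynomial to the
*control*-ROI trace, subtract that fit from both ROIs, and average across
scans. The polynomial models slow instrumental drift common to both ROIs;
fitting it on the control keeps block-locked functional signal in the active
ROI untouched. The on-block elevation is reported relative to the off-block
baseline (`(m_on - m_off) / (1 + m_off/100)`), which recovers a pure
multiplicative step exactly.

tSNR is mean/std (ddof 1) of the raw ROI-mean 40-point trace; a temporally
constant trace raises a distinct zero-variance error rather than returning
infinity. tSNR versus averaging depth draws 80 random N-subsets per N
(without replacement within a subset, independently across draws), averages
the raw traces, and reports the mean tSNR of the averages; with white noise
the log–log slope is 0.5.

Contrast maps are pooled-variance two-sample t statistics between the
temporal-mean images of on- and off-parity measurements, thresholded at
t ≥ 2.5 with no smoothing or clustering — a stand-in for a GLM with a
measurement-parity boxcar regressor, with which it coincides up to variance
pooling on measurement-mean data.

## Ghosting

A background sampled once per trial at frequency `f` imprints `f * 0.2 s`
cycles per line along the acquisition order, i.e. sidebands displaced by
`(f * 0.2 * n_pe) mod n_pe` pixels along the phase encode axis (±16 px at
1 Hz, ±8 px at 0.5 Hz; identical for `f` and `f + 5 Hz`). At 5 Hz the
modulation aliases to a constant per frame and the ghosts land back on the
source — no artifact, but the surviving frame-to-frame oscillation aliases
into the trial average and inflates its confidence interval.

Ghost visualization zeroes the static k-space contribution and synthesizes
one noiseless measurement without a neuronal response. Detection labels
connected components above 5% of the maximum of the mean image *after the
dilated true-ROI footprint is zeroed*: with 0.5% peak-to-peak backgrounds
the sidebands are ~0.12% of the main image, so the threshold must be
relative to the brightest out-of-ROI structure to mean anything. Centroids
are intensity-weighted and compared against the intensity-weighted ROI
centroid (the ghosts are shifted copies of the ROI *image*, whose centroid
differs from the mask centroid on an asymmetric phantom).

## Numerical choices and degenerate inputs

* Block-background evaluation adds 1e-9 s before the floor division so
  readouts landing exactly on a block boundary are not mis-assigned by
  floating-point rounding (readouts are milliseconds apart).
* Percent change requires a strictly positive baseline; ROI processing only
  touches ROI voxels, so zero-signal background voxels never enter it.
  Contrast maps operate on raw temporal means and need no such guard.
* The degree-6 drift-removal guarantee (residual < 1e-8 relative) holds for
  drift entering multiplicatively and identically in both ROIs at the trace
  level; drift injected through k-space additionally produces small,
  physical modulation ghosts that are not pipeline error.
* Seeds: every stochastic path (phantom texture, scan phases, noise streams,
  bootstrap draws, replicate studies) derives from explicit seeds or
  `SeedSequence` children of a master seed; reruns are bit-identical.

## Study sizes

The bundled studies use the protocol sizes where they are cheap (23 scans
for the background-interference study, N up to 128 from a 160-measurement
pool for the tSNR bootstrap, N up to 256 with 20 replicates for
detectability) and a 16 x 16, 8-frame miniature configuration for
structural and smoke tests.

## What the generator does and does not emulate

Synthetic data reproduce the acquisition geometry, timing, on/off paradigm
structure, background timescales and amplitudes, and a calibrated noise
level. They do not contain real physiological noise spectra, B0/shim drift
physics, coil sensitivities, partial-volume or vascular-bias effects in the
ROI, stimulated echoes, or EPI-specific artifacts. Passing tests therefore
demonstrate properties of the acquisition-and-pipeline *model* — e.g. that
slow backgrounds cannot mimic or mask a millisecond response at the response
bins — not claims about any in-vivo dataset. The in-vivo-scale hemodynamic
step sizes (0.7–1.1%) appear only as injected parameters whose recovery the
pipeline is tested on.
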