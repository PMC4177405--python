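# Methods

This note documents the generative model behind the simulator, the
statistical procedures in the analysis pipeline, the parameter defaults
and the reasoning behind them, and the design decisions taken where the
underlying experimental convention leaves room.

## Stimulus protocol

A session is a contiguous sequence of trials, each a blank period
followed by a drifting sinusoidal grating. Defaults: 4 s blank, 4 s
stimulus, 8 equally spaced directions, 1 Hz temporal frequency,
0.05 cycles/degree spatial frequency (metadata only — no spatial
receptive fields are modelled), 15 Hz frame rate, 5 trials per
direction. Trials are ordered repetition-major (all 8 directions, then
the next repetition). Frame times are frame-start times;
`frame_rate × trial_duration` must be an integer so trials align to
frames.

## Forward model

**Spiking.** Each cell fires as an inhomogeneous Poisson process. During
the blank the rate is `baseline_rate`; during the grating it is

    baseline + (peak − baseline) · g(θ − θ_pref) · (1 + m·sin(2π f_t t')),

clipped at zero, where `g` is a von Mises-shaped gain
`exp(κ(cos Δ − 1))` normalized to 1 at the preferred direction, `m` the
modulation depth and `f_t` the grating temporal frequency. The von Mises
form is a standard smooth circular tuning curve; only "tuned responses"
are required of it, so any unimodal circular bump would do. Sampling is
by thinning against the per-trial rate ceiling, so the expected count
equals the rate integral exactly. Defaults: baseline 2 spikes/s, peak
10 spikes/s, κ = 2, m = 0.5 — mid-range values for L2/3 visual-cortex
responses to high-contrast gratings that put single-trial responses
comfortably above the noise floor without saturating the classifier.

**Calcium transients.** A spike at time s contributes
`A·k(t − s)` to ΔF/F, with `k` a peak-normalized difference of
exponentials. The decay time constant is solved numerically (Brent's
method, nested for the inner half-crossing) so the *measured* post-peak
half-decay of the kernel equals the model's `decay_half_time` exactly —
for a difference of exponentials the half-decay is not `τ_d ln 2`
because the rise term keeps decaying after the peak. Transients sum
linearly across spikes and across trial boundaries (the session is one
continuous frame grid). Presets:

| preset | rise τ (s) | half-decay (s) | A (ΔF/F per spike) | baseline (a.u.) |
|--------|-----------|----------------|--------------------|-----------------|
| fast   | 0.045     | 0.14           | 0.19               | 100             |
| slow   | 0.18      | 0.51           | 0.25               | 100             |

These are simulator parameters chosen within the ranges measured for
GCaMP6f-like and GCaMP6s-like indicators in cortical tissue; they are
inputs to the simulation, not claims about any preparation. Transient
evaluation is windowed to the kernel's support (cut at 1e-12 of peak),
which is exact to numerical precision and keeps a 2000-cell session
under ten seconds.

**Measurement.** The measured somatic trace is
`cyto + r_true·neuropil + noise` with `r_true = 0.7` by default. The
neuropil trace has baseline `0.7 ×` mean somatic baseline and
co-fluctuates with population-average ΔF/F (unit coupling), so
contamination is *correlated with signal*, which is the regime the
subtractive correction is meant for. Noise is additive Gaussian with SD
a fraction (default 0.05) of each cell's baseline, or Poisson photon
noise when a photon scaling is set. At zero noise the composition is
exactly invertible, which the tests exploit.

**Rendering.** Movies draw each soma as a nucleus-excluded ring
(radius 6 µm, nucleus 3 µm) carrying its cytosolic signal plus
see-through neuropil; the background is the neuropil trace times a
static smooth spatial texture (Gaussian-filtered noise, SD 10%); cell
placement is rejection sampling with a minimum separation of two soma
radii and a bounded retry budget. The extraction round trip (render →
mask mean) recovers composed traces with correlation > 0.999 at zero
noise; the residual is the spatial texture entering through the
contamination term.

**Histology generator.** The red (NeuN-like) channel shows every soma as
a filled disk; the green channel shows a Bernoulli(`labeled_fraction`)
subset as rings with lognormal brightness (log-SD 0.5 — about the
spread seen across transgenic cortical neurons). A separate bead field
contains 3.8 µm disks. All signal scales with an `illumination` factor,
emulating the excitation-intensity drift that bead normalization is
designed to remove.

## Analysis pipeline

**Extraction.** ROI masks use the pixel-center half-open convention
(a pixel belongs to a region iff its center at `(i+0.5)·pixel_size`
satisfies `inner ≤ d < outer`). The neuropil region is a 20 µm disk
around the cell center minus the union of *all* soma disks, including
the annular interiors (a nucleus is still soma, not neuropil) and the
cell's own. The annular-vs-circular choice is automated: annular when
the central mean of the time-average image is below 80% of the ring
mean; manual override supported.

**Exclusion, correction, ΔF/F₀.** The baseline-vs-neuropil comparison
(keep iff raw baseline > 1.03 × neuropil baseline, pooled across trials
over the pre-stimulus window) runs on *uncorrected* means, before the
correction — a cell that fails it is never corrected. F₀ is the mean of
the corrected trace over the window ending at grating onset (2 s fast /
1 s slow: the fast indicator returns to rest quickly, leaving a longer
usable window); frames are those whose start times fall in
`[onset − w, onset)`. Cells with non-positive F₀ in any trial are
excluded as unreliable.

**Responsiveness.** ANOVA groups are per-trial period means: one blank
sample per trial plus one sample per grating period, giving 9 groups
(40 + 8×5 samples at defaults). Per-frame samples would inflate N by
the frame count and invalidate the p-value. One deliberate choice: the
blank sample is the mean over the blank frames *preceding* the F₀
window. The F₀ frames are the ΔF/F₀ reference — their ΔF/F₀ is ≈0 by
construction — and including them shrinks the blank group's variance
about threefold relative to the stimulus groups, which a null
simulation showed inflates the false-positive rate of the p < 0.01 test
to ~7%. With the F₀ frames excluded the classifier runs at or slightly
below its nominal α (measured ~0.2–0.3% responsive under a pure-noise
null, the threshold test absorbing part of α). The amplitude condition
(max trial-mean period ΔF/F₀ > 0.05) is evaluated on trial-mean
direction responses, not single-trial maxima, for robustness.

**Preferred direction and alignment.** Preferred direction is the
argmax of trial-mean direction responses, ties broken to the lowest
direction index. The population-average preferred response takes cells
with peak ΔF/F₀ > 1, shifts each trace by an integer number of frames
so its maximum lands on the nearest of the 1/2/3/4 s anchors
(shifted-out samples are dropped, not wrapped), averages, and returns
both the raw average and a 3-sample moving-average smoothed version for
display.

**Spectra.** Per cell, the trial-averaged preferred-stimulus ΔF/F₀ over
the stimulus window is mean-subtracted and transformed with no zero
padding (0.25 Hz resolution for a 4 s window, rectangular windowing).
Amplitudes are energy-preserving (one-sided, weighted so the sum of
squared amplitudes equals the signal's sum of squares — Parseval). The
population spectrum is the per-bin median across cells; the peak is the
argmax over non-DC bins.

**Kinetics.** Preferred-direction trials are averaged (5 by default;
fewer warns), each extended past stimulus offset with the next trial's
blank frames on the session clock, so the decay is observable;
preferred trials at the end of the session without a full tail are
dropped. The gate compares the mean over the last 1 s of the stimulus
with baseline mean + 5 SD (pre-stimulus window); with zero baseline SD
the gate degenerates to response > baseline. The half-decay reference
is the **last response peak during stimulus presentation**: the last
local maximum in the stimulus window whose value reaches 50% of the
stimulus-window maximum. The sub-peak filter rejects noise blips; the
local-maximum rule matters because under 1 Hz rate modulation a fast
indicator's final response peak can precede stimulus offset by most of
a grating cycle, and a scan anchored at offset would start below half
peak and latch onto later spontaneous transients. From the peak, the
first sample pair bracketing half the baseline-subtracted peak is
linearly interpolated; traces that never reach half peak before the
recording ends yield an undefined (excluded) estimate with a warning.
The estimator is invariant under affine brightness transforms, and its
bias on pure exponentials shrinks with frame rate (checked at 15, 30,
60 Hz).

**Peak-normalized transients.** Baseline-subtracted traces are divided
by their peak, aligned so maxima coincide (at the median peak index),
and averaged — so the group average peaks at exactly 1.0. Non-positive
peaks are skipped with a warning.

**Histology quantification.** Somata are detected by matched filtering:
convolution with a normalized disk of one soma radius, whose response
is maximal exactly at a soma center for both rings and filled disks
(a Gaussian blur instead peaks on an off-center crest for rings and
loses cells to peak suppression). The threshold is the median response
plus the larger of 5 robust (MAD-based) noise SDs and 5% of the dynamic
range — somatic brightness spans an order of magnitude, so a
bimodal-histogram (Otsu) threshold drops the dim tail. Local maxima at
least one soma radius apart, refined to local response centroids,
become centers with annular ring masks. Bead measurement masks are
disks of 0.8 × the known bead radius at detected-component centroids
(the thresholded component includes blurred halo pixels that would bias
the mean down). Co-labeling uses greedy one-to-one nearest matching
with a default match radius of one soma radius. Box statistics use
linear-interpolation quartiles (stated because it changes values at
small n) with 1.5 IQR whiskers clamped to the most extreme sample in
range.

## What the simulator does and does not emulate

It emulates: Poisson spiking with circular tuning and stimulus-locked
rate modulation, linear indicator dynamics with calibrated half-decay,
signal-correlated neuropil contamination, Gaussian/photon noise,
non-overlapping ring somata, illumination drift in histology. It does
not emulate: brain motion, bleaching, scattering/PSF blur, spatial
receptive fields, indicator nonlinearity/saturation, overlapping or
out-of-focus somata, inhibitory cell types, or slow drifts in baseline.
Passing tests therefore demonstrate the *correctness of the analysis
given the stated measurement model*, not robustness to every artifact
of real recordings — in particular the exclusion rule's "~10% of cells"
figure from real tissue is a property of real data and is not asserted
here.

## Numerical choices and degenerate inputs

- Kernel decay constant: Brent's method to 1e-12; kernel support cut at
  1e-12 of peak.
- ANOVA: sums of squares computed directly; p from the F distribution
  with (k−1, N−k) df. Zero within-group variance with unequal means →
  p = 0; fully constant data → degenerate-data error (classified
  non-responsive with a warning at the pipeline level).
- Sample (n−1) SD for across-FOV variability and half-decay summaries;
  a single value reports SD 0 with n = 1.
- Exact two-way preference ties break to the lower direction index.
- Empty neuropil region, empty ROI mask, zero detected beads, and zero
  red somata raise typed errors rather than returning silent defaults.

## Problem sizes

The test suite and acceptance script run desk-scale simulations chosen
to make each statistical check well-powered: 2000 cells for the null
calibration (Monte-Carlo SE of the responsive fraction ≈ 0.002), 60
cells for the spectrum, 200 cells for tuned-fraction recovery, 20 seeds
× 12 cells per indicator for the kinetics ordering, and 100–150 somata
per histology image. A full 2000-cell session simulates in under ten
seconds; the complete acceptance script runs in well under a minute.

## Known limitations

- The half-decay of a population response mixes indicator decay with
  firing-rate decay; estimates for sustained responders exceed the
  single-spike half-decay (the fast preset's 0.14 s appears as ~0.15 to
  0.3 s population means depending on tuning strength). The fast < slow
  ordering is preserved in every seeded run.
- Automated soma detection is built for the generator's non-overlapping
  somata; real in vivo movies need curated ROIs (the `extract` command
  accepts any ROI table).
- The contamination ratio r is a single global constant; no
  regression-based per-cell estimation is provided.
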