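# Methods

This note records the models, numerical conventions and design choices
behind `semint`, and what the synthetic validation does and does not show
about real intracranial data.

## Signal chain

**Line-noise removal.** Zero-phase band-stop filtering at the line
frequency and its harmonics: a 2nd-order Butterworth band-stop (the order
of the one-pass filter; forward–backward application doubles the effective
order and cancels phase), stop bands of ±1 Hz around each harmonic
(configurable, `line.notch_halfwidth_hz`). Harmonics at or above Nyquist
are skipped with a warning.

**Re-referencing.** Common-average reference over retained (non-bad)
channels; bad channels are excluded from the average and passed through
unchanged. The operation is idempotent. Bad-channel and bad-trial masks
are *inputs*: the package performs no epileptiform-artifact detection,
mirroring practice where such rejection is manual.

**Band amplitude.** The analytic signal is built in the frequency domain:
negative frequencies are zeroed, positive frequencies multiplied by
`2·W(f)`, DC and Nyquist zeroed, and the inverse transform's magnitude
returned. The band weight is the product of two logistic flanks,
`W(f) = L((f−f_lo)/h)·L((f_hi−f)/h)` with `h` = 1.5 Hz. We read
"half-width" as the logistic scale, so the weight is exactly 0.5 at each
band edge and ≈0.95 at 4.4 Hz inside it; other parameterizations (e.g. a
10–90 % transition width) are possible, and `h` is configurable. Signals
are zero-padded to the next fast FFT length; the padding affects only the
recording edges, which lie outside all epochs.

**Smoothing.** Savitzky–Golay least-squares polynomial smoothing, 3rd
order, 251 ms frame. At 2 kHz a 251 ms frame is 502 samples; the frame is
rounded to the nearest odd count (501) as the filter requires.

**Percent change.** Per trial and channel,
`100·(A(t) − Ā_base)/Ā_base`, where `Ā_base` is the mean analytic
amplitude over −500…−100 ms before the *first* word of the same trial
(per-trial, not session-wide). Trials with a non-positive or non-finite
baseline are dropped with a warning; applying percent change to data that
is already in percent-change units is rejected by a unit guard.

**Epochs.** Time windows are half-open `[start, end)` in ms; the sample at
the lock onset belongs to the epoch. Locks: first word, final word, or
response onset. Trials flagged incorrect or listed in a bad-trial mask are
removed before any statistics.

## Statistics

**Pointwise activation.** One-tailed one-sample *t* (activation above
baseline, i.e. positive) at each time point, Benjamini–Hochberg step-up at
*q* = 0.05. The FDR family is the set of time points within a single trace
(per electrode or grouped trace), not the set of electrodes. Zero-variance
time points get p = 1 with a warning.

**Grouped traces.** Electrodes are averaged within each subject, then
subject means are averaged; the SEM is taken over subjects. This two-stage
average weights subjects, not electrodes.

**Window contrasts.** "Cumulative" window activity is implemented as the
window *mean* of percent change (equivalent to the sum up to a constant),
so the reported β is in percent units and comparable across window
lengths. Units are electrodes (within subject) or subjects (group level);
the paired two-sided *t* is evaluated at α = 0.01 by convention, with
conventional paired-*t* degrees of freedom (n−1).

**Narrowing classification.** A sentence's identification probability is
the fraction of norming participants whose typed answer at the penultimate
word position exactly matches the target (case-insensitive, trimmed; no
synonym handling). Sentences at or above the median probability are
labelled *strong* narrowing, the rest *limited*; the cut rule is
configurable (median default, ties go to *strong*).

**ROI grouping.** Electrodes are grouped by HCP parcel label into the
regions used in this literature (e.g. medial parietal cortex = {RSC, POS1,
POS2, v23ab, 7m, 31pv, 31pd, d23ab}); an electrode whose parcel matches
several ROI sets is assigned to all of them with a warning.

## Surface statistics (SB-MEMA)

**Projection.** Each electrode is indexed to the nearest mesh vertex by
Euclidean distance; ties break to the lowest vertex index. The
within-subject node effect is the window-mean percent-change difference
across trials; its variance is `var_A/n_A + var_B/n_B` of trial window
means. Multiple electrodes of one subject on one node are combined
precision-weighted.

**Geodesic smoothing.** Gaussian kernel
`K(d) ∝ exp(−d²/2σ²)`, σ = FWHM/2.3548, with `d` the shortest-path
(Dijkstra) distance over mesh edges — an approximation to exact polyhedral
geodesics that is adequate at small FWHM on dense meshes. The kernel is
truncated at 3σ and **row-normalized** (each output value is a convex
combination of inputs), which preserves constant fields exactly and does
not bias effect estimates; the alternative column normalization would
preserve total mass instead but distorts constants on irregular meshes.
Data and coverage masks are smoothed with the same kernel; a node counts
as covered if any covered node lies inside its kernel support.

**Random-effects combination.** At each node with at least `min_coverage`
subjects (default 3), DerSimonian–Laird: `Q = Σw_i(β_i − β_FE)²` with
fixed-effect weights `w_i = 1/s_i²`;
`τ̂² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))`; random-effects weights
`1/(s_i² + τ̂²)`; `t = pooled/√(1/Σw)`, df = k−1. The published SB-MEMA
implementations use richer estimators with outlier down-weighting; DL was
chosen for its closed form and testability, and the estimator is an
isolated, replaceable function. With equal variances and τ̂² = 0 the
pooled effect reduces exactly to the subject mean.

**Cluster familywise-error correction.** Per iteration, i.i.d. standard
normal noise per vertex is smoothed with the same kernel, re-standardized
per vertex (dividing by the kernel row 2-norm), thresholded at the vertex
threshold, and the largest connected suprathreshold component recorded
(vertices connect iff they share a mesh edge). The minimum surviving
cluster size is `ceil(quantile_{1−α}(max sizes)) + 1`. "Same dimension and
smoothness" is operationalized as: same mesh, same kernel. The paper-scale
default is 5000 iterations; the desk-scale studies here use 500.

*Vertex-threshold matching.* The calibration field is Gaussian, so its
vertex threshold is a z critical value (2.5758 for two-sided α = 0.01).
The measured map's marginal is t with k−1 df when node variances are
estimated; in that case the matching t quantile at the same tail
probability should be used so per-vertex exceedance matches the
calibration. In the null-calibration studies shipped here the subject
variances are known by construction, the map statistic is approximately
standard normal, and the same z threshold is used on both sides.

**Thresholded and conjunction maps.** A node survives iff t > t_min,
|%BGA| > pct_min, coverage ≥ min_coverage, and its connected
suprathreshold cluster reaches the calibrated minimum size. Default map
thresholds follow the figure-legend conventions (t > 1.96 at α = 0.05,
t > 2.57 at corrected α = 0.01; conjunction binarization %BGA > 5 %,
t > 2.57, coverage ≥ 2; the 5 % criterion is applied to the pooled group
estimate). Contrast maps use one-sided tests. Conjunction codes are the
exact per-node Boolean combination of the binarized inputs.

## Synthetic cohorts

The generator emulates what the analysis *assumes*: Gaussian 1/f^α
background (α = 1, RMS 20 µV by default) synthesized in the frequency
domain; 60 Hz line noise plus decaying harmonics with random phase; the
RSVP timeline (1000 ms fixation, 500 ms per word, 3–12 words per sentence,
1 s post-sentence blank, 2 s response window, 42 referential + 42
non-referential trials, ~95 % correct responses, articulation latencies
~N(1765, 680) ms); uniform random electrode placement over mesh vertices
per subject (optionally anchored at chosen nodes so a ground-truth region
is covered by every subject); and a norming table with monotone
non-decreasing identification probabilities across word positions that
reach certainty at the final word.

**Injected effects.** A condition-locked burst is Hann-enveloped
narrowband Gaussian noise confined to the effect band. Because background
and burst are independent circular-Gaussian band signals, the expected
analytic amplitude scales as the square root of band power; the burst peak
power is solved numerically (Brent) so that the *expected percent change
of the window-averaged amplitude* equals the requested value, relative to
the channel's measured background band power. Effects are injected before
line noise is added, so the downstream notch filter sees the same
background the calibration saw. The Hann envelope keeps the burst near
zero at the window edges, so Savitzky–Golay smoothing redistributes energy
almost entirely within the window and the window mean is approximately
preserved (residual bias measured at < 1 percentage point for a 50 %
effect).

**Mesh.** A sphere-like closed triangulation: the convex hull of seeded
uniform points on a sphere (every point is extreme, so all vertices are
used; Euler characteristic 2), with ±2 % seeded radial jitter applied
after triangulation for irregular edge lengths.

**What the synthetic data does not model.** Epileptiform artifacts,
non-stationary background spectra, volume conduction and shared noise
between electrodes, realistic cortical geometry and curvature, electrode
localization error, and behavioral structure beyond condition-independent
reaction times. Passing tests therefore validate the *statistical
machinery* — filters, estimators, calibration, error control — not the
package's robustness to those real-data features.

## Problem sizes of the shipped studies

Desk-scale sizes were chosen so the validation studies represent each
regime faithfully: recovery of injected amplitudes uses 20 cohort seeds
(one subject, four electrodes, the full 84-trial block each); the surface
sensitivity study uses 8 subjects anchored on a connected six-node patch
of a 100-vertex mesh; null error-control studies use 100–1000 all-null
epoch sets for FDR and a 500-vertex mesh with 500 calibration iterations
and 500 null replicates for FWER. On these coarse meshes the 3 mm
paper-scale kernel is nearly the identity, so the FWER study uses a 10 mm
kernel that genuinely couples neighboring vertices; calibration and
measurement always share the kernel.

Recovery studies run the chain without the common-average reference: with
only four synthetic channels, CAR would fold ~¼ of the injected burst
into the reference and bias the recovered amplitude by construction — a
montage effect that is negligible at a realistic ~200-channel scale. CAR
correctness is validated separately.

## Known limitations

- The DL random-effects core is a documented stand-in for the richer
  mixed-effects estimators of the SB-MEMA literature.
- Graph-geodesic distances overestimate true geodesics on coarse meshes.
- The theta band for the low-frequency (hippocampal-style) analysis
  defaults to 4–8 Hz and is configurable; no wavelet or multitaper
  alternatives are provided.
- The EDF container is read-only (via mne when available); the canonical
  on-disk signal format is HDF5.
- β values from electrode-paired window contrasts are in percent-change
  units; comparisons with values derived from other unit conventions
  require care.
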