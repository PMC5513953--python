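# Methods

This note documents the models and procedures implemented in `dusqa`, the
assumptions behind them, the tunables that matter, and what the synthetic-data
tests do and do not establish.

## Signal model and preprocessing

A 1-D DUS recording is mono audio whose energy is the Doppler shift of moving
fetal cardiac structures. For a ~3.3 MHz transducer, valve and wall motion map
to audio frequencies roughly below 1 kHz (wall velocities a few hundred Hz),
so a 4 kHz working rate preserves the cardiac content. Resampling uses a
least-squares linear-phase FIR (order 512, passband edge at 0.9 × the target
Nyquist, i.e. 1800 Hz) applied as a centred zero-net-delay convolution,
followed by rational polyphase resampling. Content inside the 1800–2000 Hz
transition band is attenuated but not aliased.

Segments are 3.75 s on a 3-s stride (exactly 15000 samples; start index
`round(start·4000)`), the standard analysis length for computerised fetal
non-stress tests. Consensus labelling expects three per-second annotation
tracks: a segment spans whole seconds `floor(start) .. floor(start+3.75−ε)`
(the trailing 0.75 s inherits its containing second's label); any annotator
switching class mid-segment rejects the segment, otherwise 3/2/1/0 good votes
map to good / mostly-clean / mostly-noisy / poor.

## Empirical mode decomposition

Classical EMD by sifting: cubic-spline envelopes through maxima/minima with
mirror extension of the two nearest extrema at each end; per-iteration stop
when the Cauchy criterion `Σ(h_{k−1}−h_k)²/Σh²_{k−1} < 0.2` is met **and** the
candidate satisfies the defining count property (|#extrema − #zero-crossings|
≤ 1), capped at 100 iterations. The count requirement matters: the Cauchy
criterion alone leaves occasional components violating the IMF property by
several counts. Decomposition stops when the residual is monotonic or has
fewer than four extrema (spline envelopes undefined). Only the first four
IMFs are used downstream. Reconstruction (`Σ IMFs + residual = input`) is
exact by telescoping.

## Beat detection

Per 4-s window (3-s stride → 1-s overlaps):

1. Sift the window; for each of the first four IMFs build an amplitude
   envelope (cubic spline through the IMF's peaks, then a zero-phase 4th-order
   Butterworth low-pass at 25 Hz).
2. Detect envelope peaks by the positive-first-derivative /
   negative-second-derivative rule, discard peaks below 10 % of the envelope's
   95th percentile, and greedily merge peaks closer than the minimum
   physiological interval `60/bpm_max` (keeping the larger peak — with two
   Doppler bursts per cycle this locks onto the stronger systolic burst).
3. Score each IMF by the SD of its gated peak-to-peak intervals divided by
   peak salience (mean peak height / envelope median) and keep the argmin
   (ties → lowest IMF index).

Two of these choices deserve comment because the plain textbook rule fails on
realistic broadband noise. (a) Without the gating and the salience
normalisation, a noise-dominated low-frequency IMF produces a dense train of
small, *regularly spaced* envelope wiggles whose raw PPI SD undercuts the
cardiac IMF; measured on 342 synthetic windows, the salience-normalised metric
removed all gross misselections. (b) Peaks within 0.1 s of a window edge are
deferred to the overlapping neighbour window, because spline envelopes are
distorted at chunk boundaries.

Window peak lists are stitched: in each 1-s overlap, peaks closer than
0.2 × the local median PPI are merged keeping the earlier; a peak seen by only
one window survives. The merged train is gated to 90–210 bpm (short intervals
merged greedily; an interval longer than `60/bpm_min` is subdivided by the
local median PPI, i.e. missed-beat interpolation) and finally cleaned by the
moving 5-PPI rule: sliding left to right, if the middle interval differs from
the mean of the other four by more than 20 % of that mean it is set to that
mean. The correction relocates only the middle interval's trailing beat (the
next interval absorbs the shift). Rebuilding all beats by cumulative summation
instead would translate the entire tail after a single replacement; on
synthetic data with known beats that one change moved recall from ~0.1–0.4 to
≥ 0.95, so the local form is used.

## Templates and SQIs

The CWT uses the order-2 complex Gaussian mother
`ψ(u) ∝ (4u² + 4iu − 3)·e^{−u²−iu}`, unit L2 energy, evaluated at one scale
(default 8 samples at 4 kHz, placing the response maximum a few hundred Hz —
the wall/valve band; the scale is a config knob because reasonable readings of
"the third scale" differ). Magnitudes are computed over 25-s windows and
concatenated. The envelope of the magnitude (spline through local maxima,
25 Hz zero-phase low-pass) is cut at beat locations; each cycle is normalised
to zero mean and unit SD; zero-variance cycles (dropouts) are discarded.

Templates tile the record in 15-s windows from t = 0; a cycle belongs to the
window containing its onset. `L` = rounded mean cycle length of the window;
cycles are truncated or tail-zero-padded to `L` and averaged pointwise
(≥ 2 cycles required). The update pass re-averages only cycles with Pearson
`r ≥ 0.6` against the initial template and requires at least 20 % of cycles to
pass (boundary inclusive); otherwise the window borrows the previous window's
updated template, else the next window's; with neither available the window is
template-less and its beats score 0 — conservative for quality screening. The
fallback is resolved in a second pass over all windows so it does not depend
on processing order.

The four per-beat SQIs are Pearson correlations with the window template,
negatives clipped to 0:

- **SQI1** — cycle truncated to `L` or zero-padded at the tail (cycles are
  onset-aligned, so padding at the end).
- **SQI2** — cycle linearly resampled to exactly `L` points.
- **SQI3** — cycle warped onto the template time base by DTW (steps
  {(1,0),(0,1),(1,1)}, boundary-anchored, squared-difference cost; the aligned
  value at template index j is the mean of cycle samples matched to j).
- **SQI4** — as SQI3 with the weighted-DTW cost `w(|i−j|)·(x_i−t_j)²`,
  `w(d) = 1/(1+e^{−g(d−L/2)})`, `g = 0.02`. The logistic pivots at `L/2`:
  larger `g` penalises long-range warps and relaxes near-diagonal ones, so the
  optimal cost is *not* monotone in `g`; what holds (and is tested) is that
  `w` is monotone in the lag and that a steep penalty shrinks the maximum path
  lag. At `g = 0` the weight is constant and SQI4 equals SQI3.

A segment's SQI (per index) is the median over the beats whose onset falls in
the segment; a segment without beats scores 0 on all four.

## Sample entropy and PSD ratio

Sample entropy uses `m = 2`, tolerance `r = 0.1·SD`, computed on the raw 4 kHz
segment: with templates `x[i:i+m]`, `i = 0..N−m−1` (the same index set for
lengths m and m+1), `B` counts unordered pairs within Chebyshev distance `r`,
`A` the same for length m+1, `H_s = −ln(A/B)`. Self-matches are excluded. A
constant segment returns the sentinel 0; `A = 0` is capped at
`ln(B·(N−m−1))` to stay finite. Counting uses a KD-tree; tests verify exact
count agreement with a naive O(N²) oracle.

The PSD ratio is band power in 160–660 Hz over total power (DC excluded),
estimated by Welch's method with Hann-tapered 1-s windows at 50 % overlap.
The band itself can be re-derived by `optimize_band`: a grid search (lower
edge 80–400 Hz, upper 580–900 Hz, 20-Hz steps) maximising the earth-mover's
(1-D Wasserstein-1) distance between the good- and poor-class ratio
distributions; ties prefer the widest band.

## Classifier and validation

RBF-SVM with `k(x_i,x_j) = exp(−|x_i−x_j|²/2σ²)` (scikit-learn SVC with
`gamma = 1/2σ²`). Hyperparameter grids are config-held exponent lists,
defaults `C ∈ 2^{−3,−1,1,3,5}` and `σ ∈ 2^{−5,−2,1,2}`; the σ list is stated
in the config because the printed sequence it derives from is not arithmetic —
both lists are data, not code. Grid search maximises inner stratified
five-fold CV accuracy; ties prefer the smallest `C`, then the largest `σ`
(simpler, smoother models).

Bootstrap cross-validation operates on subjects: per repetition, subjects are
permuted into five folds (re-drawn if a fold lacks a class); each fold draws
60 segments per class with replacement from its own subjects' segments;
training uses the union of the other folds' draws, z-scored with statistics of
the training rows only; the repetition's accuracy/sensitivity/specificity are
medians over folds, and the result is the distribution over repetitions.
Sensitivity is good-class recall, specificity poor-class recall; balanced
draws make fold accuracy exactly their mean. One master seed derives all
per-repetition streams, so runs are bit-reproducible. The train/test subject
split ranks subjects by good-segment count (descending, ties lexicographic)
and alternates; an odd last subject joins the side with fewer total segments.

`P(good)` is a Platt-style logistic calibration of the (good-oriented) SVM
decision value, fitted on training data with Platt's regularised targets so
separable data does not diverge. The probability threshold is re-derived per
training run as the cut maximising training balanced accuracy (ties → closest
to 0.5); it is stored in the model record. Intermediate classes (mostly
clean / mostly noisy) are evaluated against that threshold without retraining.
An exhaustive 2⁶−1 feature-subset sweep (`feature_subset_search`) ranks
subsets by median CV accuracy, then specificity.

## Synthetic data

`SynthSpec` states the world: duration (default 60 s), mean fetal heart rate
140 bpm with 5 bpm Gaussian beat-to-beat variability, two Gaussian-windowed
bursts per cycle (systolic at the beat, width 15 ms; diastolic at 42 % of the
cycle, amplitude 0.55, width 12 ms) carried by noise band-passed to
160–660 Hz, additive broadband noise at the stated SNR (default 10 dB,
optionally per second), and artifacts (alternating dropouts and 5–30 Hz
movement transients) at a stated rate. Three simulated annotators share the
latent per-second quality (local SNR in dB, artifact seconds heavily
penalised) and threshold it at 5 dB with offsets −1.5/0/+1.5 dB, so
intermediate SNR produces genuine disagreement and all four consensus classes.
Burst widths and the 5-dB quality threshold are the package's own choices of
realistic values; they were fixed before the acceptance runs and are not
tuned.

What the generator does **not** model: physical insonation (angle, depth,
speckle), maternal heart and placental sounds, probe-movement spectra, or
annotator biases beyond a threshold offset. A green end-to-end test therefore
establishes that the pipeline recovers planted structure under statistical
mimicry of DUS audio — not clinical performance. The published clinical
figures for this method (≈86 % median CV accuracy on hand-labelled hospital
recordings) come from a private dataset and are not reproduction targets here.

## Numerical choices and degenerate inputs

- Pearson correlation returns 0 for zero-variance inputs everywhere.
- Cycles with SD ≤ 1e−10 × their magnitude are treated as zero-variance.
- DTW backtracking prefers the diagonal on cost ties; any optimal path yields
  the same cost, and the tests assert optimality of the returned path rather
  than a particular tie-break.
- `sift` requires ≥ 16 samples; `sample_entropy` ≥ m+2; both raise otherwise.
- Segment counts follow `floor((duration − 3.75)/3) + 1`; a record shorter
  than one segment yields an empty list with a warning.
- Model files are plain JSON (scaler, good-oriented dual coefficients, Platt
  coefficients, threshold); reloaded models reproduce probabilities to 1e−8.

## Known limitations

- Beat detection assumes a quasi-periodic rhythm in 90–210 bpm; arrhythmic
  or heavily intermittent signals degrade the PPI-SD selection metric.
- The 5-PPI correction repairs isolated interval outliers; clustered errors
  (several adjacent bad intervals) are only partially repaired.
- Sample entropy on 15000 samples with r = 0.1·SD is sensitive to heavy
  low-frequency artifacts; the PSD ratio partially compensates.
- Template length L is a single per-window constant; strong heart-rate drift
  within 15 s blurs templates.
- With very small cohorts (< 5 subjects) the subject-level five-fold CV is
  not meaningful; the tools require ≥ 2 subjects and the tests use ≥ 6.
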