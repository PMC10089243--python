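# Methods

`serialdep` implements a complete analysis chain for sensory-history biases
in continuous-report working memory: behavioral serial-dependence statistics,
spatiotemporal multivariate decoding of orientation from epoched
multichannel recordings, neural asymmetry/bias scores, cross-decoding of
prior stimuli, and permutation inference — together with a synthetic-data
generator that plants known biases so every estimator has a
parameter-recovery test surface.

## Orientation circularity

Orientations are 180°-periodic. All circular statistics operate on the
doubled-angle circle (angles × 2 live on an ordinary 360° circle) and signed
differences are mapped to (−90°, 90°]. Exact antipodes (difference of
exactly 90°) map to +90°; this tie-break is defined once in
`circstats.signed_diff` and inherited everywhere.

## Synthetic experiments

The generator emulates a two-grating delayed-report task: per trial up to
two gratings with independent uniform orientations in [0°, 180°), a cue
(report-first / report-second) crossed with item count (one / two), trials
in blocks of 50 by default, 400 trials per session. On one-item trials only
the cued grating is shown. Previous-trial orientations carry over within a
block and are undefined on each block's first trial.

**Responses** follow the classic three-component mixture: with probability
`p_target` the response centers on the target, with `p_swap` on the
same-trial nontarget (reallocated to the target on one-item trials, where
no swap is possible), and with `p_guess` it is uniform. Von Mises noise with
concentration κ (doubled-angle circle; κ = ∞ means noiseless) is added to
the non-guess components. Target responses additionally receive a
difference-of-Gaussians (DoG) systematic bias

    DoG(Δ; a, w) = a · (Δ/w) · exp(0.5 − Δ² / (2 w²)),

normalized so the peak bias is exactly `a` degrees at Δ = w: an *attractive*
pull toward the previous trial's target (default a = 1.5°, w = 30°) minus a
*repulsive* push away from the same-trial nontarget (default a = 1°,
w = 25°). The DoG form is a modeling choice for the generator — the analysis
operators are agnostic to the true curve shape, so recovery tests validate
the estimators, not a specific bias law. Default mixture weights
(0.9 / 0.067 / 0.033) and κ = 8 (error SD ≈ 10° within the target component,
mean absolute error ≈ 12° overall) are in the range typically reported for
orientation working memory. Note that at these defaults the *within-trial*
behavioral bias curve is dominated by swap responses, which masquerade as
attraction toward the nontarget — a genuine property of mixture-generated
data worth remembering when interpreting the within-trial summed bias.

**Epochs** are trials × channels × time arrays. Each presented grating
contributes an orientation-tuned pattern
`snr · [cos(2θ_enc)·u + sin(2θ_enc)·v] · h(t)` with fixed random orthonormal
channel vectors u, v, under a piecewise-linear envelope h(t) rising from
50 ms to a peak at 150 ms and decaying to zero at 700 ms (envelope shape is
irrelevant to the decoder, which is fit per time point). Two planted neural
effects are available:

* an **encoding shift**: θ_enc = θ + s·`repulse_shift`, with s = −sign(Δ)
  when the absolute inducer distance falls inside `shift_range` — a
  repulsion of the encoded orientation away from the inducer (negative
  `repulse_shift` values yield attraction);
* a **lingering trace** of the previous target with amplitude `linger_amp`
  (negative = sign-reversed suppression), which both drives negative
  cross-decoding and induces an apparent repulsive asymmetry in current-item
  decoding — the mechanistic coupling the cross-decoding correlation test
  exercises.

Noise is i.i.d. Gaussian per sample (default SD 1 against pattern amplitude
`snr` = 1). The generator does not emulate a realistic forward model, 1/f
noise, artifacts, or head movement; passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
structure, not robustness to real recording confounds. Channel positions
lie on a Fibonacci sphere so searchlight neighborhoods are spatially
coherent; `n_pattern_channels` can confine the tuned pattern for
localization tests.

## Behavioral statistics

**Performance-bias curve.** The signed report error (response − target) is
expressed as a function of the signed inducer-target distance Δ
(inducer − target; binning is by *target* orientation, never by response,
to avoid confounding with the oblique bias). Distances are sorted into 64
equally spaced, overlapping bins; each bin keeps the 25% of trials nearest
its center (wrapped distance, ties broken by trial order; "25%" rounds to
nearest). Bin centers are offset half a step so none falls on 0° or ±90°
and mirror pairs are exact. Error signs are flipped in negative-Δ bins and
mirrored bins averaged, folding the curve into 32 bins over absolute
distance; the **summed bias** (sum of the folded means, degrees) is the
scalar attraction(+)/repulsion(−) index. Because each bin averages over a
±22.5° window of Δ (quantile binning under uniform Δ), the expected bin
value is the *window average* of the underlying bias curve, not its value
at the center; recovery tests use the closed-form window-averaged DoG as
the oracle. Between-trial analyses drop the first trial of each block.

**Mixture model.** EM fit of
`p_T·VM(e_T; κ) + p_S·VM(e_NT; κ) + p_G/180` on the doubled-angle circle,
with the swap term dropped for trials lacking a nontarget. Initialization is
a method-of-moments κ and weights (0.8, 0.1, 0.1); the κ M-step uses the
fixed-zero-mean cosine moment inverted through A₁ (Best–Fisher start plus
Newton refinement), which keeps the EM log-likelihood exactly monotone.
κ is floored at 1.0 (at init and in the M-step): a von Mises with κ → 0 is
indistinguishable from the uniform guess component, so the unconstrained
model is unidentified on near-uniform data; the floor routes such data to
the guess component while leaving realistic fits (κ ≳ 2) untouched.
Non-convergence after `max_iter` returns the best fit with a flag rather
than raising. Per-trial posterior responsibilities are returned as
single-trial weights.

## Decoding

Features at time t concatenate all channels over the trailing window
(t − window_len + 1 … t) — 306 sensors × 30 samples = 9180 dimensions at
full scale — after multiplying magnetometers by 20 to match gradiometer
magnitudes. No baseline correction is applied, deliberately preserving
slowly varying traces of earlier events. Per time point and fold, PCA
keeping 90% of the *training* variance de-noises the data (fold-pure to
exclude any leakage), then a 10-class LDA (eigen solver; analytic shrinkage
of the within-class covariance toward its diagonal, needed for stability at
desk-scale trial counts) projects data into the 9-dimensional discriminant
space. Class evidence is the negated Euclidean distance of each test trial
to the training class means, centered across classes (any monotone
likelihood mapping preserves the downstream cosine statistic's sign; the
centered-linear choice keeps it linear). Folds are 10-fold stratified on
class, seeded, and fixed across time points.

Evidence re-aligned so offset 0 is the bin containing an alignment
orientation gives representational-similarity curves over offsets
{−72, …, 72, 90}°; the cosine convolution
`mean_k ev(k)·cos(2·offset_k)` yields one evidence scalar per trial and
time point. Aligning to the previous trial's target instead of the
presented orientation implements cross-decoding without retraining. The
searchlight repeats the whole analysis on each sensor plus its 47 nearest
neighbors (Euclidean distance on sensor positions) and maps window-averaged
cosine evidence per sensor.

## Neural asymmetry and bias scores

Trials are selected by the inducer-presented distance: within-trial inducer
(the other grating) with |Δ| strictly inside (10°, 50°), between-trial
inducer (previous target) with |Δ| in (0°, 60°]; Δ = 0 is always excluded
(no sign). One geometric convention is used throughout: *clockwise* denotes
the negative-offset side, so the CW evidence bins are offsets −72…−18
(CCW: 18…72; offsets 0 and 90 belong to neither set) and CW-inducer trials
are those with Δ < 0. Per trial the asymmetry is mean CW-bin minus mean
CCW-bin evidence; per sign group it is averaged over trials, and the
**neural bias score** is the CW-group minus CCW-group asymmetry, averaged
over the 250–600 ms analysis window (where stimulus decoding is reliable).
Attraction comes out positive and repulsion negative — verified by
injected-shift simulation rather than assumed, since bin labels and inducer
signs only fix the convention jointly.

## Permutation inference

* **Sign-flip shuffle null**: each iteration flips every trial's Δ sign
  independently (per subject), recomputes the subject statistic (summed
  bias, or the CW/CCW group difference of per-trial asymmetries — no
  re-decoding needed) and averages across subjects. The null is z-scored;
  the observed statistic's z and its two-tailed normal p are the headline
  values, with the empirical (b+1)/(m+1) permutation p reported alongside
  (never exactly zero). Default 10,000 iterations; desk-scale analyses in
  the pipeline and tests use fewer (stated per use).
* **Cluster-based permutation test** (one-sample, 1-D): pointwise t against
  zero, threshold at the t quantile for α = 0.05 (per tail, configurable),
  clusters are maximal contiguous supra-threshold runs of one sign, mass is
  the summed t, and the null is the maximum absolute cluster mass under
  random per-subject sign flips. Zero-variance points are excluded with a
  warning. The implementation is cross-checked against MNE-Python's
  `permutation_cluster_1samp_test` in the test suite.
* An **alignment-shuffle null** for decoding-evidence window means permutes
  the alignment orientations across trials, reusing the fitted evidence —
  a cheap chance-level reference for single-session decoding.

## Simulation sizing

Recovery and calibration tests run at desk scale, sized from pilot
standard-error estimates so the prescribed contrasts are resolvable on a
single CPU: behavioral recovery uses n = 4000 trials (bin-mean Monte-Carlo
error ≈ 0.03°, well under the 0.1° tolerance); decoding checks use 16–32
channels, 240–400 trials, 100 Hz sampling with features decimated inside
the 250–600 ms window; shift-recovery contrasts average 10–20 simulations
per condition (between-condition gaps ≳ 0.15 evidence units against SEs
< 0.01); type-I calibration uses 300–500 null simulations with 250–1000
permutation iterations each. Default generator parameters are never tuned
per test; tests vary only the bias parameters they are designed to recover.

## Known limitations

* The generator's sensor model is a two-dimensional tuned subspace with
  white noise; decoding performance numbers are not comparable to real MEG.
* The mixture model assumes a shared κ across components and a fixed zero
  mean; systematic biases inflate κ slightly rather than shifting means.
* The cluster test is 1-D only (time or angular-distance axis); no TFCE,
  no 2-D clustering.
* Searchlight maps use raw sensor positions and Euclidean neighborhoods; no
  forward-model-aware channel grouping.
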