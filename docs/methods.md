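# Methods

This note documents the models, defaults and numerical choices behind
`bistream`, and what its synthetic validation does and does not establish.

## Stimulus and percept model

The paradigm is a continuous auditory stream of A-B-A tone triplets
(A = 1414 Hz, B = 1000 Hz; 100 ms tones, 50 ms inter-tone gaps, 200 ms
silence), one 600 ms *trial* per triplet, delivered in blocks
(defaults: six 5-minute blocks of 500 trials at a 600 Hz sampling rate).
Blocks are generated as independent contiguous segments and epochs never
cross block boundaries.

Percept dynamics are a two-state renewal process: dominance durations are
i.i.d. lognormal(μ_log, σ_log) seconds and the states strictly alternate.
This matches the universally observed right-skewed, log-normalizable
dominance-duration distributions of bistable stimuli; a Markov chain with
self-transitions adds parameters without changing any tested quantity and
was rejected for simplicity. Defaults μ_log = ln 8, σ_log = 0.4 give a mean
dominance near 9 s, inside the wide between-listener range for streaming
stimuli (median dominance can span roughly 2–100 s); both parameters are
per-process configurable. The final segment is truncated at the recording
end and contributes its censored duration uncorrected.

The neural ground truth is an auditory-like evoked response (Gaussian
deflections ~100 ms after each tone onset) emitted by each active source on
every trial, plus an *additive* percept-dependent offset at designated
effect sources, confined to a latency window (default 250–267 ms after
triplet onset). An additive rather than multiplicative effect is the
simplest mechanism consistent with an additive difference time course at
the group level. Sources project to sensors through a fixed-orientation
lead field — by default random Gaussian columns normalized to unit norm
(any supplied matrix is accepted; realistic head modelling is out of
scope) — with additive white Gaussian sensor noise.

Button reports lag true perceptual switches by a truncated-Gaussian motor
latency (mean 400 ms, SD 100 ms, floored at 0). Around each realized button
switch an ambiguous episode may occur: a release gap ("none", probability
0.2) or an overlap of both buttons ("both", probability 0.1), with duration
|N(0.3 s, 0.1 s)|. These values are not measurements; they produce a
plausible minority of ambiguous trials (~5–10%) to exercise the exclusion
logic.

## Preprocessing

Order is fixed: filter → downsample → label → exclude → epoch → baseline →
average.

- Filters: separate 5th-order Butterworth high-pass at 0.1 Hz and low-pass
  at 30 Hz, applied forward–backward (zero phase; effective order doubles).
  Two separate filters rather than one band-pass design; 600 → 300 Hz
  downsampling is plain decimation because the 30 Hz low-pass already
  prevents aliasing (non-integer ratios fall back to polyphase resampling
  with a logged warning).
- Labelling: a trial is "gallop"/"segregated" only if that button state is
  held for the entire 600 ms window; anything else (none, both, a switch
  mid-trial) is ambiguous.
- Switch exclusion: at each state change between consecutive unambiguous
  trials, `n_exclude` trials on each side are dropped (default 1 — the
  literal reading of "immediately before and after"; configurable since the
  convention is ambiguous).
- Baseline: the stimulus is continuous, so there is no silent pre-stimulus
  period; the default baseline is the whole-epoch mean per trial and
  channel, configurable to any sub-window.
- Robust averaging: iteratively reweighted mean with bisquare weights
  w = (1 − (r/(k·MAD))²)² for |r| < k·MAD (else 0), k = 4.685, where r is
  the residual against the current estimate and MAD the across-trial median
  absolute residual per channel and timepoint; iterate until the estimate
  moves less than 1e-6 of the data scale or 20 iterations. Where the MAD
  vanishes (identical trials) exact agreement gets weight 1; timepoints
  with all-zero weights fall back to the across-trial median with a
  warning.

Note the 30 Hz low-pass attenuates the 17 ms planted boxcar to ~0.87 of its
amplitude and smears it in time — by design, not error. Recovery tests
therefore compare the pipeline's evoked difference against the ground-truth
difference passed through the same filters.

## Feature reduction

Balanced trials (majority percept subsampled to the minority count — either
"spread": evenly spaced over the acquisition, deterministic; or
"sequential": first n) are pooled across both percepts and reduced without
reference to the labels: SVD of the channels × (trials·samples) unfolding
gives 5 spatial modes; SVD of the spatially projected, pooled
(trials·modes) × samples matrix gives 5 temporal modes; each trial becomes
the 5 × 5 coefficient matrix flattened spatial-major (25 features). Bases
are orthonormal; the SVD sign ambiguity is fixed by making each basis
vector's largest-magnitude element positive, so results are exactly
reproducible. Whether the original reduction used single trials or
averages is ambiguous; pooled single-trial data is used here (the
alternative only changes the basis-estimation noise). Features are not
z-scored by default. Single-source (ROI) analyses skip the spatial step and
use 5 temporal modes only.

## Canonical variate analysis

For features X (n × p) and a binary class factor (q = 1 contrast), W and B
are the within- and between-class SSP matrices; canonical values are the
generalized eigenvalues of W⁻¹B (at most min(p, q) nonzero);
Wilks' Λ = Π(1+λᵢ)⁻¹ = det(W)/det(W+B). The default p-value is Bartlett's
approximation χ² = −(n − 1 − (p+q+1)/2)·ln Λ with p·q df; Rao's exact F,
(1−Λ)/Λ · (n−p−1)/p on (p, n−p−1) df, is exact under normality for q = 1
and reduces to the pooled two-sample t-test at p = 1 — both are computed and
stored, and the small-sample correction term is the conventional one (the
exact variant used by any particular implementation may differ in that
term, which is why both transforms are reported side by side). A singular W
is ridge-regularized by 1e-10·trace(W)/p with a warning. Per-subject
screens use α = 0.05 uncorrected, matching the convention of reporting
single collapsed tests per subject.

## SVM decoding

`SVC` with C = box constraint; RBF kernel
K(x,x′) = exp(−‖x−x′‖²/(2s²)) with kernel scale s (so sklearn's
γ = 1/(2s²) — stated explicitly because conventions differ). Accuracy is
the mean over 100 repetitions of stratified 10-fold cross-validation
(stratification preserves the enforced class balance within folds; fold
assignment is reshuffled each repetition from a named seed). The binomial
test uses k = round(accuracy·n) successes out of n trials against chance
0.5 (balanced classes), one-sided — anticonservative given the dependence
between folds and repetitions, which is why a label-permutation p-value is
also provided. The RBF grid search is two-stage: 9 × 9 log-spaced over
kernel scale 1e−3…1e15 and box constraint 1e−3…1e9, one 10-fold CV per
pair with a shared fold assignment; stage 2 spans ±1 stage-1 grid step
around the winner (clipped at the stage-1 range, logged), fresh 9 × 9 grid;
ties prefer the lowest box constraint then the lowest kernel scale
(simplest model). SVM fits carry a 1e6 iteration cap so degenerate grid
corners terminate.

## Source analysis

Minimum-norm inversion J = Lᵀ(LLᵀ + λI)⁻¹Y, applied per trial after the
pooled sensor data are reduced to their top 16 temporal SVD modes. The
default λ = trace(LLᵀ)/(n_sensors·SNR²) with SNR = 3 — a standard
signal-to-noise prior; no value was prescribed. "Posterior variance" is the
variance of a source's reconstructed time course pooled over retained
trials and samples (pooled rather than per-condition; the per-condition
alternative changes only the ranking metric). Unconstrained analyses take
the top-5 posterior-variance sources greedily with a 15 mm exclusion zone;
ROI analyses take the max-variance source inside a sphere (default radius
10 mm — unspecified in the source literature, configurable per ROI) at the
a-priori MNI centers rAC (54, −14, 11), lAC (−49, −20, 5) and rPIPS
(34, −72, 38); the rPIPS z-coordinate is typeset ambiguously in the
literature table it derives from and is exposed as configuration. The
multi-ROI screen applies the same single-source chain per ROI from a
user-supplied table (name, x, y, z, radius CSV); the specific 34-region
atlas concatenation is not reproduced.

## Group analysis

Per subject, one PCA over right-temporal sensors of the two evoked
responses *concatenated in time* (a single shared spatial component, so the
two component time courses live in the same basis; a separate-per-state
mode is available since the convention is ambiguous). Right-temporal
sensors are selected geometrically on synthetic arrays (x > 2 cm,
|y| < 5.5 cm) or by an explicit channel-name list on real data. The
gallop − segregated component difference (180 samples, 0–600 ms) enters a
pointwise one-sample t-test; runs of |t| above the two-sided p < 0.005
threshold form clusters scored by Σ|t| (cluster mass); family-wise error is
controlled at 0.05 via the max-cluster-mass null over 1000 random
whole-subject sign flips (which preserve each subject's temporal
autocorrelation). Sign-flip permutation replaces parametric random-field
cluster inference deliberately: it is assumption-free and its calibration
is directly testable by simulation (measured family-wise false-positive
rate 0.05 with a [0.03, 0.08] acceptance band). Cluster bounds are
half-open [start, end) in ms, sample i ↦ i/300 s. Fewer than 100
permutations are refused (unstable null).

## Validation conditions and problem sizes

The full acquisition (274 sensors, 6 × 500 trials at 600 Hz) is the
generator default, but validation and the acceptance script run a scaled
cohort chosen to exercise every code path at simulation sizes appropriate
for routine testing: 14 subjects × 500 trials (two 2.5-minute blocks),
64 sensors, a 64-source grid containing the rAC/lAC/rPIPS positions, active
sources at rAC and lAC with the percept effect at rAC only, sensor noise
SD 1. The effect amplitude (0.55, source units) was fixed once so that this
cohort sits in the regime characteristic of the paradigm — per-subject CVA
significant in a majority of subjects while single-trial accuracies stay in
the 50–65% band — and is not adjusted thereafter. Statistical calibrations
use 1000 null simulations (CVA type-I error at n = 200, p = 25) and
200 null cohorts × 1000 permutations (cluster FWE).

## What the synthetic data do not show

- The lead field is random Gaussian, so sensor topographies carry no
  geometry: "right-temporal" sensors bear no privileged relation to the
  right-hemisphere sources, and the *sign* of each subject's first-PC
  difference is arbitrary. Group-level sign consistency — which real
  anatomy provides — is therefore absent end-to-end, and the group cluster
  test is validated on directly simulated difference time courses instead.
- White sensor noise and a single fixed evoked waveform omit correlated
  background brain activity, physiological artifacts, head movement and
  between-trial waveform variability; passing tests demonstrate the
  statistics and bookkeeping, not robustness to those nuisances.
- Dominance durations are stationary and independent; real listeners drift,
  adapt and occasionally exercise volitional control.
- Overlap of successive evoked responses (each trial begins 350 ms after
  the previous triplet's last tone) is present in the simulation but no
  deconvolution is attempted, matching the analysis being modelled.

## Degenerate inputs and tie-breaks

Zero-variance duration samples return an undefined (NaN) normality marker;
all-zero robust weights fall back to the median; SVD rank deficits reduce
the requested mode count with a warning; CVA refuses n ≤ p + 2; grid-search
ties prefer the simplest model; source selection asserts the pairwise
15 mm separation invariant on every call.
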