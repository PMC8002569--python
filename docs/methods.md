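# Methods

## Scope and pipeline

`somnowave` scores 30-second EEG epochs into the six Rechtschaffen &
Kales classes (W, S1–S4, REM). The chain is: epoch ingestion (EDF +
plain-text hypnogram, or the synthetic generator) → design of a
two-channel biorthogonal wavelet filter bank → five-level periodized
decomposition → ℓ1/ℓ2/ℓ∞ norms of the six sub-bands → optional class
balancing → bagging over CART trees → repeated stratified 10-fold
cross-validation with confusion-matrix, κ, F1 and ROC reporting, plus
one-way ANOVA / Fisher-LSD feature screening.

## Filter-bank design

The analysis lowpass is constrained to the halfband form: odd length
L, center tap exactly 1/2, even off-center taps exactly zero (imposed
structurally, never approximated). Writing the zero-phase amplitude
A(ω) = 1/2 + 2 Σₖ aₖ cos((2k−1)ω) over the K = ⌊(c+1)/2⌋ free
odd-offset taps, the identity A(ω) + A(π−ω) = 1 holds for *any* a, so
the passband and stopband errors coincide and one stopband-energy term
E_s = ∫ over [π−ω_p, π] of A² suffices.

The design problem is

    min_a  α·E_s(a) + γ·(U_t(a) + λ·U_ω(a))
    s.t.   A(π) = 0  and  A^(2j)(π) = 0 for j = 1..R−1,

where U_t = Σₙ (n−c)² h[n]² is the (unnormalized) time spread and
U_ω = ∫₀^π ω² A(ω)² dω the frequency spread. Odd derivatives at π
vanish by symmetry, so R constraints buy 2R zeros at π. E_s is
assembled from closed-form cosine-product integrals; U_ω by trapezoid
quadrature on an 8192-point grid. All three terms are convex quadratics
in a and E_s (resp. U_t) is positive definite whenever α > 0 (resp.
γ > 0), so the equality-constrained minimum is unique and computed
exactly by a null-space reduction of the KKT system — the eigenfilter
family of designs realized as a direct linear solve. Uniqueness makes
the spectral tie-breaking rules that eigenvector formulations need
unnecessary here; degenerate reduced Hessians are rejected with a
diagnostic rather than resolved arbitrarily. With R = K the solution
coincides with the classical maxflat (Lagrange) halfband filters,
which is used as an exactness test at L = 7 and 11.

The synthesis lowpass f0 (odd length M, symmetric) is the solution of
linear constraints: p = h0∗f0 must satisfy p[d] = 1 and p[d±2k] = 0
(d = (L+M−2)/2), giving perfect reconstruction, plus V vanishing-moment
conditions Σₙ (−1)ⁿ nʲ f0[n] = 0, j < V (odd j are implied by symmetry).
Leftover degrees of freedom minimize the same α/γ objective on f0's
amplitude. Counting matters: f0 has (M+1)/2 free taps against
⌊d/2⌋ + 1 PR conditions plus ⌈V/2⌉ independent moment conditions, so
for L = 15 feasibility starts at M = 17. The default is **M = 25**,
which leaves two degrees of freedom for the objective: at the minimal
feasible length the filter is fully pinned by the constraints, its
stopband is poor (|F0| peaks ≈ 1.5), and the modulated highpass then
leaks roughly half of a single tone's energy into the neighbouring
sub-band; at M = 25 about 89 % of a band-center tone's energy lands in
its nominal sub-band, which the frequency-targeting tests assert.

Highpass filters are h1[n] = (−1)ⁿ f0[n] and f1[n] = ±(−1)ⁿ h0[n]; the
sign depends on the parity of d, so it is chosen by an explicit
one-level reconstruction self-test (relative error < 1e−8 on a seeded
random probe) rather than assumed. Banks serialize to self-describing
JSON at full double precision.

Defaults: L = 15, M = 25, ω_p = 0.4π, α = 0.95, γ = 0.05, λ = 1,
R = 2, V = 2 — all exposed in the experiment config; none of the
correctness properties depend on them.

## Transform

Boundary handling is periodic (circular convolution with the filter
aligned on its center tap). Rationale: 15 360 = 30·512 is divisible by
2⁵, so every level halves exactly and sub-band lengths are
deterministic (480, 480, 960, 1920, 3840, 7680); PR is exact rather
than approximate at the edges; and epochs are ~10³ times longer than
the filters, so the boundary choice cannot move the norm features.
The approximation branch keeps even-phase samples and the detail
branch odd-phase — the pairing under which the modulated highpass
cancels aliasing exactly. Sub-band ordering is coarsest-first: Sb-1 is
the level-5 approximation (0–8 Hz at 512 Hz, the delta/theta range
that dominates deep sleep), Sb-6 the level-1 detail.

## Synthetic EEG

Each stage is a mixture of band-limited Gaussian noise components
(delta 0.5–4, theta 4–8, alpha 8–13, sigma 12–16, beta 16–32, gamma
32–64 Hz; 4th-order zero-phase Butterworth band-passes on white noise,
edge transients trimmed) with stage-specific relative band powers and
a target RMS amplitude in µV:

| stage | band weights (δ, θ, α, σ, β, γ) | RMS (µV) |
|-------|--------------------------------|----------|
| W     | .05 .10 .45 .10 .25 .05        | 30 |
| S1    | .15 .50 .15 .05 .10 .05        | 40 |
| S2    | .25 .35 .10 .20 .08 .02        | 50 |
| S3    | .60 .30 .04 .03 .02 .01        | 65 |
| S4    | .85 .10 .02 .01 .01 .01        | 80 |
| REM   | .10 .45 .10 .05 .25 .05        | 35 |

The weights follow textbook sleep physiology — wake alpha/beta-rich
and small, S2 with spindle-band (sigma) power, slow-wave sleep
delta-dominant and large, REM a low-amplitude theta/beta mixture — and
reproduce the qualitative pattern seen on real data that coarse-band
norms are maximal in S4 and minimal in wake/REM. Absolute delta power
is strictly ordered S4 > S3 > S2 > REM by construction, which the
tests assert via periodograms. Seeding: every epoch draws its own
`numpy` generator keyed by (master seed, group, stage, epoch index,
channel), so cohorts are bit-reproducible and independent of
generation order, and channels are independent realizations.

What the generator does *not* emulate: transients (spindle bursts as
events, K-complexes, vertex waves), artifacts (eye movement, EMG,
electrode pops), stage-transition dynamics, inter-subject variability,
or any disorder pathophysiology. Consequently the near-perfect
synthetic classification scores validate the *plumbing* — that the
designed bank, norm features and classifier recover a known
stage-conditioned spectral structure — and say nothing about accuracy
on clinical recordings, where class overlap is the dominant
difficulty.

## Balancing

Random over-sampling with replacement (exact duplicates) below the
target and under-sampling without replacement above it, per class,
seeded. The per-group targets of the study database are shipped as
`STUDY_TARGETS` (healthy 1000 … all-combined 14 000). Default protocol
balances the whole dataset before cross-validation — this is what the
published epoch totals imply — with the documented caveat that
duplicated minority epochs can then appear in both training and test
folds, inflating CV scores; a `strict` mode balances inside each
training fold only and never resamples the test fold.

## Classifier

Bagging over CART trees (Gini impurity), full-size bootstrap samples,
no feature subsampling; scores are the mean of per-tree class
distributions and ties break toward the earliest class in the fixed
order (W, S1, S2, S3, S4, REM). The split budget is enforced as a leaf
cap (a binary tree with q leaves has q−1 internal splits);
`max_splits=0` degenerates to a majority stump. The estimators behind
the module surface are scikit-learn's `DecisionTreeClassifier` and
`BaggingClassifier`. A `learning_rate` field is accepted in configs
for compatibility and ignored with a log note — it is a boosting
parameter with no meaning for bagging. Hyperparameter tuning sweeps
(n_learners, max_splits) grids by k-fold misclassification rate, with
ties resolved toward fewer trees, then fewer splits; per-dataset
optima are re-derived rather than hard-coded because they depend on
the epoch count.

## Evaluation

Stratified k-fold (default 10) repeated over independent reshuffles
(default 5). Per-trial accuracy is the unweighted mean over folds;
trials aggregate as mean ± **population** standard deviation (ddof=0)
— the convention that reproduces reference trial tables exactly
(sample std does not). κ is computed per trial from the trial-pooled
confusion matrix and aggregated the same way; "κ error" is the
population std of per-trial κ. Stratification is used because S1
occupies ~4 % of real recordings and unstratified folds could miss it
entirely. Printed confusion matrices are pooled over all folds and
trials. "Per-stage individual accuracy" is one-vs-rest accuracy
((TP+TN)/total after collapsing to stage-versus-rest): that reading is
what reconciles per-stage figures in the mid-90s with much lower
row-diagonal percentages on unbalanced data. When reconstructing a
count matrix from a printed row-percent table, the diagonal cell keeps
its printed share exactly and off-diagonal cells absorb the rounding
remainder (largest-remainder allocation), so row totals are exact.

ANOVA screening ranks features by descending F (p-values underflow on
realistic sample sizes and cannot order features); per-stage spreads
are sample std. Fisher LSD is deliberately unprotected — all pairs are
always computed — but the result carries a flag when the omnibus test
did not reject. No multiple-testing correction is applied, matching
the screening-only role of the test.

## Numerical choices and degenerate inputs

- Halfband structural zeros and the center tap are set, not optimized:
  they are exact in floating point.
- PR conditions on f0 are linear and solved exactly; residual
  tolerance for declaring a constraint system consistent is 1e−8, with
  an explicit rank report on failure.
- Frequency-domain quadratures use ≥ 4096-point trapezoid grids
  (8192 in the design objective).
- Empty coefficient vectors have norm 0 by convention (logged);
  `tf_localization` of an all-zero filter is rejected.
- EDF writing quantizes to 16 bits over the per-channel data range
  (max round-trip error one quantization step); reading goes through
  MNE with unit restoration to µV.
- Hypnogram clock times are referenced to the first scored row and
  wrap across midnight; labels outside the six-class set (e.g. MT) are
  dropped and counted.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of
the protocol: unit tests use 256 Hz / 4-s epochs (1024 samples, still
divisible by 2⁵) with 50 epochs per stage; the end-to-end recovery
check uses the full 512 Hz / 30-s epochs with 100 epochs per stage
(600 epochs, 36 features) under 5×10-fold CV. Accounting and
balancing arithmetic run on the full 80 667-epoch reference
distributions, which involve labels only.

## Known limitations

- Synthetic validation only exercises spectral separability; clinical
  performance requires real recordings (EDF + hypnogram ingestion is
  provided for exactly that).
- Whole-dataset balancing before CV leaks duplicated epochs across
  folds; use `strict` mode when unbiased estimates matter.
- The EDF writer supports the plain 16-bit format with integer
  sampling rates and 1-s records — not EDF+ annotations.
- AASM five-class scoring (merging S3+S4 into N3) is not performed;
  labels follow the six-class R&K convention throughout.
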