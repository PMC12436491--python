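# Methods

This note documents the statistical model behind `fitbmi`, the synthetic
cohort generator it is tested against, the numerical choices made where the
design was genuinely open, and the limits of what the synthetic experiments
demonstrate.

## 1. Problem and data model

One record per participant: four fitness scores — 3,000 m run time (s),
pull-up count, sit-up count (1 min), 30 m × 2 shuttle time (s) — plus
height (cm) and weight (kg).  BMI = weight / (height/100)² is categorized
with WHO cut-points 18.5 / 25 / 30 into classes A (underweight),
B (normal), C (overweight), D (obese); intervals are half-open [lo, hi),
so a BMI of exactly 18.5 is class B.  The reference cohort structure used
throughout (class mix 355 / 4,991 / 1,270 / 82 = 6,698; pairwise Pearson
correlations such as r(BMI, 3,000 m) = 0.201, r(BMI, pull-ups) = −0.279)
describes a male university population; nothing in the code assumes
maleness beyond the marginal defaults.

## 2. Synthetic cohort generator

**Gaussian copula.**  A 5-variate latent normal (BMI, 3,000 m, pull-ups,
sit-ups, shuttle) is pushed through marginal quantile functions.  Marginal
defaults are anchored on the passing standards of the tests: 3,000 m ~
truncated normal (810 s, sd 60, [600, 1200]); pull-ups ~ rounded truncated
normal (10, 4, [0, 30]); sit-ups ~ rounded truncated normal (40, 8,
[0, 80]); shuttle ~ truncated normal (10.0 s, 0.8, [7, 14]); height ~
normal (172 cm, 6), drawn independently of the copula.  BMI has a
four-component truncated-normal mixture (means 17.5 / 21.5 / 26.5 / 31.5,
sd 1, truncated at the category bounds, outer bounds 14 and 45) whose
mixture weights equal the class proportions — so category labels are
exactly multinomial by construction, and weight is derived as
BMI·(height/100)².

**Correlation calibration.**  Pearson correlations survive monotone
transforms only approximately, so each latent pairwise correlation ρ is
solved such that the *post-transform* Pearson correlation equals the
target.  Writing each transform g(z) in the probabilists' Hermite basis,
cov(g_j(Z₁), g_k(Z₂)) = Σ_m m!·a_{jm}·a_{km}·ρ^m; the expansion (order 24,
160 Gauss–Hermite nodes) is evaluated inside a Brent root-find on
ρ ∈ (−0.9995, 0.9995).  This is deterministic — no simulation in the
calibration loop — and accurate to ≪ the ±0.03 Monte-Carlo band at
n = 6,698.  The assembled latent matrix is then repaired to positive
semi-definiteness (eigenvalues clipped at 1e-8, diagonal renormalized),
since only 10 pairwise values are specified and their joint feasibility is
not guaranteed.

**Anonymization jitter** (optional, off by default): uniform noise within
±0.5 cm on height and ±1 kg on weight, applied *after* label assignment,
mimicking a post-hoc anonymization step; the stored BMI column and labels
reflect the true pre-jitter values.

The cohort is modelled as a cross-section (one record per participant);
multi-year repeated measures are out of scope.  Calibration targets treat
BMI as a continuous value, not its ordinal category code.

## 3. Encoder

Input: z-scored scores in fixed order (3,000 m, pull-ups, sit-ups,
shuttle) — normalization statistics come from training data only.  This
order is a *feature* axis, not time; convolution over it captures
physiological couplings between adjacent tests.

- Convolutions: widths {2, 3}, 8 channels each, centered "same"
  zero-padding, ReLU, concatenated per position (feature dim 16).
  Centered padding keeps every attention position aligned with its test,
  which matters for interpreting the attention profile as feature
  importance.
- Attention: single-query additive scoring, s_t = vᵀ tanh(W h_t + b)
  (attention dim 16), α = softmax(s), pooled u = Σ α_t h_t.
- Heads: a linear softmax classifier over the four categories; one linear
  regression head per timed test and one 5-bin softmax head per count test
  (bins are training-set quintiles), all reading u.

**Loss.**  Total = class-weighted CE + multi-task + attention.

- *Class-weighted CE*: mean over the batch of w_{y_i}·(−log p_i),
  probabilities floored at 1e-12.  The pure loss function uses whatever
  weights it is given; in training the inverse-frequency weights
  w_i = 1/N_i are rescaled by N/4 so their expectation over the data is 1.
  Without the rescale a batch-*mean* with raw 1/N_i weights is ~N/4 times
  smaller than the task losses and the label signal vanishes; the rescaled
  mean equals the per-class-balanced cross-entropy and is batch-size
  invariant.  Ratios between classes — the part that shapes the decision
  rule — are untouched.
- *Multi-task*: (0.4, 0.2, 0.2, 0.2)-weighted sum of the four
  reconstruction losses (MSE for timed tests, CE for count bins).  The
  endurance run carries the largest weight as the strongest single BMI
  correlate.  Targets are the records' own normalized scores: the heads
  force the pooled feature to remain informative about each test.
- *Attention*: λ·mean((Σ_t α_t)·CE_i) with λ = 0.1.  As printed this is
  degenerate: softmax rows sum to 1 identically, so the term reduces to
  λ·mean CE and its gradient path through Σα is exactly zero.  It is
  implemented literally and kept testable in its unreduced form; no
  non-degenerate variant is invented.

**Optimization.**  Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3,
100 epochs, mini-batches of 256 with a seeded shuffle.  Mini-batching is
the default because full-batch at cohort scale gives only `epochs`
optimizer steps — far too few to train the attention path.  Everything is
seeded; identical config + data give bit-identical parameters and
history.  Gradients are hand-derived NumPy and verified against central
finite differences (step 1e-5, max relative error < 1e-4; in practice
~1e-6) — the step size matters because at 1e-6 the check is dominated by
floating-point cancellation on near-zero gradient entries.

## 4. Hybrid stage

The frozen encoder maps each record to its pooled feature u; the tree
stage trains LightGBM (200 rounds, depth ≤ 6, 63 leaves, learning rate
0.1, L2 leaf penalty 1.0, deterministic single-thread mode) on
x̃ = u ⊕ raw-normalized-scores with the same inverse-frequency sample
weights.  Concatenating the raw scores preserves both signals; a flag
(`include_raw=False`) reduces x̃ to the pooled feature alone.  The phrase
"feature weights imported into the tree model" has no standard meaning for
tree ensembles; the feature-*transfer* reading (learned representation as
tree input) is adopted.

## 5. Evaluation and benchmark

Accuracy is trace/total of the 4×4 confusion matrix; F_α is per-class
one-vs-rest (1+α²)TP / ((1+α²)TP + α²FN + FP) with α = 1, reported
weighted (headline; the dominant class makes micro ≈ accuracy) and macro.
A class with TP = FP = FN = 0 scores 0.

Protocols: a stratified 70/30 split (largest-remainder rounding per class,
seeded shuffle) and stratified 10-fold cross-validation; both are exposed
because both appear in practice, and the benchmark never asserts which
produced any published figure.  All models of a split see byte-identical
training records.  Registry: Gaussian naive Bayes, RBF-SVM, a small MLP,
LightGBM on raw scores, the encoder alone, and the hybrid; scikit-learn
baselines run with library defaults (the MLP unweighted — it accepts no
sample weights; recorded in the report manifest), all others with the
shared inverse-frequency weights.

## 6. What the synthetic experiments do and do not show

The generator reproduces the reference cohort's *pairwise linear*
structure and class mix.  It does not contain nonlinear dependence,
within-person longitudinal structure, measurement error, or cohort drift —
so passing tests demonstrate that the pipeline recovers planted structure,
not that real-cohort accuracies are attainable.  Published absolute
accuracies on the undeposited cohort are out of reach by design.

Two quantitative consequences of the default conditions are worth stating
plainly (both measured by oracle computation on the latent model, 200k
draws):

- The planted linear signal is weak — multiple R² of latent BMI on the
  four tests ≈ 0.09.  The Bayes-optimal *unweighted* classifier has plain
  accuracy 0.745, identical to always predicting the majority class.
- Under inverse-frequency weighting the optimal decision rule is the
  *balanced* one, whose plain accuracy is 0.218.  A model that trains well
  under the weighted loss therefore *loses* plain accuracy by design:
  weighted logistic regression scores 0.253, and the encoder head lands at
  0.21–0.26.  Weighted LightGBM does not fully converge to the balanced
  rule within its default rounds and keeps majority bias (≈ 0.53).  Plain
  accuracy consequently cannot rank a converged balanced model above a
  partially balanced tree baseline on this cohort; the stacking benefit
  (hybrid trees ≥ raw trees, 10/10 seeds) is the comparison the synthetic
  conditions can and do support.

The attention-recovery experiment plants a single strong dependence
(copula r(BMI, 3,000 m) = 0.8, all other cross-correlations zero,
n = 2,000) and checks that the trained encoder's mean attention peaks at
the 3,000 m position in ≥ 8 of 10 seeds.  Because kernels wider than 1
mix neighbouring positions, some attention mass always spreads to the
neighbour of the planted position; centered padding keeps the peak on the
correct test.

## 7. Problem sizes and determinism

Cohort-scale experiments use n = 6,698 (the reference size) with 10 seeds
for orderings and 20 seeds for calibration bands; the attention experiment
uses n = 2,000.  Every stochastic component (copula draws, splits,
shuffles, parameter init, LightGBM) is driven by an explicit integer seed,
and artifacts (model bundles, reports) embed the config and seeds needed
to regenerate them.

## 8. Known limitations

- The degenerate attention loss means λ effectively rescales the CE term;
  it is kept for fidelity, not because it adds information.
- Reconstruction task heads are one reading of under-specified auxiliary
  losses; alternatives (e.g. predicting held-out tests) would change the
  pooled feature's geometry.
- The generator's independence of height from fitness scores is a
  simplification; real anthropometrics correlate with strength tests.
- Integer marginals (pull-ups, sit-ups) are rounded truncated normals,
  which slightly attenuates their achievable correlation range; the
  calibration accounts for this, but extreme targets (|r| ≳ 0.95) would
  be unreachable and are rejected with an error.
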