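# fitbmi

Predicting **BMI categories from physical fitness test results** in male
university cohorts, with a hybrid deep-feature / boosted-tree classifier and
a calibrated synthetic-cohort generator.

Routine fitness assessments (a 3,000 m endurance run, pull-ups, sit-ups and
a 30 m × 2 shuttle run) correlate with body composition: slower endurance
times go with higher BMI, higher pull-up counts with lower BMI. `fitbmi`
turns that association into a four-class classification problem —
underweight (A, BMI < 18.5), normal weight (B, 18.5–25), overweight
(C, 25–30) and obese (D, ≥ 30; WHO cut-points, half-open intervals) — so
that BMI categories can be inferred, screened, or projected from fitness
data alone.

## The model

Each record's four scores form an ordered length-4 sequence
x = (3,000 m, pull-ups, sit-ups, shuttle).  The classifier is a stack:

1. **Multi-kernel 1D convolution.**  Parallel convolutions of widths
   {2, 3} (8 channels each, "same" zero-padding, ReLU) are concatenated
   per position into feature vectors H_t ∈ ℝ¹⁶, modelling local
   physiological couplings between adjacent tests.
2. **Attention pooling.**  Additive attention s_t = vᵀ tanh(W H_t + b),
   α = softmax(s), pools the sequence into u = Σ_t α_t H_t.  The weights
   α are the model's feature-importance signal.
3. **Composite loss.**  Training minimizes
   `L = L_multi-task + L_attention + L_class-weighted-CE`, where the
   cross-entropy is weighted by inverse class frequency w_i = 1/N_i
   (the cohort is heavily imbalanced: class mix ≈ 355/4,991/1,270/82),
   the multi-task term α·L₃₀₀₀ₘ + β·L_pull + γ·L_sit + δ·L_shuttle with
   (α, β, γ, δ) = (0.4, 0.2, 0.2, 0.2) reconstructs each normalized score
   from u (squared error for the timed tests, cross-entropy over quintile
   bins for the counts), and the attention term is λ·mean(Σ_t α_t · CE)
   with λ = 0.1.
4. **Boosted trees.**  The frozen encoder's pooled feature u (plus the raw
   normalized scores) becomes the input of a LightGBM multiclass ensemble
   ŷ = Σ_k f_k(x̃), trained with the same inverse-frequency sample weights.

Because no real cohort is distributed with the package, a **Gaussian-copula
generator** produces synthetic cohorts whose pairwise Pearson correlations
are calibrated (deterministically, via a Hermite-polynomial expansion and
root-finding on the latent correlation) to the reference cohort's published
structure — e.g. r(BMI, 3,000 m) = 0.201, r(BMI, pull-ups) = −0.279,
r(3,000 m, pull-ups) = −0.406 — and whose BMI marginal is a per-category
truncated-normal mixture reproducing the reference class mix exactly in
distribution.  The copula correlation between BMI and the tests is the
planted, learnable signal every downstream model is judged on.

## Worked example

```python
import numpy as np
import fitbmi as fb
from fitbmi.evaluate import run_benchmark

cfg = fb.default_config(n=6698, seed=42)      # reference-calibrated copula
cohort = fb.simulate_cohort(cfg)
r = fb.empirical_correlations(cohort)
print(f"r(BMI, 3000m)    = {r[0,1]:+.4f}")
print(f"r(BMI, pull-ups) = {r[0,2]:+.4f}")

report = run_benchmark(cohort.df, protocol="split70/30", seeds=[0],
                       models=("gbdt_raw", "encoder", "hybrid"))
print(report.to_table().to_string(index=False))
```

prints

```
r(BMI, 3000m)    = +0.2169
r(BMI, pull-ups) = -0.2987
   model  accuracy_mean  accuracy_sd  f1_weighted_mean  f1_macro_mean
gbdt_raw       0.533599          0.0          0.563915       0.280560
 encoder       0.241414          0.0          0.277429       0.192456
  hybrid       0.628671          0.0          0.620970       0.284913
```

The empirical correlations land within Monte-Carlo noise (±0.03 at
n = 6,698) of the calibration targets.  In the benchmark, feature transfer
helps: trees on attention-pooled encoder features (`hybrid`, 0.629) beat
trees on the raw scores (`gbdt_raw`, 0.534).  The encoder's own softmax
head (`encoder`, 0.241) converges to the *balanced* decision rule implied
by inverse-frequency weighting, which sacrifices plain accuracy for
minority-class recall on this weakly separable cohort — see
`docs/methods.md` for the analysis.

The same pipeline is available from the shell:

```bash
fitbmi simulate --n 6698 --seed 42 --out cohort.csv
fitbmi train    --cohort cohort.csv --out model/ --seed 0
fitbmi predict  --model model/ --cohort cohort.csv --out predictions.csv
fitbmi benchmark --cohort cohort.csv --protocol kfold10 --seed 0 --out report.json
```

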