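# Methods

## Model and procedure

The package implements two-stage Taguchi optimization (TSTO) of a
black-box objective `f(setting) → response ∈ (0, 1]`, larger-better, with
replicate noise. The procedure is:

1. **Screening.** All factors are placed on a coarse orthogonal array
   (canonically six 3-level factors on columns 2–7 of L18(2¹×3⁷)); every
   run is evaluated with `replicates` (default 3) independent replicate
   seeds.
2. **Analysis.** Replicates are condensed into a per-run mean and a
   per-run SN ratio; response tables and a pooled main-effects ANOVA are
   computed on each summary response; the best level per factor is the
   one maximizing the mean-response level mean (ties: higher SN level
   mean, then lower level index); the additive model predicts the
   response at the recommended setting; `r` confirmation runs (default 5)
   are judged against the prediction ± CI.
3. **Refinement.** Categorical winners are fixed; structural factors
   (e.g. network depth) whose winner is the lowest offered level are
   fixed rather than shrunk; every other numeric factor is re-leveled to
   winner ± half the coarse spacing (integer factors: step rounded half
   up, minimum 1). Extrapolation past the coarse range is allowed;
   optional per-factor bounds clip with a warning.
4. **Stage 2.** The refined factors go on L9(3⁴) when exactly three
   3-level factors advance; otherwise the smallest catalog array that
   fits, with a warning. Analysis and confirmation repeat, and a
   comparison table reports confirmed mean/SD/SN per stage plus the raw
   stage-2 − stage-1 differences.

Key assumptions: main effects are approximately additive over the
explored range (the additive prediction and the fractional design both
ignore interactions); replicate noise is exchangeable across runs; the
response orientation is larger-the-better (accuracy-like). Confirmation
pass/fail is advisory — it is recorded, never used for control flow,
because confirmation validates reproducibility rather than steering the
search.

## Statistical detail and conventions

- **SN ratios** use base-10 logarithms (decibel convention). LTB:
  `−10·log₁₀(mean(1/y²))`; STB: `−10·log₁₀(mean(y²))`; NTB:
  `−10·log₁₀(mean((y−m)²))`. The NTB "mean-plus-variance" form equals the
  summation form only with the population variance (denominator n); the
  summation form is primary and the identity is tested with ddof = 0.
  Ideal inputs (all-zero STB, on-target NTB) return +∞ rather than
  raising. Responses are floored at 1e−6 before LTB computation so the
  ratio stays defined.
- **Reported dispersion** is the sample SD (denominator n − 1) per run; a
  single replicate reports SD 0. The grand SD of a design is the mean of
  the per-run SDs — the average replicate-noise level — not a pooled SD.
- **ANOVA** operates on one summary response per run (total DF = runs − 1),
  never on raw replicates. Factor SS = (runs per level) · Σ(level mean −
  grand mean)². The error term is total SS minus the unpooled factors'
  SS, which absorbs both pooled-factor SS and the residual carried by
  unassigned array columns; with a zero residual (noiseless additive
  data) unpooled F ratios are reported as +∞ with p = 0. Default pooling
  retains the k = 2 largest-SS factors; an explicit pooled set overrides.
  Significance is p < α (α = 0.1 for screening) on unrounded p-values;
  R² = retained SS / total SS, R²adj = 1 − (SSE/ν₂)/(SST/(a−1)).
- **Prediction and CI.** The additive prediction uses only the retained
  (unpooled) factors. CI half-width: `√(F(α;1,ν₂)·Vₑ·(1/n_eff + 1/r))`
  with `n_eff = N/(1 + Σ DF of prediction factors)` and α = 0.05. F
  quantiles and p-values come from `scipy.stats.f`.
- **Effect-rank ties** break by factor declaration order (stable);
  best-level ties break toward the smaller level index (smaller
  resource).
- **Determinism.** Every evaluation seed derives from
  `SeedSequence([base, stage, run, replicate])`, reduced below 2³¹; a
  campaign with a fixed base seed is byte-identical, and every
  evaluation is logged exactly once in the run manifest.
- **Display rounding** in `*_display.csv` reports: accuracy-scale 4
  decimals, SN 3 decimals, p-values 3 decimals; full-precision CSVs are
  authoritative.

## Orthogonal-array catalog

Arrays are stored as literal 1-based integer matrices (L4(2³), L8(2⁷),
L9(3⁴), L18(2¹×3⁷)), not generated; `verify_orthogonality` checks
single-column balance and strength-2 pairwise balance, and every catalog
entry passes. The L18 variant is the standard one whose columns 2–7
realize the canonical six-factor mixed design used by the bundled case
study; factors with fewer levels than their column are rejected (no
dummy treatment). Unused columns stay in the plan — their variation is
exactly what gives the pooled ANOVA its residual degrees of freedom
(stage 1: 4 pooled factors × 2 DF + 5 residual DF = 13 error DF).

## Objectives

- `LookupObjective` replays recorded responses for the settings of a
  known design; confirmation settings that extend a recorded setting
  with extra fixed factors fall back to the unique consistent match.
- `SyntheticAdditiveObjective` is the test harness: baseline + per-level
  effects + N(0, σ²) noise, clipped to (0, 1], with the true optimum
  known by construction. On σ = 0 the DOE pipeline recovers level means
  and the optimum exactly (verified against brute-force enumeration of
  the full factorial).
- `MLPObjective` wraps `sklearn.neural_network.MLPClassifier`: all
  hidden layers share one width; momentum is passed only to the sgd
  solver (adam and lbfgs do not define it); replicates share one
  train/test split (80/20 seeded shuffle, unstratified by default) and
  vary only the weight-initialization seed, so replicate scatter
  isolates training randomness. The training budget (`max_iter`, default
  200) is configuration; non-convergence is a warning, not an error.

## Synthetic cohort generator

`generate_synthetic_cvd` emulates the marginal structure of the public
70 000-row cardiovascular screening cohort: each continuous feature is
drawn from its published band frequencies with uniform jitter inside the
band (integer features floored), categorical features from their
published frequencies, and the binary outcome from a logistic model on
z-scored features whose intercept is bisection-calibrated to ≈50%
prevalence. Default coefficients follow clinical direction (systolic
pressure, age, cholesterol, weight positive; activity protective) with
magnitudes giving a Bayes accuracy in the low 0.7s.

What it does **not** model: correlations between features (age–pressure,
height–weight), measurement artifacts and entry errors present in the
real data, or any interaction structure in the outcome. Tests passing on
this generator therefore demonstrate the correctness of the DOE
machinery and the plumbing of the MLP adapter, not the real-data
accuracy of any particular hyperparameter setting.

## Problem sizes used in the checks

The bundled case-study replay is desk-scale by construction (18×3 + 5 +
9×3 + 5 recorded evaluations; the whole chain runs in well under a
second). The Monte-Carlo recovery check uses 100 seeded repeats of an
18-run screening stage on a synthetic additive objective with two
dominant factors (effect span 0.16) and four minor ones (span 0.04),
noise σ = 0.25 × the smallest dominant span; cohort-marginal checks use
30 000 generated rows, judged at ±3 binomial SE for a single fixed seed.

## Design choices and limitations

- The canonical L18 column ordering is taken from the case-study design
  itself; other textbook orderings are column permutations with
  identical statistical properties.
- Best-level selection prioritizes the mean response over SN because the
  two tables agreed in both case-study stages; a conflicting ranking
  would be resolved in favor of the mean, with the SN table available
  for inspection.
- The refinement rule can place a refined level on a value the objective
  has never seen (e.g. momentum 0.95); objectives must be defined over
  the refined range, and hard bounds (momentum < 1) should be declared
  via `RefinementRule.bounds`.
- Exactly two stages are supported; the method offers no global-optimum
  guarantee — it converges toward a locally improved setting under the
  additivity assumption.
- Interaction effects, dummy-leveling of mixed factors, linear-graph
  column allocation and multiple-comparison corrections are out of
  scope.
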