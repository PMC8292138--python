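# Methods

## The Dietary Inflammatory Index

The DII summarises how pro- or anti-inflammatory a diet is, using
literature-derived constants per food parameter (nutrient or dietary
component): a global daily mean intake `mu_j`, its standard deviation
`sigma_j`, and an overall inflammatory effect score `w_j` in [-1, 1]
(negative = anti-inflammatory). For a participant's 24-hour intake `x_j`:

```
z_j  = (x_j - mu_j) / sigma_j
cp_j = 2 * Phi(z_j) - 1          # centered percentile, in (-1, 1)
DII  = sum_j cp_j * w_j
```

`Phi` is the standard normal CDF. The published construction says only
"converted to a percentile score"; we use the closed-form normal-CDF reading
because it is deterministic and consistent with the z-score framing, and we
expose the CDF as the single pluggable point (`cdf=` argument of
`centered_percentile`/`dii_score`) so an empirical-distribution percentile
can be swapped in without touching anything else.

Properties that follow and that the test suite verifies: a diet at every
global mean scores exactly 0; the score decomposes exactly into
per-parameter contributions; `|DII| <= sum_j |w_j|`; and the score is
strictly monotone in each single intake with the sign of its effect score.
Numerically, `Phi` saturates at 0/1 in double precision for `|z| > ~8.3`; the
centered percentile is clamped to the largest double strictly inside
(-1, 1) so the open-interval invariant holds for arbitrarily extreme
intakes.

The bundled reference table (`data/dii_reference_26.csv`) carries the 26
nutrient parameters used here (alcohol, vitamins B12/B6/A/C/E, beta-carotene,
caffeine, carbohydrate, cholesterol, energy, total/saturated fat, MUFA,
PUFA, n-3 fatty acids, fiber, folic acid, iron, magnesium, niacin, protein,
riboflavin, selenium, thiamin, zinc), with constants transcribed from the
published DII design literature. The loader accepts any user table with the
same columns, so the constants are data, not code. The DII design remains
valid when fewer than 30 of the 45 original parameters are available;
records with fewer than `min_parameters` (default 20, configurable)
non-missing parameters are flagged unscorable rather than scored on a
truncated sum. DII is computed from a single 24-h recall; no multi-day
averaging and no energy standardisation ("per 1000 kcal" variants are out
of scope).

Tertiles are rank-based: sizes differ by at most one with the remainder
allocated to the upper tertiles (1,382 scores split 460/461/461), scores
exactly at a cut value stay in the lower tertile, and rank ties are broken
by stable input order — all deterministic, documented tie-breaks.

## Cohort construction

Participants flow through three ordered gates: (1) missing heart-failure
diagnosis (the "ever told you had congestive heart failure?" questionnaire
item unanswered); (2) no qualifying basic disease — none of hypertension,
diabetes, prediabetes, coronary artery disease, angina, heart attack or
stroke answered "yes"; a missing flag never qualifies (the conservative
reading of "uncertain cardiac-cerebral vascular disease"); (3) dietary
record unscorable for the DII. Survivors split into HF (diagnosis "yes") and
non-HF. The flow counts partition the input exactly on every run, which the
suite fuzz-tests. Missing covariates (BMI, education, smoking, income) never
exclude anyone at this stage; each downstream analysis owns its own
missing-data policy. HF is a single self-reported questionnaire field; no
clinical adjudication, severity or HFrEF/HFpEF subtyping is attempted.

## Descriptive comparisons

Categorical variables: per-group counts and percentages on the group-size
denominator (missing reported as its own row, excluded from the test), and a
Pearson chi-square without continuity correction on the non-missing
contingency table. Continuous variables: Levene's test (mean-centred) for
variance homogeneity; two groups get Student's t (pooled variance if Levene
p >= 0.05, otherwise Welch — the fallback is switchable); three groups get
one-way ANOVA with post-hoc tests only after a significant omnibus: Fisher's
LSD (pairwise t on the pooled ANOVA variance, no multiplicity correction —
its standard definition) under homogeneity, otherwise Dunnett's T3 with
Welch degrees of freedom. T3 p-values use the Studentized-Maximum-Modulus
CDF in its independence approximation `(2*F_t(|t|; df) - 1)^m` over the `m`
pairwise comparisons, the usual computational route. Every percentage equals
100*count/denominator to two decimals with denominators logged; p-values
render as three decimals with "<0.001" below that.

## Logistic odds-ratio ladder

Model 1 is crude (HF ~ DII, per-unit continuous term); model 2 adds age,
sex and BMI; model 3 adds race, education, income and smoking. Fits are
maximum-likelihood logistic regressions on complete cases for each model's
covariates (so n can only shrink down the ladder — asserted in tests);
`--missing-as-level` keeps missing categoricals as an explicit level
instead. Reference levels: male, "Other race or multi-racial", ">High
school", "<20,000 USD", "Non-smoking". ORs are exp(b) with Wald 95% CIs
exp(b ± 1.96 SE); likelihood-ratio p-values are available behind a flag.
Non-convergence raises with iteration diagnostics; complete separation is
detected (statsmodels' separation check plus a |b| > 15 guard) and raised
with the offending terms named. A `odds_ratio_from_counts` utility gives the
2×2 Woolf-CI OR with the Haldane–Anscombe 0.5 correction (flagged) when one
cell is zero, for crude cross-checks; tests verify the crude logistic fit on
a binary exposure reproduces it to 1e-6 on the log scale.

## Random forest

Stratified 10-fold cross-validation; one forest per fold trained on the
training folds only, with median imputation of missing features fitted on
the training folds (no leakage; complete-case is switchable). Out-of-fold
predicted probabilities are pooled into a single empirical ROC (threshold
sweep over unique predictions, trapezoidal AUC); per-fold AUCs are also
reported. The pooled AUC is provably the Mann–Whitney concordance
P(case > control) + 0.5 P(tie), and the suite checks the identity against a
brute-force O(n²) oracle to 1e-12. Impurity importances are averaged across
folds, dietary features flagged, and ranked with a stable sort. Defaults:
500 trees, sqrt(p) features per split, no depth cap, fixed surfaced seed;
class imbalance (~7% HF) is handled by stratification only. The default
feature set is demographics (age, sex indicator, BMI, waist) + the
laboratory panel + the 26 dietary intakes; the DII total itself is optional
(`include_dii`) and off by default.

## Synthetic cohort generator

The generator emulates the statistical shape the analysis assumes, with
every parameter explicit and echoed as ground truth:

* Intakes: independent log-normals per parameter, median = reference global
  mean, log-dispersion solved in closed form so SD/median matches the
  reference coefficient of variation (`sigma = sqrt(ln t)`,
  `t = (1 + sqrt(1 + 4 cv²))/2`), scaled by `spread_scale` (0 degenerates
  every intake to its mean, hence DII exactly 0).
* Demographics: age ~ N(59, 15) truncated to [20, 85], 48% male,
  BMI ~ N(31, 7) truncated to [15, 70], waist linear in BMI plus noise;
  race/education/income/smoking from fixed categorical marginals chosen to
  resemble a large US survey control group.
* Comorbidity flags: Bernoulli with probit-style dependence on one shared
  latent "cardiometabolic risk" factor (loading 0.8), intercepts solved by
  root-finding against Gauss–Hermite quadrature so marginals hit their
  targets; at least one qualifying flag is forced for a configurable 60% so
  the inclusion gate is exercised.
* HF label: Bernoulli(logit⁻¹(b0 + b_dii·DII + b_age·age + b_female·1[female]
  + b_bmi·BMI)) with effects configured as odds ratios (defaults 1.15 per
  DII unit, 1.05/year, 0.61 female, 1.05 per kg/m²). The intercept −6.95 was
  solved once by root-finding on the simulated mean probability at
  n = 200,000 to give ~7% HF prevalence under the default marginals.
* Labs: Gaussians at control-group means/SDs with additive HF mean shifts;
  missingness is injected completely at random per field (smoking 50%, labs
  10%, diet-record 5%, HF flag 2%, BMI/waist 3%, income 4%).

What it does **not** emulate: nutrient–nutrient correlation (real intakes
are strongly linked through total energy, so the synthetic DII SD (~0.9) is
smaller than real-data values (~1.7)); survey weights and sampling design;
informative missingness; lab–lab correlation beyond the HF shift;
longitudinal structure. Passing tests therefore demonstrate correctness of
the scoring arithmetic, the flow accounting, estimator calibration and
coverage under a correctly specified generating model — not fidelity to any
real survey's joint distribution.

## Problem sizes and calibration studies

The parameter-recovery study fits model 2 on 100 seeded cohorts of
n = 20,000 generated at true per-unit OR 1.15 and requires >= 93/100 CI
coverage with the median estimate within 5% of truth. Null calibration
(true OR 1) checks crude-CI coverage of 1 over 200 replicates at n = 2,000
(coverage is sample-size-free under MCAR, so the smaller n keeps replicates
cheap) and type-I error ~0.05 for the t-test, chi-square and ANOVA omnibus
over 2,000 replicates each. The random-forest surface checks run at
n <= 600 with 60–100 trees; the acceptance script's main run generates
20,000 participants and uses 100 trees × 10 folds per subgroup. Library
defaults stay at 500 trees — the smaller study sizes are the package's own
choices for its calibration reports.

## Known limitations

* Reference constants are transcribed from the public DII design table;
  users reproducing a specific published analysis should supply that
  analysis's exact table via `--reference-table`.
* Dunnett's T3 p-values use the independence SMM approximation (slightly
  conservative).
* The XPT adapter reads SAS transport v5 via pandas; it does not write XPT
  and does not harmonise cycle-specific survey variable names beyond the
  user-supplied mapping.
* Percentage denominators always equal the logged group size; published
  tables whose rows are inconsistent with their stated denominators cannot
  (and should not) be matched row-for-row.
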