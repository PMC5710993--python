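# Methods

## Synthetic twin cohort

The generator (`twincrp.cohort`) emulates a birth cohort of same-sex twin
pairs assessed at age 18, with dried-blood-spot CRP and a childhood
victimization-type count. One `numpy.random.default_rng(seed)` drives every
draw, in a fixed order, so a given `CohortSpec` reproduces its table
byte-for-byte.

### Latent outcome

For each family the latent log-CRP of the two twins is

    latent = A + C + E + effect_sex(exposure category)
             + β_whr (WHR − μ_whr) + β_temp (T − μ_temp) + SES shift

where (A, C, E) is a standardized ACE kernel: the additive-genetic
components are bivariate standard normal with correlation 1 (MZ) or 0.5
(DZ) scaled by √var_a, the shared-environment draw is common to the pair
(√var_c), and the unique-environment draws are independent (√var_e).
The preset uses (var_a, var_c, var_e) = (0.46, 0.10, 0.44) — the unique
solution of the target within-pair correlations r_MZ = A + C = 0.56 and
r_DZ = A/2 + C = 0.33.

Key preset choices and why:

| parameter | default | rationale |
|---|---|---|
| n_families | 10,000 (50,000 in calibration checks) | Monte-Carlo SE of a correlation ≈ 0.004 at 50k, small against the ±0.02 calibration band |
| prop_mz / prop_male | 0.56 / 0.49 | cohort composition being emulated |
| exposure_probs | (73.5, 20.1, 3.8, 1.8, 0.8, 0.1)% rescaled to sum to 1 | published count distribution; the printed percentages total 100.1% from rounding, so they are normalized proportionally |
| effect_female | (0, 0.21, 0.56) latent log-units | category effects for {none, one, poly} |
| effect_male | (0, 0.10, 0.20) | only the male linear trend (0.10/category) is documented; the vector is chosen exactly linear so the fitted trend equals 0.10 |
| exposure concordance | 1.0 (twins share the count) | most victimization types are household-level; a concordance parameter in [0,1] is available for sensitivity analyses |
| measurement_cv | 0.033 | blood-spot assay duplicate CV |
| contamination_rate | 0.03 | fraction with acute-phase CRP, matching the ~3.2% excluded in the emulated cohort |
| missing rates (WHR, temperature) | 25/888, 7/888 | covariate missingness proportions being emulated |
| whr: N(0.78, 0.06), β = 1.5; temp: N(36.6 °C, 0.4), β = 0.10; SES shifts (0, 0.05, 0.15) | free parameters | directions follow the emulated baseline associations; magnitudes are deliberately small — see below |

Exposure, SES (and, with concordance 1, the covariate-independent exposure
effects) are family-constant, so they add *shared* variance on top of the
standardized ACE kernel, while covariate contributions add *unique*
variance. Both perturb the latent within-pair correlations away from
(0.56, 0.33). The free magnitudes above keep the total extra variance under
3% of the latent variance; the analytically expected correlations under the
preset are r_MZ ≈ 0.562 and r_DZ ≈ 0.338, well inside the ±0.02 calibration
band the tests enforce.

### Measurement layer

True serum CRP is lognormal in the latent score:
`serum = exp(μ + σ·latent)` with μ = ln(0.85), σ = 1 — median 0.85 mg/L and
a right-skewed distribution typical of late adolescence. σ = 1 makes
latent-scale effects equal log-serum-scale regression coefficients, so the
injected category effects are the generative truth of the fitted models.
Genuine (non-acute) serum is winsorized at 9 mg/L: chronic low-grade
inflammation does not cross the 10 mg/L acute-phase threshold, and the
1 mg/L margin means assay noise cannot push a genuine record past the
exclusion cut — exclusions therefore remove exactly the contaminated
records, which are resampled as 11 + Exponential(8) mg/L.

The observed blood-spot value inverts the serum calibration
(`bloodspot = (serum − 0.14)/6.51`), is floored at a detection limit of
1e-4 (the calibration intercept means serum-equivalents are left-censored
at ≈0.14 mg/L; with median 0.85 this affects ≈4% of records), and is
multiplied by mean-1 lognormal noise with CV 3.3%. With μ = ln(0.6) —
a plausible alternative median — the left-censored fraction roughly
doubles and visibly attenuates the recovered exposure effects; the chosen
μ keeps the measurement layer close to transparent while remaining
realistic. Expected residual attenuation of the female poly coefficient
from the two censoring edges is ≈0.02 log-units, inside the tolerance the
calibration checks use.

### What the generator does *not* emulate

Item-level victimization dossiers, longitudinal CRP trajectories, sex
differences in exposure prevalence, within-pair covariate correlation
(WHR and temperature are drawn independently for the two twins),
assortative mating, and A×E interaction. Passing tests therefore show that
the estimators recover the generative structure of this idealized cohort,
not that they are robust to every feature of real data.

## Preprocessing

- Conversion: affine, `serum = 6.51·bloodspot + 0.14` (defaults
  configurable); negative inputs are a domain error.
- Exclusion: strictly `serum > 10` mg/L (acute trauma/infection), applied
  to the complete-case table; a missing CRP value raises rather than
  silently passing the filter.
- Winsorization: counts 0 → none, 1 → one, 2-5 → poly; idempotent on
  already-categorized input; order-preserving.
- Log transform: natural log (configurable only by transforming the column;
  the analysis convention is documented here rather than parameterized).
- High-CRP flag: top tertile of the post-exclusion serum-equivalent
  distribution, pooled across sexes, rank-based with ties broken by stable
  record order (exactly n − ⌊2n/3⌋ records flagged regardless of ties).
  Whether the emulated study cut tertiles before or after the exclusion is
  not documented; post-exclusion is used because the flag then refers to
  the same sample every model is fitted on.
- Imputation: missing WHR / temperature replaced by the post-exclusion
  sample-wide mean of observed values.

## Twin models

- Within-pair correlations use the double-entry estimator (each pair
  contributes both orderings), which is invariant to twin labelling.
- The ACE likelihood is maximized by L-BFGS-B over (mean, σ²_A, σ²_C, σ²_E)
  with lower bounds at 0 (σ²_E ≥ 1e-10 keeps the covariance matrix
  invertible), started from clipped Falconer values. Degenerate proposals
  (non-positive-definite pair covariance) receive a large finite penalty so
  finite-difference gradients stay defined. Convergence is reported
  honestly from the optimizer status.
- The 95% CI for `a_frac` uses profile likelihood (χ²₁ cutoff 3.84),
  profiling over the constrained fraction with the total variance and the
  C share re-optimized; boundary estimates clamp the interval at 0 or 1.
  A family-level bootstrap is available as an alternative.
- The latent genetic score is the exhaustively-tested 4-point mapping;
  records whose co-twin is missing (pair broken by exclusions) are dropped
  with a logged count, never imputed.
- The score-validation regression reports both conventions for the "beta"
  of CRP on the score, because they differ: the fully standardized
  coefficient (= Pearson correlation, ≈0.35 under the preset) and R²
  (≈0.125, matching a closed-form truncated-bivariate-normal calculation).
  A correlation of 0.33 with R² = 13% is not internally consistent for a
  simple regression (0.33² ≈ 0.11), so both numbers are always emitted.

## GEE

Gaussian identity-link estimating equations with exchangeable working
correlation. Iteration alternates (i) the weighted least-squares solve,
using the closed-form inverse of the exchangeable correlation matrix
(R⁻¹ = [I − ρ/(1+(n_c−1)ρ)·J]/(1−ρ), accumulated via per-cluster sums, so
twin pairs and arbitrary cluster sizes cost O(N)), and (ii) the moment
update of ρ from standardized residual cross-products with the standard
small-sample denominators (N − p for the scale, total pairs − p for ρ).
Defaults tol = 1e-8 on the max coefficient change, max_iter = 100; the
convergence flag is honest. Robust variance is the cluster sandwich
A⁻¹BA⁻¹; 95% CIs use ±1.96·SE and p-values the normal approximation. With
singleton clusters the fit reduces exactly to OLS. No multiple-testing
correction is applied across the model ladder, mirroring the analysis
convention being reproduced; this is a reporting choice, not an inference
recommendation.

Collinearity is detected by rank check with pivoted QR naming offending
columns. The sex-interaction test is a robust Wald test of the
linear-exposure × male product term in the pooled model.

## Pipeline

`run_pipeline` executes: generate/load → convert → exclude → derive →
score → correlations + ACE + score validation → GEE ladder (categorical
exposure, female stratum by default, matching the emulated Table) plus
linear-trend fits for all/F/M and the sex-interaction test. Reports are
JSON with sorted keys and no timestamps, so a fixed config + seed
reproduces them byte-for-byte; the provenance block stores the config
SHA-256 and seed.

## Problem sizes

Calibration and acceptance checks use 50,000 families (100,000 twins),
where correlation Monte-Carlo SEs are ≈0.004 and GEE coefficient SEs
≈0.01-0.03; unit tests use 200-8,000 families. The full test suite runs in
well under a minute on one CPU.

## Known limitations

- The exchangeable-GEE menu is limited to independence and exchangeable
  working correlations (sufficient for clusters of size 2).
- The ACE model is univariate; no sex-limitation, bivariate or
  longitudinal variants, and no DNA-based polygenic scores.
- The profile CI treats the fraction parameterization as unconstrained
  above; coverage at hard boundaries (a_frac ≈ 0 or 1) is conservative.
- Left-censoring of serum-equivalents at the calibration intercept and
  winsorization of genuine values at 9 mg/L mildly attenuate recovered
  effects (≈0.02 log-units on the poly coefficient at the preset); this is
  a property of the measurement design being emulated, quantified above.
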