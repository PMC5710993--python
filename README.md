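# twincrp

Genetically sensitive twin-cohort analysis of childhood victimization and
C-reactive protein (CRP).

## The problem

Children exposed to victimization (domestic violence, bullying, maltreatment,
sexual or emotional abuse, neglect) show elevated low-grade inflammation in
early adulthood, but an association between adversity and CRP could be
genetically confounded: CRP levels are heritable, and genes can influence both
exposure risk and inflammation. A same-sex twin design can separate the two.
This package implements that analysis end to end for cohorts in which:

- CRP is assayed from dried blood spots and converted to serum-equivalent
  mg/L through an affine calibration (`serum = 6.51 · bloodspot + 0.14`);
- childhood victimization is a count of 0-5 distinct exposure types,
  winsorized into {none, one type, poly (2+ types)};
- twins are clustered in families, so regression inference must be
  cluster-robust.

Because individual-level cohort data of this kind are not publicly
deposited, the package ships a seeded synthetic twin-cohort generator with
the same statistical structure, so every stage of the pipeline is testable
and reproducible offline.

## Models

**ACE variance decomposition.** Each twin pair's log-CRP is modelled as
bivariate normal with common mean and variance σ²_A + σ²_C + σ²_E, and
within-pair covariance σ²_A + σ²_C for monozygotic (MZ) pairs and
σ²_A/2 + σ²_C for dizygotic (DZ) pairs. `TwinACEModel.fit()` maximizes the
likelihood with non-negativity bounds and reports variance fractions with a
profile-likelihood (or family-bootstrap) CI for the heritability
`a_frac = σ²_A / (σ²_A + σ²_C + σ²_E)`. Falconer's closed forms
(A = 2(r_MZ − r_DZ), C = 2r_DZ − r_MZ, E = 1 − r_MZ) are provided as the
independent oracle.

**Latent genetic risk score.** "High CRP" is the top tertile of the
serum-equivalent distribution. Each twin's genetic liability is coded 0-3
from zygosity and the co-twin's flag: MZ co-twin not high (0) < DZ not high
(1) < DZ high (2) < MZ high (3).

**Family-clustered GEE.** `FamilyGEE` is a from-scratch Gaussian
identity-link GEE with exchangeable working correlation: coefficients solve
the weighted estimating equations, the working ρ is moment-updated from
standardized residuals, and variances use the cluster-robust sandwich
estimator (95% CI = b ± 1.96·SE). The adjustment ladder mirrors the study:
Baseline (exposure only), Model 1 (+ genetic score), Model 2 (+ SES
tertiles), Model 3 (+ waist-hip ratio, body temperature), Model 4 (all).

## Worked example

```python
import twincrp as t

cfg = t.PipelineConfig(spec=t.default_study_preset(n_families=5000), seed=7)
rep = t.run_pipeline(cfg)
```

With 5,000 families (10,000 twins) this prints, via the report fields:

```
rMZ = 0.556, rDZ = 0.321
ACE: A = 0.48 (95% CI 0.40-0.57), C = 0.08, E = 0.44
score: beta_std = 0.36, R2 = 0.128
exclusions: {'n_input': 10000, 'n_excluded': 307, 'n_retained': 9693, 'threshold': 10.0}
trend:F b = 0.26 (0.20; 0.31)
trend:M b = 0.09 (0.03; 0.15)
female poly (Baseline): b = 0.57 (0.43; 0.71)
```

Reading: the within-pair correlations are higher for MZ than DZ twins, and
the ACE fit attributes ~48% of log-CRP variance to additive genetics here.
~3% of records are excluded as acute-phase (serum-equivalent CRP > 10 mg/L).
The 0-3 co-twin score explains ~13% of log-CRP variance. The linear
victimization trend on log-CRP is clearly positive in females (0.26 per
category) and weaker in males (0.09), and poly-victimized females show a
0.57 log-unit elevation over non-victimized females before adjustment —
all reflecting the structure the preset injects.

The same pipeline runs from the command line:

```bash
twincrp run --n-families 5000 --seed 7 --outdir out/
twincrp report --fits out/gee_fits.json   # Table-1-style ladder
```

or stage by stage (`generate`, `preprocess`, `twin`, `fit`).

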