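"""Synthetic same-sex twin cohort generator.

Emulates the structure of a genetically informative birth cohort in which
C-reactive protein (CRP) was assayed from dried blood spots at age 18 and
childhood victimization was recorded as a 0-5 count of distinct exposure
types.  The latent (log-scale) CRP of each twin pair is built from an ACE
variance decomposition -- additive genetic effects correlated 1.0 within
monozygotic (MZ) and 0.5 within dizygotic (DZ) pairs, a shared-environment
component, and a unique-environment component -- plus sex-specific exposure
effects, covariate contributions and a family socioeconomic shift.

The observable biomarker is the blood-spot CRP concentration: true serum CRP
is lognormal in the latent score, mapped back through the inverse of the
affine blood-spot-to-serum calibration, floored at an assay detection limit,
and perturbed by multiplicative lognormal assay noise.  A small fraction of
individuals carries an acute-phase contamination (serum CRP above the 10 mg/L
exclusion threshold) so that downstream exclusion logic is exercised.

All randomness flows through a single ``numpy.random.default_rng(seed)``;
a given spec and seed reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .preprocess import ConversionParams

__all__ = [
    "CovariateParams",
    "CohortSpec",
    "CohortSpecError",
    "default_study_preset",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

#: Fixed column order of the cohort CSV dialect.
COHORT_COLUMNS = [
    "family_id",
    "twin_index",
    "zygosity",
    "sex",
    "victimization_count",
    "bloodspot_crp",
    "waist_hip_ratio",
    "body_temp",
    "ses_tertile",
    "latent_log_crp",
]

SES_LEVELS = ("high", "middle", "low")

# Reported victimization-count frequencies (%): 73.5 / 20.1 / 3.8 / 1.8 / 0.8 /
# 0.1.  They total 100.1% from rounding, so the preset rescales them to sum
# exactly to 1 while preserving their ratios.
_RAW_EXPOSURE = np.array([0.735, 0.201, 0.038, 0.018, 0.008, 0.001])
DEFAULT_EXPOSURE_PROBS = tuple(float(p) for p in _RAW_EXPOSURE / _RAW_EXPOSURE.sum())

_TOL = 1e-9


class CohortSpecError(ValueError):
    """A cohort specification violates one of its invariants."""


@dataclass(frozen=True)
class CovariateParams:
    """Distribution and effect parameters for the two continuous covariates.

    ``*_coef`` are the contributions to latent log-CRP per unit of the
    (mean-centred) covariate.  Waist-hip ratio is dimensionless; body
    temperature is in degrees Celsius.
    """

    whr_mean: float = 0.78
    whr_sd: float = 0.06
    whr_coef: float = 1.5
    temp_mean: float = 36.6
    temp_sd: float = 0.4
    temp_coef: float = 0.10


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic twin cohort.

    ``var_a``, ``var_c``, ``var_e`` are fractions of the standardized latent
    log-CRP variance and must sum to 1.  ``exposure_probs`` is the marginal
    distribution of the victimization-type count 0-5.  ``effect_female`` /
    ``effect_male`` are latent-scale mean shifts for the winsorized exposure
    categories (none, one, poly).  ``ses_effect`` gives latent shifts for the
    (high, middle, low) SES tertiles.  ``crp_log_mu`` / ``crp_log_sigma`` map
    the latent score to true serum CRP via ``serum = exp(mu + sigma*latent)``.
    """

    n_families: int = 10_000
    prop_mz: float = 0.56
    prop_male: float = 0.49
    var_a: float = 0.46
    var_c: float = 0.10
    var_e: float = 0.44
    exposure_probs: tuple[float, ...] = DEFAULT_EXPOSURE_PROBS
    #: probability that twin 2 inherits twin 1's victimization count verbatim
    exposure_concordance: float = 1.0
    effect_female: tuple[float, float, float] = (0.0, 0.21, 0.56)
    effect_male: tuple[float, float, float] = (0.0, 0.10, 0.20)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    ses_effect: tuple[float, float, float] = (0.0, 0.05, 0.15)
    measurement_cv: float = 0.033
    contamination_rate: float = 0.03
    missing_rate_whr: float = 25 / 888
    missing_rate_temp: float = 7 / 888
    #: lognormal location/scale linking latent log-CRP to true serum mg/L
    crp_log_mu: float = float(np.log(0.85))
    crp_log_sigma: float = 1.0
    #: genuine (non-acute) serum CRP is winsorized at this value: chronic
    #: low-grade inflammation stays below the 10 mg/L acute threshold, and the
    #: margin keeps assay noise from pushing genuine records past it
    genuine_cap: float = 9.0
    #: assay detection floor on the blood-spot scale (mg/L)
    dbs_floor: float = 1e-4
    #: acute-phase serum CRP is drawn as contamination_min + Exp(contamination_scale)
    contamination_min: float = 11.0
    contamination_scale: float = 8.0
    conversion: ConversionParams = field(default_factory=ConversionParams)
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`CohortSpecError` naming the first violated invariant."""
        if self.n_families <= 0:
            raise CohortSpecError("n_families must be a positive integer")
        if abs(self.var_a + self.var_c + self.var_e - 1.0) > _TOL:
            raise CohortSpecError(
                "var_a + var_c + var_e must equal 1 (latent scale is standardized); "
                f"got {self.var_a + self.var_c + self.var_e!r}"
            )
        if min(self.var_a, self.var_c, self.var_e) < 0:
            raise CohortSpecError("variance fractions must be non-negative")
        probs = np.asarray(self.exposure_probs, dtype=float)
        if probs.shape != (6,):
            raise CohortSpecError("exposure_probs must have exactly 6 entries")
        if (probs < 0).any():
            raise CohortSpecError("exposure_probs entries must be non-negative")
        if abs(probs.sum() - 1.0) > _TOL:
            raise CohortSpecError(f"exposure_probs must sum to 1; got {probs.sum()!r}")
        for name in (
            "prop_mz",
            "prop_male",
            "contamination_rate",
            "missing_rate_whr",
            "missing_rate_temp",
            "exposure_concordance",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise CohortSpecError(f"{name} must lie in [0, 1]; got {value!r}")
        if len(self.effect_female) != 3 or len(self.effect_male) != 3:
            raise CohortSpecError("effect vectors must have 3 entries (none, one, poly)")
        if len(self.ses_effect) != 3:
            raise CohortSpecError("ses_effect must have 3 entries (high, middle, low)")
        if self.measurement_cv < 0:
            raise CohortSpecError("measurement_cv must be non-negative")
        if self.crp_log_sigma <= 0:
            raise CohortSpecError("crp_log_sigma must be positive")
        if self.dbs_floor <= 0:
            raise CohortSpecError("dbs_floor must be positive")
        if not 0.0 < self.genuine_cap <= 10.0:
            raise CohortSpecError(
                "genuine_cap must be positive and at most the 10 mg/L threshold"
            )
        if self.contamination_min <= 10.0:
            raise CohortSpecError(
                "contamination_min must exceed the 10 mg/L acute-phase threshold"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposure_probs"] = list(self.exposure_probs)
        d["effect_female"] = list(self.effect_female)
        d["effect_male"] = list(self.effect_male)
        d["ses_effect"] = list(self.ses_effect)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "covariate_params" in d and isinstance(d["covariate_params"], dict):
            d["covariate_params"] = CovariateParams(**d["covariate_params"])
        if "conversion" in d and isinstance(d["conversion"], dict):
            d["conversion"] = ConversionParams(**d["conversion"])
        for key in ("exposure_probs", "effect_female", "effect_male", "ses_effect"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def replace(self, **changes) -> "CohortSpec":
        return dataclasses.replace(self, **changes)


def default_study_preset(n_families: int = 10_000, seed: int = 0) -> CohortSpec:
    """The documented study-emulation preset.

    ACE fractions (0.46, 0.10, 0.44) are the unique solution of the twin
    correlations rMZ = A + C = 0.56 and rDZ = A/2 + C = 0.33.  The exposure
    distribution, zygosity/sex mix, sex-specific exposure effects, blood-spot
    assay CV and covariate missingness rates follow the cohort the generator
    emulates; serum location/scale, covariate effect magnitudes and the
    contamination mechanism are package defaults documented in
    ``docs/methods.md``.
    """
    return CohortSpec(n_families=n_families, seed=seed)


def _draw_counts(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    """Victimization counts for both twins, (n, 2).

    Twin 1 draws from the marginal; twin 2 copies twin 1 with probability
    ``exposure_concordance`` and redraws independently otherwise, so the
    marginal distribution is preserved for any concordance level.
    """
    probs = np.asarray(spec.exposure_probs, dtype=float)
    probs = probs / probs.sum()
    c1 = rng.choice(6, size=n, p=probs)
    redraw = rng.random(n) >= spec.exposure_concordance
    c2_indep = rng.choice(6, size=n, p=probs)
    c2 = np.where(redraw, c2_indep, c1)
    return np.column_stack([c1, c2])


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table of ``2 * n_families`` individual records.

    Returns a DataFrame in the :data:`COHORT_COLUMNS` order.  The column
    ``latent_log_crp`` is the generator-internal truth (standardized-scale
    latent log-CRP including exposure, covariate and SES contributions) and is
    retained for testing and calibration only; the observable biomarker is
    ``bloodspot_crp``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_families
    cov = spec.covariate_params
    conv = spec.conversion

    is_mz = rng.random(n) < spec.prop_mz
    is_male = rng.random(n) < spec.prop_male

    # ACE latent components: additive-genetic correlation 1 (MZ) / 0.5 (DZ)
    a1 = rng.standard_normal(n)
    a2_orth = rng.standard_normal(n)
    a2 = np.where(is_mz, a1, 0.5 * a1 + np.sqrt(0.75) * a2_orth)
    a_part = np.sqrt(spec.var_a) * np.column_stack([a1, a2])
    c_part = np.sqrt(spec.var_c) * rng.standard_normal(n)[:, None]
    e_part = np.sqrt(spec.var_e) * rng.standard_normal((n, 2))

    counts = _draw_counts(rng, spec, n)
    category = np.minimum(counts, 2)  # 0 none, 1 one, 2+ poly
    eff_f = np.asarray(spec.effect_female, dtype=float)
    eff_m = np.asarray(spec.effect_male, dtype=float)
    exposure_shift = np.where(is_male[:, None], eff_m[category], eff_f[category])

    whr = rng.normal(cov.whr_mean, cov.whr_sd, size=(n, 2))
    temp = rng.normal(cov.temp_mean, cov.temp_sd, size=(n, 2))
    ses_idx = rng.integers(0, 3, size=n)
    ses_shift = np.asarray(spec.ses_effect, dtype=float)[ses_idx][:, None]

    latent = (
        a_part
        + c_part
        + e_part
        + exposure_shift
        + cov.whr_coef * (whr - cov.whr_mean)
        + cov.temp_coef * (temp - cov.temp_mean)
        + ses_shift
    )

    serum_true = np.exp(spec.crp_log_mu + spec.crp_log_sigma * latent)
    serum_true = np.minimum(serum_true, spec.genuine_cap)

    contaminated = rng.random((n, 2)) < spec.contamination_rate
    n_cont = int(contaminated.sum())
    serum_true[contaminated] = spec.contamination_min + rng.exponential(
        spec.contamination_scale, size=n_cont
    )

    bloodspot_true = np.maximum(
        (serum_true - conv.intercept) / conv.slope, spec.dbs_floor
    )
    if spec.measurement_cv > 0:
        sigma_ln = np.sqrt(np.log1p(spec.measurement_cv**2))
        noise = np.exp(
            sigma_ln * rng.standard_normal((n, 2)) - 0.5 * sigma_ln**2
        )
    else:
        noise = np.ones((n, 2))
    bloodspot = bloodspot_true * noise
    # Acute-phase records stay strictly above the exclusion threshold on the
    # converted scale even after assay noise, so exclusions are unambiguous.
    bs_threshold = (10.0 - conv.intercept) / conv.slope * (1.0 + 1e-9)
    bloodspot[contaminated] = np.maximum(bloodspot[contaminated], bs_threshold)

    miss_whr = rng.random((n, 2)) < spec.missing_rate_whr
    miss_temp = rng.random((n, 2)) < spec.missing_rate_temp
    whr = np.where(miss_whr, np.nan, whr)
    temp = np.where(miss_temp, np.nan, temp)

    width = max(6, len(str(n)))
    family_id = np.array([f"F{i:0{width}d}" for i in range(1, n + 1)])

    def _flat(x: np.ndarray) -> np.ndarray:
        return np.asarray(x).reshape(-1)

    table = pd.DataFrame(
        {
            "family_id": np.repeat(family_id, 2),
            "twin_index": np.tile([1, 2], n),
            "zygosity": np.repeat(np.where(is_mz, "MZ", "DZ"), 2),
            "sex": np.repeat(np.where(is_male, "M", "F"), 2),
            "victimization_count": _flat(counts),
            "bloodspot_crp": _flat(bloodspot),
            "waist_hip_ratio": _flat(whr),
            "body_temp": _flat(temp),
            "ses_tertile": np.repeat(np.array(SES_LEVELS)[ses_idx], 2),
            "latent_log_crp": _flat(latent),
        },
        columns=COHORT_COLUMNS,
    )
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table in the fixed CSV dialect (stable column order)."""
    table.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the required columns are present."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns and c != "latent_log_crp"]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return table
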