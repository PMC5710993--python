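"""End-to-end analysis pipeline: generate -> preprocess -> twin models -> GEE.

Runs the four-step analysis sequence on a generated or supplied cohort:
(1) does childhood victimization predict age-18 log-CRP; (2) the same,
stratified by sex; (3) the genetic contribution to CRP (within-pair
correlations, the ACE decomposition and the latent-genetic-score validation
regression); (4) the victimization association adjusted for the latent
genetic score and the other covariates (the Baseline / Model 1-4 ladder).

Everything is driven by a :class:`PipelineConfig`; a fixed config and seed
reproduce the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort, read_cohort_csv, write_cohort_csv
from .gee import MODEL_IDS, GEEResults, build_model_design, fit_gee, sex_interaction_test
from .preprocess import (
    ConversionParams,
    add_serum_equivalent,
    apply_exclusions,
    derive_analysis_variables,
)
from .twin import TwinACEModel, add_latent_genetic_score, score_validation, within_pair_correlations

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "table1_report"]

logger = logging.getLogger("twincrp.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``spec`` (a synthetic-cohort specification) or
    ``input_csv`` (a cohort table on disk) must be provided.  ``seed``
    overrides the spec's seed so a single integer controls all randomness.
    """

    spec: Optional[CohortSpec] = None
    input_csv: Optional[str] = None
    conversion: ConversionParams = field(default_factory=ConversionParams)
    exclusion_threshold: float = 10.0
    models: tuple[str, ...] = MODEL_IDS
    table_stratum: str = "F"
    outdir: Optional[str] = None
    seed: Optional[int] = None

    def validate(self) -> None:
        if (self.spec is None) == (self.input_csv is None):
            raise ValueError("exactly one of spec or input_csv must be provided")
        if self.exclusion_threshold <= 0:
            raise ValueError("exclusion_threshold must be positive")
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model ids: {unknown}")

    def resolved_spec(self) -> Optional[CohortSpec]:
        if self.spec is None:
            return None
        if self.seed is not None:
            return self.spec.replace(seed=self.seed)
        return self.spec

    def to_dict(self) -> dict:
        return {
            "spec": None if self.spec is None else self.resolved_spec().to_dict(),
            "input_csv": self.input_csv,
            "conversion": dataclasses.asdict(self.conversion),
            "exclusion_threshold": self.exclusion_threshold,
            "models": list(self.models),
            "table_stratum": self.table_stratum,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("spec") is not None:
            d["spec"] = CohortSpec.from_dict(d["spec"])
        if isinstance(d.get("conversion"), dict):
            d["conversion"] = ConversionParams(**d["conversion"])
        if "models" in d and d["models"] is not None:
            d["models"] = tuple(d["models"])
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class AnalysisReport:
    """Everything one pipeline run computed, ready for serialization."""

    provenance: dict
    exclusion: dict
    correlations: dict
    ace: dict
    score_dropped: int
    score_validation: dict
    sex_interaction_p: float
    gee_fits: dict  # key -> GEEResults.to_dict()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis sequence described in the module docstring."""
    config.validate()

    # Stage 1: obtain the cohort
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
        logger.info("loaded cohort: %d records from %s", len(cohort), config.input_csv)
    else:
        spec = config.resolved_spec()
        cohort = generate_cohort(spec)
        logger.info("generated cohort: %d records (%d families)", len(cohort), spec.n_families)

    # Stage 2: serum conversion, acute-phase exclusion, derived variables
    with_serum = add_serum_equivalent(cohort, config.conversion)
    retained, excl = apply_exclusions(with_serum, config.exclusion_threshold)
    logger.info(
        "exclusions: %d of %d records above %.1f mg/L; %d retained",
        excl.n_excluded, excl.n_input, excl.threshold, excl.n_retained,
    )
    analysis = derive_analysis_variables(retained)

    # Stage 3: genetic structure
    scored, n_dropped = add_latent_genetic_score(analysis)
    logger.info("latent genetic score: %d records dropped (incomplete pairs)", n_dropped)
    r_mz, r_dz = within_pair_correlations(scored, "log_crp")
    ace = TwinACEModel.from_cohort(scored, outcome="log_crp").fit()
    validation = {
        "all": score_validation(scored),
        "F": score_validation(scored[scored["sex"] == "F"]),
    }
    interaction_p, _ = sex_interaction_test(scored)

    # Stage 4: GEE ladder (categorical exposure, Table-1 stratum) and
    # sex-stratified linear trends
    fits: dict[str, GEEResults] = {}
    for model_id in config.models:
        design = build_model_design(
            scored, model_id, "categorical", config.table_stratum
        )
        fits[model_id] = fit_gee(design)
        logger.info("fit %s: n=%d clusters=%d", model_id, fits[model_id].n_obs,
                    fits[model_id].n_clusters)
    trend_fits: dict[str, GEEResults] = {}
    for stratum in ("all", "F", "M"):
        design = build_model_design(scored, "baseline", "linear", stratum)
        trend_fits[f"trend:{stratum}"] = fit_gee(design)

    all_fits = {**fits, **trend_fits}
    report = AnalysisReport(
        provenance={
            "package": "twincrp",
            "version": __version__,
            "config_sha256": _config_hash(config),
            "seed": config.seed if config.seed is not None else (
                config.spec.seed if config.spec is not None else None
            ),
        },
        exclusion=excl.to_dict(),
        correlations={"r_mz": r_mz, "r_dz": r_dz, "outcome": "log_crp"},
        ace=ace.to_dict(),
        score_dropped=n_dropped,
        score_validation=validation,
        sex_interaction_p=interaction_p,
        gee_fits={key: fit.to_dict() for key, fit in all_fits.items()},
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(cohort, outdir / "cohort.csv")
        scored.to_csv(outdir / "analysis_table.csv", index=False)
        (outdir / "config.json").write_text(
            json.dumps(config.to_dict(), sort_keys=True, indent=2)
        )
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "gee_fits.json").write_text(
            json.dumps(report.gee_fits, sort_keys=True, indent=2)
        )
        (outdir / "table1.txt").write_text(table1_report(fits))
        logger.info("artifacts written to %s", outdir)

    return report


# -- Table-1-style report ------------------------------------------------------

_MODEL_LABELS = {
    "baseline": "Baseline",
    "model1": "Model 1",
    "model2": "Model 2",
    "model3": "Model 3",
    "model4": "Model 4",
}

_ROWS = [
    ("Childhood victimization", None),
    ("  None", "REF"),
    ("  1 type", "victimization_one"),
    ("  2+ types", "victimization_poly"),
    ("Latent genetic score", "genetic_score"),
    ("Child socioeconomic status", None),
    ("  High", "REF_SES"),
    ("  Middle", "ses_middle"),
    ("  Low", "ses_low"),
    ("Waist-hip ratio", "waist_hip_ratio"),
    ("Body temperature", "body_temp"),
]


def _cell(fit: Union[GEEResults, Mapping], term: str) -> str:
    if isinstance(fit, GEEResults):
        coefs = fit.params
        if term not in coefs.index:
            return ""
        ci = fit.conf_int().loc[term]
        lo, hi = ci["lower"], ci["upper"]
        b = coefs[term]
        p = fit.pvalues[term]
    else:
        if term not in fit["coefficients"]:
            return ""
        b = fit["coefficients"][term]
        lo = fit["ci_lower"][term]
        hi = fit["ci_upper"][term]
        p = fit["p_values"][term]
    star = "*" if p < 0.05 else ""
    return f"{b:.2f} ({lo:.2f}; {hi:.2f}){star}"


def table1_report(fits: Mapping[str, Union[GEEResults, Mapping]]) -> str:
    """Render the adjustment-ladder table (rows = terms, columns = models).

    ``fits`` maps model ids (``baseline`` .. ``model4``) to fitted GEE results
    (objects or their serialized dicts).  Coefficients are unstandardized with
    95% confidence intervals; ``*`` marks p < 0.05.  A requested model with no
    fit yields a blank column and a warning rather than silent omission.
    """
    model_ids = [m for m in _MODEL_LABELS]
    present = {}
    for mid in model_ids:
        if mid in fits:
            present[mid] = fits[mid]
        else:
            warnings.warn(f"no fit supplied for {mid}; column left blank")
    width = 22
    header = f"{'':<28}" + "".join(f"{_MODEL_LABELS[m]:>{width}}" for m in model_ids)
    lines = [header, "-" * len(header)]
    for label, term in _ROWS:
        if term is None:
            lines.append(label)
            continue
        cells = []
        for mid in model_ids:
            fit = present.get(mid)
            if fit is None:
                cells.append("")
            elif term == "REF":
                cells.append("Ref")
            elif term == "REF_SES":
                has_ses = (
                    "ses_low" in (fit.params.index if isinstance(fit, GEEResults)
                                  else fit["coefficients"])
                )
                cells.append("Ref" if has_ses else "")
            else:
                cells.append(_cell(fit, term))
        lines.append(f"{label:<28}" + "".join(f"{c:>{width}}" for c in cells))
    lines.append("")
    lines.append("Unstandardized coefficients (95% CI); * p < 0.05 (robust).")
    return "\n".join(lines)
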