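import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from twincrp import (
    CovariateParams,
    add_latent_genetic_score,
    add_serum_equivalent,
    apply_exclusions,
    default_study_preset,
    derive_analysis_variables,
    generate_cohort,
)


def pure_ace_spec(n_families, seed, var_a=0.46, var_c=0.10):
    """Preset with every non-ACE contribution switched off: the latent
    log-CRP is exactly the standardized A + C + E sum."""
    return default_study_preset(n_families=n_families, seed=seed).replace(
        var_a=var_a,
        var_c=var_c,
        var_e=1.0 - var_a - var_c,
        effect_female=(0.0, 0.0, 0.0),
        effect_male=(0.0, 0.0, 0.0),
        ses_effect=(0.0, 0.0, 0.0),
        covariate_params=CovariateParams(whr_coef=0.0, temp_coef=0.0),
        measurement_cv=0.0,
        contamination_rate=0.0,
    )


def preprocess_chain(cohort):
    """Raw cohort -> analysis table with serum, exclusions, derived vars, score."""
    with_serum = add_serum_equivalent(cohort)
    retained, report = apply_exclusions(with_serum)
    analysis = derive_analysis_variables(retained)
    scored, n_dropped = add_latent_genetic_score(analysis)
    return scored, report, n_dropped


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-family preset cohort for fast unit tests."""
    return generate_cohort(default_study_preset(n_families=2000, seed=3))


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    scored, _, _ = preprocess_chain(small_cohort)
    return scored


@pytest.fixture(scope="session")
def big_cohort():
    """50,000-family preset cohort shared by the acceptance checks."""
    return generate_cohort(default_study_preset(n_families=50_000, seed=1234))


@pytest.fixture(scope="session")
def big_analysis(big_cohort):
    scored, _, _ = preprocess_chain(big_cohort)
    return scored
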