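from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aquanuisance import nuisance_glmm as glmm
from aquanuisance import survey_qc as qc
from aquanuisance import synthetic_survey as synth

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def site_configs():
    return synth.default_site_configs(seed=1)


@pytest.fixture(scope="session")
def sagittifolia_long(site_configs):
    """Long nuisance table from a 100-respondent S. sagittifolia cohort."""
    cfg = replace(site_configs["S. sagittifolia"], n_respondents=100, seed=11)
    records = synth.generate_survey(cfg)
    retained, _ = qc.filter_responses(records)
    return qc.to_long_nuisance(qc.clean_records(retained))


@pytest.fixture(scope="session")
def sagittifolia_fit(sagittifolia_long):
    return glmm.fit_binomial_glmm(
        sagittifolia_long, glmm.ModelSpec(terms=("growth_level", "respondent_type")))


@pytest.fixture()
def independent_bernoulli_frame():
    """sigma = 0 data: ticks independent given the fixed effects."""
    rng = np.random.default_rng(3)
    n = 400
    df = pd.DataFrame({
        "growth_level": np.tile([1.0, 2, 3, 4, 5], n),
        "respondent_id": np.repeat(np.arange(n), 5),
    })
    eta = -3.0 + 1.0 * df["growth_level"]
    df["nuisance"] = (rng.random(len(df)) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return df
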