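"""Shared fixtures: one mid-sized synthetic cohort and its fitted models.

The session-scoped cohort keeps the expensive pieces (generation, Cox fits)
to a single evaluation across the whole suite.
"""

import numpy as np
import pandas as pd
import pytest

from counterrisk import GeneratorConfig, fit_cpm, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """20k-person cohort under the default (study-condition) configuration,
    smoking-cessation scenario active."""
    return generate_cohort(GeneratorConfig(n_participants=20_000, seed=7))


@pytest.fixture(scope="session")
def powered_cohort():
    """Cohort with higher return/adoption rates, for tests that need a
    well-populated treated arm."""
    cfg = GeneratorConfig(
        n_participants=20_000, seed=11, followup_prob_base=0.45,
        uptake_prob_base={"I": 0.5, "IIa": 0.2, "IIb": 0.25,
                          "IIIa": 0.15, "IIIb": 0.2})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_models(default_cohort):
    return fit_cpm(default_cohort.baseline)


def make_baseline(**overrides) -> pd.DataFrame:
    """One hand-specified baseline row with sensible defaults."""
    row = {
        "id": 0, "age": 55.0, "sex": "male", "ethnicity": "European",
        "nzdep": 3, "smoking": "never", "family_history": 0, "diabetes": 0,
        "af": 0, "sbp": 130.0, "tchdl": 4.0, "bplm": 0, "llm": 0, "atm": 0,
        "event_time": 60.0, "event_type": "admin_censor",
    }
    row.update(overrides)
    return pd.DataFrame([row])


@pytest.fixture
def one_record():
    return make_baseline
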