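"""Shared fixtures: demography defaults and a fixed synthetic ground truth."""

import numpy as np
import pytest

from eacsim import (
    CancerMortality,
    LifeTable,
    SyntheticTruth,
    TransitionParameters,
    generate_synthetic_targets,
    make_gompertz_life_table,
)

#: Clinically plausible mid-range ground truth for 3-age-group recovery tests,
#: fixed once: an early burst of GERD onset, slowly rising BE inflow, a
#: BE->cancer hazard rising with age, a 8%/yr secular slope and 6-y sojourn.
RECOVERY_TRUTH = TransitionParameters(
    p_normal_gerd=[0.05, 0.01, 0.005],
    p_normal_be=[0.0015, 0.002, 0.0025],
    p_gerd_be=[0.003, 0.004, 0.005],
    r_lsbe_ca=[0.001, 0.002, 0.003],
    secular_slope=0.08,
    mean_sojourn_years=6.0,
)

RECOVERY_YEARS = range(1973, 1983)


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return make_gompertz_life_table()


@pytest.fixture(scope="session")
def cancer_mortality() -> CancerMortality:
    return CancerMortality()


@pytest.fixture(scope="session")
def flat_life_table() -> LifeTable:
    """Constant 10%/yr all-cause mortality at every age (analytic test cases)."""
    return LifeTable(age_min=20, q=np.full(81, 0.1))


@pytest.fixture(scope="session")
def zero_life_table() -> LifeTable:
    return LifeTable(age_min=20, q=np.zeros(81))


@pytest.fixture(scope="session")
def params6() -> TransitionParameters:
    """A plausible 6-group parameter set used across simulation tests."""
    return TransitionParameters(
        p_normal_gerd=[0.04, 0.006, 0.004, 0.004, 0.004, 0.004],
        p_normal_be=[0.002, 0.0015, 0.001, 0.001, 0.001, 0.001],
        p_gerd_be=[0.002, 0.002, 0.002, 0.002, 0.002, 0.002],
        r_lsbe_ca=[0.0002, 0.0005, 0.001, 0.002, 0.003, 0.004],
        secular_slope=0.08,
        mean_sojourn_years=4.5,
    )


@pytest.fixture(scope="session")
def recovery_targets(life_table, cancer_mortality):
    """Zero-noise synthetic targets generated from the fixed ground truth."""
    return generate_synthetic_targets(
        SyntheticTruth(RECOVERY_TRUTH, noise_cv=0.0, seed=0),
        RECOVERY_YEARS,
        life_table,
        cancer_mortality,
    )
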