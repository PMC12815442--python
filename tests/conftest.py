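import numpy as np
import pytest

from wase.simulate import (
    PopulationConfig,
    calibrate_linkage,
    generate_cohort,
    score_cohort,
    simulate_injuries,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 1,000-athlete cohort, scored but without outcomes."""
    return score_cohort(generate_cohort(PopulationConfig()))


@pytest.fixture(scope="session")
def default_linkage(default_cohort):
    return calibrate_linkage(default_cohort)


@pytest.fixture(scope="session")
def injured_cohort(default_cohort, default_linkage):
    """Default cohort with calibrated injury outcomes."""
    return simulate_injuries(default_cohort, default_linkage)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with outcomes, for fast pipeline tests."""
    cohort = score_cohort(generate_cohort(PopulationConfig(n=200, seed=11)))
    linkage = calibrate_linkage(cohort)
    return simulate_injuries(cohort, linkage)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
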