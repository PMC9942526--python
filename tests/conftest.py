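"""Shared fixtures. Expensive recovery runs are session-scoped so the
acceptance suite and unit tests reuse a single computation."""

import numpy as np
import pandas as pd
import pytest

from gamblefit.recovery import parameter_recovery
from gamblefit.simulate import default_population, simulate_cohort
from gamblefit.task import build_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_schedule(seed=7, subjects=1)[0]


@pytest.fixture(scope="session")
def schedule_pair():
    return build_schedule(seed=7, subjects=2)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects simulated from the winning combination."""
    pop = default_population("D5-BMT3", 6, seed=21)
    return simulate_cohort(pop)


@pytest.fixture(scope="session")
def small_cohort_nolearn():
    pop = default_population("D1-none", 8, seed=22)
    return simulate_cohort(pop)


@pytest.fixture(scope="session")
def recovery_d5bmt3_200():
    """The parameter-recovery backbone: 200 subjects from D5-BMT3, MAP refit.

    Session-scoped: shared by the acceptance criterion and the
    broken-pairing / cross-correlation contract tests (~45 s once).
    """
    return parameter_recovery("D5-BMT3", 200, seed=11, mode="map")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
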