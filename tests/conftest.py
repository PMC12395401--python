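"""Shared fixtures: the two reference synthetic pipelines (one per sex).

The girls/boys runs mirror the package's standard recovery benchmark:
calibrate the sex's reference curve, simulate n=100 subjects with the
default generator, apply the inclusion filter and fit by MAP.  They are
session-scoped because several test modules interrogate the same fit.
"""

import warnings

import numpy as np
import pytest

from sitarbayes import (
    apply_inclusion_filter,
    fit_map,
    individual_landmarks,
    population_landmarks,
    simulate,
)


class _Run:
    def __init__(self, sex: str, seed: int):
        self.cohort, self.truth = simulate.generate_default_cohort(
            sex, n_subjects=100, seed=seed
        )
        self.kept, self.exclusions = apply_inclusion_filter(self.cohort)
        self.fit = fit_map(self.kept)
        self.pop = population_landmarks(self.fit)
        self.ind = individual_landmarks(self.fit)
        self.targets = dict(
            zip(("atgv", "tgv", "aphv", "phv"), self.truth.config.landmark_targets)
        )


@pytest.fixture(scope="session")
def girls_run():
    return _Run("F", seed=11)


@pytest.fixture(scope="session")
def boys_run():
    return _Run("M", seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, _ = simulate.generate_default_cohort("F", n_subjects=8, seed=5)
    return cohort


@pytest.fixture(autouse=True)
def _quiet_arviz():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*ArviZ.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
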