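"""Shared fixtures: simulated experiments reused across test modules.

Expensive 2000-feature simulations are session-scoped so the calibration,
parameter-recovery and permutation suites share one computation each.
"""

import numpy as np
import pytest

from senseq.detest import run_de_tests
from senseq.normalization import size_factors_median_ratio
from senseq.synthetic import (
    DispersionModel,
    LfcDistribution,
    SimulationConfig,
    simulate_counts,
)


@pytest.fixture(scope="session")
def null_experiment():
    """2000 features, 4 RNAi vs 3 WT, no true differential expression."""
    config = SimulationConfig(n_features=2000, frac_de=0.0, seed=11)
    return simulate_counts(config)


@pytest.fixture(scope="session")
def null_results(null_experiment):
    """Full three-test result table on the null experiment."""
    return run_de_tests(null_experiment.counts, null_experiment.samples)


@pytest.fixture(scope="session")
def alpha02_experiment():
    """Null data with constant dispersion 0.2 for parameter recovery."""
    config = SimulationConfig(
        n_features=2000, frac_de=0.0,
        dispersion=DispersionModel(alpha0=0.2, alpha1=0.0), seed=5,
    )
    experiment = simulate_counts(config)
    factors = size_factors_median_ratio(experiment.counts)
    return experiment, factors


@pytest.fixture(scope="session")
def alpha01_experiment():
    """Null data with constant dispersion 0.1 for the local variance fit."""
    config = SimulationConfig(
        n_features=2000, frac_de=0.0,
        dispersion=DispersionModel(alpha0=0.1, alpha1=0.0), seed=6,
    )
    experiment = simulate_counts(config)
    factors = size_factors_median_ratio(experiment.counts)
    return experiment, factors


@pytest.fixture(scope="session")
def poisson_experiment():
    """Null Poisson data (dispersion 0), the degenerate NB limit."""
    config = SimulationConfig(
        n_features=2000, frac_de=0.0,
        dispersion=DispersionModel(alpha0=0.0, alpha1=0.0), seed=7,
    )
    experiment = simulate_counts(config)
    factors = size_factors_median_ratio(experiment.counts)
    return experiment, factors


@pytest.fixture(scope="session")
def small_experiment():
    """A quick 300-feature experiment with default (5.5%) DE structure."""
    return simulate_counts(SimulationConfig(n_features=300, seed=1))


def strong_effect_config(seed: int, n_features: int = 1000) -> SimulationConfig:
    """Large genotype effects (median 5.7-fold) for structure-recovery checks."""
    return SimulationConfig(
        n_features=n_features, frac_de=0.25, seed=seed,
        lfc=LfcDistribution(location=2.5, scale=0.3),
    )
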