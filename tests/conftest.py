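"""Shared fixtures: small datasets, a quick trained potential, and the
independently located surrogate minimum."""

from __future__ import annotations

import numpy as np
import pytest

import dimergpr as dg
from dimergpr.gpr import TrainingConfig
from dimergpr.training import train_dimer_potential


@pytest.fixture(scope="session")
def oracle_spec() -> dg.OraclePotentialSpec:
    return dg.OraclePotentialSpec()


@pytest.fixture(scope="session")
def small_dataset() -> dg.Dataset:
    """400 WD24-style dimers, fixed seed."""
    return dg.generate_dataset(dg.GeneratorConfig(n_geometries=400, seed=11))


@pytest.fixture(scope="session")
def small_labeled(small_dataset, oracle_spec):
    return dg.label_dataset(small_dataset, oracle_spec)


@pytest.fixture(scope="session")
def small_potential(small_labeled):
    """A quick six-atom potential trained on 250 surrogate-labeled dimers;
    accurate enough for interpolation/consistency checks."""
    return train_dimer_potential(
        small_labeled[:250], TrainingConfig(seed=3, n_restarts=3, max_iter=100))


@pytest.fixture(scope="session")
def surrogate_minimum(oracle_spec):
    """(geometry, energy) of the surrogate's bound dimer minimum, located by
    dense scan plus gradient refinement on the analytic surface."""
    return dg.locate_minimum(oracle_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    from dimergpr.generator import random_rotation

    return random_rotation(rng), rng.uniform(-5.0, 5.0, 3)
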