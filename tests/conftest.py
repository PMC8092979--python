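"""Shared fixtures: small planted-structure trajectories and helpers."""

import numpy as np
import pytest

from allopath import (
    EnergyTrajectory,
    GeneratorConfig,
    generate_energy_trajectory,
)
from allopath.energy_io import COMPONENT_TERMS


def make_trajectory(values_by_term, residue_ids=None):
    """Build an EnergyTrajectory from per-term (R, N) arrays.

    Terms not supplied default to distinct deterministic non-constant
    series so every correlation is defined.
    """
    some = next(iter(values_by_term.values()))
    shape = np.asarray(some, dtype=float).shape
    if residue_ids is None:
        residue_ids = np.arange(1, shape[0] + 1)
    components = {}
    for k, term in enumerate(COMPONENT_TERMS):
        if term in values_by_term:
            components[term] = np.asarray(values_by_term[term], dtype=float)
        else:
            base = np.arange(shape[1], dtype=float)
            components[term] = np.tile(base, (shape[0], 1)) * (k + 1)
    return EnergyTrajectory(residue_ids=np.asarray(residue_ids), components=components)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator conditions with a 3-residue planted backbone."""
    return GeneratorConfig(
        n_residues=60,
        n_snapshots=400,
        pathway_residues=(10, 20, 30),
        sources=(40, 45),
        sinks=(5, 55),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_energy(small_config):
    traj, truth = generate_energy_trajectory(small_config)
    return traj, truth


@pytest.fixture(scope="session")
def default_energy():
    """One full-scale draw under the default study conditions."""
    config = GeneratorConfig(seed=5)
    traj, truth = generate_energy_trajectory(config)
    return config, traj, truth
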