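"""Shared fixtures: small synthetic trajectories with known dynamics."""

import numpy as np
import pytest

from hydroshell import GeneratorConfig, generate


@pytest.fixture(scope="session")
def free_traj():
    """Free diffusion, D = 0.01 nm^2/ps, 400 particles x 2000 frames."""
    cfg = GeneratorConfig(400, 0.1, 2000, 5.0, 101, "free_diffusion", {"D": 0.01})
    return generate(cfg)


@pytest.fixture(scope="session")
def caged_traj():
    """Pure cage rattling (no hops), sigma = 0.0224 nm -> MSD plateau 6 sigma^2."""
    cfg = GeneratorConfig(
        500, 0.1, 3000, 5.0, 102, "caged_hopping", {"sigma": 0.0224}
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def hopping_traj():
    """Cage rattling with Poisson hops onto the first three neighbour shells."""
    cfg = GeneratorConfig(
        800, 0.1, 4000, 5.0, 103, "caged_hopping",
        {"sigma": 0.0224, "hop_rate": 2e-3, "hop_distances": [0.29, 0.45, 0.67]},
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def static_traj():
    """Frozen particles: sigma = 0, no hops."""
    cfg = GeneratorConfig(100, 0.1, 200, 5.0, 104, "caged_hopping", {"sigma": 0.0})
    return generate(cfg)


@pytest.fixture(scope="session")
def protein_scene_traj():
    cfg = GeneratorConfig(
        300, 0.1, 50, 6.0, 105, "protein_scene", {"n_protein": 25, "D": 0.005}
    )
    return generate(cfg)


def per_particle_se(values_2d: np.ndarray) -> float:
    """Standard error of an (origins x particles) sample, treating particles
    as the independent units (origins of one particle are correlated)."""
    per_particle = values_2d.mean(axis=0)
    return float(per_particle.std(ddof=1) / np.sqrt(per_particle.size))
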