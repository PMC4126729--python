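"""Shared fixtures: small seeded clouds and analytic fixtures."""

import numpy as np
import pytest

import afpq


@pytest.fixture(scope="session")
def carpet4() -> afpq.RasterImage:
    return afpq.generate_sierpinski_carpet(4)


@pytest.fixture(scope="session")
def cascade_weights() -> tuple[float, float, float, float]:
    return (0.4, 0.3, 0.2, 0.1)


@pytest.fixture(scope="session")
def cascade8(cascade_weights) -> afpq.ConcentrationMap:
    return afpq.generate_deterministic_cascade(cascade_weights, 8)


@pytest.fixture(scope="session")
def base_params() -> afpq.FingerprintParams:
    return afpq.FingerprintParams(n_particles=20_000, seed=42)


@pytest.fixture(scope="session")
def base_cloud(base_params) -> afpq.ParticleCloud:
    return afpq.generate_fingerprint(base_params)


@pytest.fixture(scope="session")
def uniform_cloud() -> afpq.ParticleCloud:
    """Uniformly distributed cloud on the disk (background component only)."""
    params = afpq.FingerprintParams(
        n_particles=50_000,
        vortex_weight=0.0,
        stripe_weight=0.0,
        background_weight=1.0,
        seed=7,
    )
    return afpq.generate_fingerprint(params)


def brute_force_box_count(grid: np.ndarray, eps: int) -> int:
    """Naive double-loop occupied-box counter (top-left anchored grid)."""
    h, w = grid.shape
    count = 0
    for i0 in range(0, h, eps):
        for j0 in range(0, w, eps):
            if grid[i0 : i0 + eps, j0 : j0 + eps].any():
                count += 1
    return count
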