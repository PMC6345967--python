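import numpy as np
import pytest

from tfmkit import (ElasticSubstrate, TractionGrid, assemble_irregular,
                    assemble_regular, make_benchmark_scene,
                    sample_displacements)
from tfmkit.synthetic import DEFAULT_PIXEL_SIZE


@pytest.fixture(scope="session")
def substrate():
    return ElasticSubstrate(youngs_modulus=10_000.0, poisson_ratio=0.3)


@pytest.fixture(scope="session")
def grid8(substrate):
    return TractionGrid(shape=(8, 8), mesh_constant=0.5, origin=(0.25, 0.25))


@pytest.fixture(scope="session")
def op8(grid8, substrate):
    """Regular 8x8 operator (128 x 128), shared across tests."""
    return assemble_regular(grid8, substrate)


@pytest.fixture(scope="session")
def desk_problem(substrate):
    """Reduced benchmark problem: 15-spot scene, 1 um mesh, 800 samples.

    Returns (scene, grid, operator in pix units, noise-free displacement
    field in pix units).  Shared by the Bayesian and selection tests.
    """
    scene = make_benchmark_scene("fifteen_spot_0_250Pa", seed=1)
    grid = TractionGrid(shape=(25, 25), mesh_constant=1.0, origin=(0.5, 0.5))
    field = sample_displacements(scene, 800, seed=101)
    op = assemble_irregular(field.positions, grid, scene.substrate)
    return (scene, grid, op.in_units("pix", DEFAULT_PIXEL_SIZE),
            field.in_units("pix", DEFAULT_PIXEL_SIZE))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
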