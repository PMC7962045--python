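import numpy as np
import pytest

from thermosole import (
    BoundarySpec,
    GridResolution,
    LayerSpec,
    MaterialProps,
    build_domain,
    foot_tissue_layers,
    insole_shoe_layers,
)


@pytest.fixture
def slab_material():
    """Inert conductive slab material (no perfusion, no metabolic heat)."""
    return MaterialProps(
        "slab", density=1000.0, thermal_conductivity=0.5, specific_heat=1000.0,
        biological=False,
    )


@pytest.fixture
def full_stack():
    """Tissue + insole layer stack of the published configuration."""
    return foot_tissue_layers() + insole_shoe_layers()


@pytest.fixture
def coarse_resolution():
    """Small lateral cell count for fast laterally-uniform solves."""
    return GridResolution(dx=0.065, dy=0.0225)


def uniform_column_grid(layers, n_tissue, dx=0.01, footprint=(0.02, 0.02), res=None):
    """Tiny laterally-uniform grid helper used across solver tests."""
    res = res or GridResolution(dx=dx, dy=dx)
    return build_domain(
        tissue_layers=layers[:n_tissue],
        insole_layers=layers[n_tissue:],
        footprint=footprint,
        resolution=res,
    )


@pytest.fixture
def column_grid():
    """Factory fixture for tiny laterally-uniform grids."""
    return uniform_column_grid


@pytest.fixture
def standard_bc():
    return BoundarySpec(floor_h=5.0, floor_T_env=20.0, sock_resistance=0.02)
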