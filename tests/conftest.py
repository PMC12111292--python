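"""Shared fixtures: small scenarios sized for fast, exact checks."""

import numpy as np
import pytest

import rdnsim as rd


@pytest.fixture(scope="session")
def small_invivo_config():
    """In-vivo preset shrunk to a 13x13x15 mm block for quick solves."""
    return rd.build_scenario(
        "in_vivo",
        {
            "domain_size": (13.0, 13.0, 15.0),
            "grid_spacing": 0.5,
            "duration": 2.0,
            "layout": {"axial_pitch": 0.8},
        },
    )


@pytest.fixture(scope="session")
def small_grid(small_invivo_config):
    grid = rd.discretize(small_invivo_config)
    rd.place_electrodes(grid, small_invivo_config.layout)
    return grid


@pytest.fixture(scope="session")
def small_basis(small_invivo_config, small_grid):
    sigma = rd.build_sigma_map(small_grid, small_invivo_config.materials)
    return rd.solve_basis_potentials(small_grid, sigma)


@pytest.fixture(scope="session")
def short_run(small_invivo_config):
    """A complete (2 s) ablation run on the small domain."""
    return rd.run_ablation(small_invivo_config)


def make_single_electrode_grid(
    n=(12, 12, 12), spacing=0.5e-3, electrode_cells=((5, 5, 5), (6, 5, 5))
):
    """Tiny handmade grid: uniform tissue with a few electrode cells."""
    from rdnsim.geometry import (
        DomainGrid,
        ELECTRODE_BASE,
        LABEL_TISSUE,
    )

    labels = np.full(n, LABEL_TISSUE, dtype=np.int32)
    for ijk in electrode_cells:
        labels[ijk] = ELECTRODE_BASE
    grid = DomainGrid(
        spacing=spacing,
        shape=tuple(n),
        origin=(0.0, 0.0, 0.0),
        labels=labels,
        lumen_radius=1e-3,
        n_electrodes=1,
    )
    return grid
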