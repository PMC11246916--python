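"""Shared fixtures.  Expensive FEM solves are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from tdcsphere.fem import build_source, compute_efield, point_source, solve_potential
from tdcsphere.montage import MontageSpec, place_electrodes
from tdcsphere.oracle import default_oracle_spec, oracle_voxel_model
from tdcsphere.phantom import (
    build_sphere_phantom,
    conductivity_table,
    default_head_spec,
)


@pytest.fixture(scope="session")
def table():
    return conductivity_table()


@pytest.fixture(scope="session")
def head_spec():
    return default_head_spec()


@pytest.fixture(scope="session")
def head_h4(head_spec):
    """Default 6-shell phantom voxelized at the coarse 4 mm test grid."""
    return build_sphere_phantom(head_spec, 4.0, phantom_id="head-h4")


@pytest.fixture(scope="session")
def oracle_case_h4(table):
    """4-layer verification sphere at h=4 with antipodal single-voxel ±2 mA
    sources, solved to 1e-6: (spec, model, source, potential)."""
    spec = default_oracle_spec()
    model = oracle_voxel_model(spec, 4.0)
    R = spec.R_mm
    src = point_source(model, np.array([0.0, 0.0, R]), np.array([0.0, 0.0, -R]), 2.0)
    phi = solve_potential(model, table, src, 1e-6)
    return spec, model, src, phi


@pytest.fixture(scope="session")
def montage_solution_h4(head_h4, table):
    """FCz-POz at 2 mA on the default phantom at h=4, solved to 1e-6:
    (placement, source, potential, efield)."""
    m = MontageSpec("FCz", "POz", 2.0)
    placement = place_electrodes(head_h4, m)
    src = build_source(placement.model, placement, m.current_mA)
    phi = solve_potential(placement.model, table, src, 1e-6)
    ef = compute_efield(phi, placement.model)
    return placement, src, phi, ef
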