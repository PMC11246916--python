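"""FEM solver: sources, discrete solution properties, field derivation and
current conservation."""

import numpy as np
import pytest

from tdcsphere.fem import (
    PotentialField,
    build_source,
    check_current_conservation,
    compute_efield,
    solve_potential,
)
from tdcsphere.phantom import Tissue, TissueConductivityTable, VoxelModel, conductivity_table


class _Placement:
    def __init__(self, anode, cathode):
        self.anode_voxels = np.asarray(anode)
        self.cathode_voxels = np.asarray(cathode)


def _cube_model(n=12, h=1.0, tissue=Tissue.GRAY_MATTER):
    labels = np.full((n, n, n), int(tissue), dtype=np.int16)
    return VoxelModel(labels, h, np.zeros(3), {"phantom_id": "cube"})


def _face_placement(n):
    grid = np.argwhere(np.ones((n, n), dtype=bool))
    anode = np.column_stack([np.zeros(len(grid), dtype=int), grid[:, 0], grid[:, 1]])
    cathode = np.column_stack([np.full(len(grid), n - 1), grid[:, 0], grid[:, 1]])
    return _Placement(anode, cathode)


def test_source_density_from_definition():
    """2 mA over 1000 anode voxels of (1 mm)³ gives 2×10⁻³/10⁻⁶ A/m³."""
    model = _cube_model(n=12)
    idx = np.argwhere(np.ones((12, 12, 12), dtype=bool))
    src = build_source(model, _Placement(idx[:1000], idx[-500:]), 2.0)
    assert src.density_A_m3[0] == pytest.approx(2e-3 / (1000 * 1e-9))
    assert abs(src.total_current_A()) < 1e-18


def test_zero_current_source_is_zero():
    model = _cube_model(n=6)
    src = build_source(model, _face_placement(6), 0.0)
    assert np.all(src.density_A_m3 == 0.0)
    phi = solve_potential(model, conductivity_table(), src)
    assert np.all(phi.phi == 0.0)


def test_source_polarity_swap_negates_density():
    model = _cube_model(n=6)
    p = _face_placement(6)
    fwd = build_source(model, p, 2.0)
    rev = build_source(model, _Placement(p.cathode_voxels, p.anode_voxels), 2.0)
    np.testing.assert_allclose(np.sort(fwd.density_A_m3), np.sort(-rev.density_A_m3))


def test_empty_electrode_rejected():
    model = _cube_model(n=6)
    with pytest.raises(ValueError, match="nonempty"):
        build_source(model, _Placement(np.empty((0, 3), int), np.ones((1, 3), int)), 2.0)


def test_uniform_conductor_has_uniform_field():
    """Opposing-face injection through a homogeneous cube reproduces the 1-D
    closed form E = J/σ to machine precision in the interior."""
    n, h, sigma = 16, 2.0, 0.2
    model = _cube_model(n=n, h=h)
    src = build_source(model, _face_placement(n), 2.0)
    phi = solve_potential(model, conductivity_table(), src, tol=1e-10)
    E = compute_efield(phi, model).E
    expected = 2e-3 / (n * h * 1e-3) ** 2 / sigma
    interior = E[4:-4, 4:-4, 4:-4]
    np.testing.assert_allclose(interior[..., 0], expected, rtol=1e-9)
    np.testing.assert_allclose(interior[..., 1:], 0.0, atol=expected * 1e-9)


def test_gradient_of_linear_potential_is_constant():
    """φ = -x (in m, scaled to mm grid) gives E = (1000, 0, 0) V/m."""
    model = _cube_model(n=8, h=1.0)
    nx, ny, nz = (s + 1 for s in model.shape)
    x_mm = np.arange(nx)[:, None, None] * model.h_mm
    phi = PotentialField(np.broadcast_to(-x_mm * 1e-3 * 1000.0, (nx, ny, nz)).copy(), model)
    E = compute_efield(phi, model).E
    np.testing.assert_allclose(E[..., 0], 1000.0, rtol=1e-12)
    np.testing.assert_allclose(E[..., 1:], 0.0, atol=1e-9)


def test_gauge_invariance_of_field():
    model = _cube_model(n=8)
    src = build_source(model, _face_placement(8), 2.0)
    phi = solve_potential(model, conductivity_table(), src)
    shifted = PotentialField(phi.phi + 0.123, model)
    np.testing.assert_allclose(
        compute_efield(phi, model).E, compute_efield(shifted, model).E, atol=1e-9
    )


def test_grid_mismatch_rejected(head_h4):
    model = _cube_model(n=8)
    src = build_source(model, _face_placement(8), 2.0)
    phi = solve_potential(model, conductivity_table(), src)
    with pytest.raises(ValueError, match="grid"):
        compute_efield(phi, head_h4)


def test_polarity_swap_negates_solution():
    model = _cube_model(n=10)
    p = _face_placement(10)
    table = conductivity_table()
    fwd = solve_potential(model, table, build_source(model, p, 2.0), 1e-8)
    rev = solve_potential(
        model, table, build_source(model, _Placement(p.cathode_voxels, p.anode_voxels), 2.0), 1e-8
    )
    np.testing.assert_allclose(fwd.phi, -rev.phi, atol=1e-12 * np.abs(fwd.phi).max())
    Ef = compute_efield(fwd, model)
    Er = compute_efield(rev, model)
    np.testing.assert_allclose(Ef.magnitude, Er.magnitude, rtol=1e-9)


def test_linearity_in_current_and_superposition():
    model = _cube_model(n=10)
    p = _face_placement(10)
    table = conductivity_table()
    one = solve_potential(model, table, build_source(model, p, 2.0), 1e-8)
    two = solve_potential(model, table, build_source(model, p, 4.0), 1e-8)
    np.testing.assert_allclose(two.phi, 2.0 * one.phi, rtol=1e-6, atol=1e-12)

    # superposition: a second, different source pair
    n = 10
    grid = np.argwhere(np.ones((n, n), dtype=bool))
    p2 = _Placement(
        np.column_stack([grid[:, 0], np.zeros(len(grid), dtype=int), grid[:, 1]]),
        np.column_stack([grid[:, 0], np.full(len(grid), n - 1), grid[:, 1]]),
    )
    sol2 = solve_potential(model, table, build_source(model, p2, 2.0), 1e-8)
    s12 = build_source(model, p, 2.0)
    s22 = build_source(model, p2, 2.0)
    both = type(s12)(
        anode_voxels=np.vstack([s12.anode_voxels, s22.anode_voxels]),
        cathode_voxels=np.vstack([s12.cathode_voxels, s22.cathode_voxels]),
        density_A_m3=np.concatenate(
            [
                s12.density_A_m3[: len(s12.anode_voxels)],
                s22.density_A_m3[: len(s22.anode_voxels)],
                s12.density_A_m3[len(s12.anode_voxels) :],
                s22.density_A_m3[len(s22.anode_voxels) :],
            ]
        ),
        current_mA=2.0,
        shape=model.shape,
        h_m=model.h_mm * 1e-3,
    )
    sol_both = solve_potential(model, table, both, 1e-8)
    np.testing.assert_allclose(
        sol_both.phi, one.phi + sol2.phi, atol=1e-6 * np.abs(one.phi).max()
    )


def test_global_conductivity_scaling(oracle_case_h4, table):
    """σ → kσ at fixed current scales E by 1/k (solved on the 4-layer sphere)."""
    spec, model, src, phi = oracle_case_h4
    doubled = solve_potential(model, table.scaled(2.0), src, 1e-6)
    np.testing.assert_allclose(doubled.phi, 0.5 * phi.phi, rtol=1e-6, atol=1e-10)


def test_unbalanced_source_rejected():
    model = _cube_model(n=6)
    src = build_source(model, _face_placement(6), 2.0)
    src.density_A_m3 = src.density_A_m3 + 1.0  # break the balance
    with pytest.raises(ValueError, match="unbalanced"):
        solve_potential(model, conductivity_table(), src)


def test_current_conservation_monotone_in_tolerance(oracle_case_h4, table):
    """Enclosed-surface current matches the injected 2 mA within 1% at
    tol=1e-6 and degrades at tol=1e-2."""
    spec, model, src, phi = oracle_case_h4
    tight = check_current_conservation(model, table, phi, src)
    assert tight["relative_flux_error"] < 0.01
    loose_phi = solve_potential(model, table, src, 1e-2)
    loose = check_current_conservation(model, table, loose_phi, src)
    assert loose["relative_flux_error"] > tight["relative_flux_error"]


def test_zero_source_zero_flux():
    model = _cube_model(n=6)
    table = conductivity_table()
    src = build_source(model, _face_placement(6), 0.0)
    phi = solve_potential(model, table, src)
    rep = check_current_conservation(model, table, phi, src)
    assert rep["enclosed_current_A"] == pytest.approx(0.0, abs=1e-15)


def test_partial_volume_changes_element_conductivity():
    """A mixed voxel's effective conductivity is the volume-weighted mean."""
    from tdcsphere.fem import assemble_system

    model = _cube_model(n=4, h=1.0)
    plain, _, _ = assemble_system(model, conductivity_table())
    mixed = model.copy()
    mixed.mixed = (
        np.array([[1, 1, 1]], dtype=np.int32),
        (int(Tissue.GRAY_MATTER), int(Tissue.CSF)),
        np.array([[0.5, 0.5]], dtype=np.float32),
    )
    avg, _, _ = assemble_system(mixed, conductivity_table())
    # mixed element conductance rose from 0.2 to (0.2+1.8)/2 = 1.0
    assert avg.diagonal().max() > plain.diagonal().max()
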