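"""Voxel finite-element solver for the volume-conduction equation.

The quasi-static potential obeys ``∇·(σ∇φ) = -i`` with homogeneous Neumann
boundary conditions (no current leaves the head except through the
electrodes).  The discretization uses first-order (trilinear) shape
functions on the cubical voxels themselves, one conductivity per element
taken from its tissue label.  The resulting symmetric positive
semi-definite system — singular because a pure-Neumann potential is defined
only up to a constant — is solved by Jacobi-preconditioned conjugate
gradients with the constant mode projected out every iteration; the
returned potential is zero-mean over the conducting domain.

Sign convention: the weak form is ``∫ σ∇φ·∇v dV = ∫ i v dV`` with ``i > 0``
at the anode, so the potential is positive under the anode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantom import TissueConductivityTable, VoxelModel

log = logging.getLogger(__name__)

_GAUSS = 1.0 / np.sqrt(3.0)
_CORNERS = np.array(
    [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
)  # local node order: k fastest


def _reference_stiffness() -> np.ndarray:
    """8x8 stiffness ∫ ∇N_a·∇N_b dV of the unit-cube trilinear element,
    integrated exactly with 2x2x2 Gauss quadrature."""
    K = np.zeros((8, 8))
    pts = 0.5 + 0.5 * np.array([-_GAUSS, _GAUSS])
    for gx in pts:
        for gy in pts:
            for gz in pts:
                grads = np.empty((8, 3))
                for a, (ci, cj, ck) in enumerate(_CORNERS):
                    sx = gx if ci else 1 - gx
                    sy = gy if cj else 1 - gy
                    sz = gz if ck else 1 - gz
                    dx = 1.0 if ci else -1.0
                    dy = 1.0 if cj else -1.0
                    dz = 1.0 if ck else -1.0
                    grads[a] = (dx * sy * sz, sx * dy * sz, sx * sy * dz)
                K += (grads @ grads.T) / 8.0  # weight = 1/8 per Gauss point
    return K


_K_REF = _reference_stiffness()


@dataclass
class SourceDistribution:
    """Per-voxel volumetric current source density i (A/m^3), nonzero only on
    the rubber-sheet voxels; the anode carries +I in total, the cathode -I."""

    anode_voxels: np.ndarray  # (n, 3) indices
    cathode_voxels: np.ndarray
    density_A_m3: np.ndarray  # per listed voxel, anode block then cathode block
    current_mA: float
    shape: tuple

    def total_current_A(self) -> float:
        """Signed sum of source density x voxel volume (should be ~0)."""
        return float(np.sum(self.density_A_m3 * self._voxel_volume_m3))

    @property
    def _voxel_volume_m3(self) -> float:
        return self.h_m**3

    h_m: float = 0.0

    def voxel_indices(self) -> np.ndarray:
        return np.vstack([self.anode_voxels, self.cathode_voxels])


def build_source(model: VoxelModel, placement, I_mA: float) -> SourceDistribution:
    """Uniform volumetric injection: +I spread over the anode rubber voxels,
    -I over the cathode's; exact global balance enforced by subtracting the
    floating-point residue from the cathode block."""
    anode = np.asarray(placement.anode_voxels, dtype=np.int64)
    cathode = np.asarray(placement.cathode_voxels, dtype=np.int64)
    if len(anode) == 0 or len(cathode) == 0:
        raise ValueError("anode and cathode rubber-voxel sets must be nonempty")
    inter = set(map(tuple, anode)) & set(map(tuple, cathode))
    if inter:
        raise ValueError("anode and cathode voxel sets overlap")
    h_m = model.h_mm * 1e-3
    vol = h_m**3
    I_A = I_mA * 1e-3
    dens = np.concatenate(
        [np.full(len(anode), I_A / (len(anode) * vol)), np.full(len(cathode), -I_A / (len(cathode) * vol))]
    )
    residue = dens.sum() * vol
    dens[len(anode):] -= residue / (len(cathode) * vol)
    return SourceDistribution(anode, cathode, dens, I_mA, model.shape, h_m)


def point_source(model: VoxelModel, anode_mm, cathode_mm, I_mA: float) -> SourceDistribution:
    """Single-voxel ±I sources at the non-air voxels nearest two world points
    (used for analytic-oracle comparisons)."""
    from .phantom import Tissue

    nz = np.argwhere(model.labels != Tissue.AIR)
    centers = model.origin_mm + (nz + 0.5) * model.h_mm

    def nearest(p):
        d2 = np.sum((centers - np.asarray(p, dtype=float)) ** 2, axis=1)
        return nz[int(np.argmin(d2))][None, :]

    class _P:
        anode_voxels = nearest(anode_mm)
        cathode_voxels = nearest(cathode_mm)

    return build_source(model, _P, I_mA)


@dataclass
class PotentialField:
    """Nodal scalar potential (V) on the (nx+1, ny+1, nz+1) grid-node lattice;
    zero-mean over conducting-domain nodes (the chosen gauge)."""

    phi: np.ndarray
    model: VoxelModel
    gauge: str = "zero-mean"
    iterations: int = 0
    residual_history: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class EFieldSample:
    """Electric-field vectors E = -∇φ (V/m) at element (voxel) centers."""

    E: np.ndarray  # (nx, ny, nz, 3)
    model: VoxelModel

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)


def _node_ids(shape):
    nx, ny, nz = shape
    return (nx + 1, ny + 1, nz + 1)


def assemble_system(model: VoxelModel, table: TissueConductivityTable):
    """Galerkin stiffness matrix over non-air elements, restricted to the
    touched nodes.  Returns (A_csr, touched_node_flat_ids, node_grid_shape).

    Element stiffness is ``σ_e · h · K_ref`` (gradients scale 1/h, volume h^3;
    conductivities in S/m with h in meters give conductances in siemens).
    """
    labels = model.labels
    sigma = table.as_array(int(labels.max()) + 1)
    elem_sigma = sigma[labels]
    if model.mixed is not None:
        # volume-weighted conductivity for interface-straddling voxels
        idx, tissues, fracs = model.mixed
        sigma_t = table.as_array(max(tissues) + 1)[list(tissues)]
        elem_sigma[idx[:, 0], idx[:, 1], idx[:, 2]] = fracs @ sigma_t
    ii, jj, kk = np.nonzero(elem_sigma > 0)
    if len(ii) == 0:
        raise ValueError("model contains no conducting voxels")
    nshape = _node_ids(labels.shape)
    ny1, nz1 = nshape[1], nshape[2]

    conn = np.empty((len(ii), 8), dtype=np.int64)
    for a, (di, dj, dk) in enumerate(_CORNERS):
        conn[:, a] = ((ii + di) * ny1 + (jj + dj)) * nz1 + (kk + dk)

    touched, conn_c = np.unique(conn, return_inverse=True)
    conn_c = conn_c.reshape(conn.shape).astype(np.int32)
    n = len(touched)

    h_m = model.h_mm * 1e-3
    coef = (elem_sigma[ii, jj, kk] * h_m).astype(np.float64)
    data = coef[:, None] * _K_REF.reshape(1, 64)
    rows = np.repeat(conn_c, 8, axis=1).ravel()
    cols = np.tile(conn_c, (1, 8)).ravel()
    A = sp.coo_matrix((data.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return A, touched, nshape


def _load_vector(source: SourceDistribution, touched, nshape, n, h_m):
    """FEM load vector: each source voxel's current splits equally over its 8
    nodes (trilinear shape-function integral of a uniform density)."""
    ny1, nz1 = nshape[1], nshape[2]
    vox = source.voxel_indices()
    conn = np.empty((len(vox), 8), dtype=np.int64)
    for a, (di, dj, dk) in enumerate(_CORNERS):
        conn[:, a] = ((vox[:, 0] + di) * ny1 + (vox[:, 1] + dj)) * nz1 + (vox[:, 2] + dk)
    per_node = np.repeat(source.density_A_m3 * h_m**3 / 8.0, 8)
    pos = np.searchsorted(touched, conn.ravel())
    if np.any(pos >= n) or np.any(touched[np.minimum(pos, n - 1)] != conn.ravel()):
        raise ValueError("source voxels lie outside the conducting domain")
    b = np.zeros(n)
    np.add.at(b, pos, per_node)
    return b


def _pcg(A, b, tol, maxiter):
    """Jacobi-preconditioned CG for the singular Neumann system; the constant
    nullspace component is projected out of every preconditioned residual."""
    d = A.diagonal()
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal: disconnected or non-conducting node")
    inv_d = 1.0 / d
    n = len(b)
    x = np.zeros(n)
    r = b - 0.0  # x = 0
    r = r - r.mean()
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return x, 0, np.zeros(1)
    z = inv_d * r
    z -= z.mean()
    p = z.copy()
    rz = r @ z
    hist = []
    for it in range(1, maxiter + 1):
        Ap = A @ p
        alpha = rz / (p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        r -= r.mean()
        rel = np.linalg.norm(r) / bnorm
        hist.append(rel)
        if rel <= tol:
            return x - x.mean(), it, np.asarray(hist)
        z = inv_d * r
        z -= z.mean()
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise RuntimeError(
        f"CG failed to reach tol={tol:g} in {maxiter} iterations "
        f"(last relative residual {hist[-1]:.3e})",
    )


def solve_potential(
    model: VoxelModel,
    table: TissueConductivityTable,
    source: SourceDistribution,
    tol: float = 1e-6,
    maxiter: int = 10000,
) -> PotentialField:
    """Solve the discrete volume-conduction problem to relative residual
    ``tol``; returns the zero-mean nodal potential."""
    A, touched, nshape = assemble_system(model, table)
    h_m = model.h_mm * 1e-3
    b = _load_vector(source, touched, nshape, len(touched), h_m)
    imbalance = abs(b.sum())
    scale = np.abs(b).sum()
    if scale > 0 and imbalance > 1e-9 * scale:
        raise ValueError(f"unbalanced source: net current {imbalance:.3e} A")
    x, it, hist = _pcg(A, b, tol, maxiter)
    log.info("solve_potential: %d nodes, %d CG iterations, rel. residual %.2e",
             len(touched), it, hist[-1] if len(hist) else 0.0)
    phi = np.zeros(int(np.prod(nshape)))
    phi[touched] = x
    return PotentialField(phi.reshape(nshape), model, iterations=it, residual_history=hist)


def compute_efield(phi: PotentialField, model: VoxelModel) -> EFieldSample:
    """E = -∇φ from trilinear shape-function gradients, evaluated at element
    centers.  The center gradient along x is the difference of the two
    x-face-averaged potentials divided by h (and likewise for y, z)."""
    p = phi.phi
    if p.shape != _node_ids(model.shape):
        raise ValueError("potential grid does not match the model grid")
    h_m = model.h_mm * 1e-3
    E = np.empty(model.shape + (3,))
    fx = 0.25 * (p[:, :-1, :-1] + p[:, 1:, :-1] + p[:, :-1, 1:] + p[:, 1:, 1:])
    E[..., 0] = -(fx[1:] - fx[:-1]) / h_m
    fy = 0.25 * (p[:-1, :, :-1] + p[1:, :, :-1] + p[:-1, :, 1:] + p[1:, :, 1:])
    E[..., 1] = -(fy[:, 1:] - fy[:, :-1]) / h_m
    fz = 0.25 * (p[:-1, :-1, :] + p[1:, :-1, :] + p[:-1, 1:, :] + p[1:, 1:, :])
    E[..., 2] = -(fz[:, :, 1:] - fz[:, :, :-1]) / h_m
    return EFieldSample(E, model)


def check_current_conservation(
    model: VoxelModel,
    table: TissueConductivityTable,
    phi: PotentialField,
    source: SourceDistribution,
    margin_voxels: int = 3,
) -> dict:
    """Verification report on a solved system.

    * ``enclosed_current_A``: the discrete flux out of a closed node box
      enclosing the anode assembly, computed by summing (A φ) over the nodes
      inside the box (the discrete divergence theorem); expected = +I.
    * ``max_nodal_residual``: max |b - A φ| over nodes away from the sources,
      relative to the source-vector scale.
    """
    A, touched, nshape = assemble_system(model, table)
    x = phi.phi.reshape(-1)[touched]
    h_m = model.h_mm * 1e-3
    b = _load_vector(source, touched, nshape, len(touched), h_m)
    Ax = A @ x

    lo = source.anode_voxels.min(axis=0) - margin_voxels
    hi = source.anode_voxels.max(axis=0) + 1 + margin_voxels
    ti = np.empty((len(touched), 3), dtype=np.int64)
    ny1, nz1 = nshape[1], nshape[2]
    ti[:, 2] = touched % nz1
    rem = touched // nz1
    ti[:, 1] = rem % ny1
    ti[:, 0] = rem // ny1
    inside = np.all((ti >= lo) & (ti <= hi), axis=1)
    enclosed = float(Ax[inside].sum())

    vox = source.voxel_indices()
    src_lo = vox.min(axis=0) - 1
    src_hi = vox.max(axis=0) + 2
    near_src = np.all((ti >= src_lo) & (ti <= src_hi), axis=1)
    resid = b - Ax
    scale = np.abs(b).max()
    max_res = float(np.abs(resid[~near_src]).max() / scale) if scale > 0 else 0.0

    I_A = source.current_mA * 1e-3
    return {
        "enclosed_current_A": enclosed,
        "expected_current_A": I_A,
        "relative_flux_error": abs(enclosed - I_A) / I_A if I_A > 0 else abs(enclosed),
        "max_nodal_residual": max_res,
    }
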