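"""Closed-form potential of an N-layer concentric sphere with surface
point-current electrodes — the independent verification oracle for the FEM.

For a point source of current I on the outer surface, the interior potential
separates into a Legendre series; within layer j the radial part is
``A_j r^l + B_j r^-(l+1)``, with coefficients matched by continuity of φ and
of the radial current density σ ∂φ/∂r at every interface, regularity at the
center, and the point-source Neumann datum at the outer boundary.  Source
and sink superpose; the l = 0 mode is pure gauge and is dropped.

The per-layer radial basis is rescaled to stay O(1) inside its layer, which
keeps the interface systems well-conditioned up to truncation orders of
several hundred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import Tissue, VoxelModel


@dataclass(frozen=True)
class LayeredSphereSpec:
    """Continuous N-layer sphere: radii strictly increasing (innermost -> outer
    surface, mm) with one conductivity per layer; two surface point electrodes
    carrying ±I."""

    radii_mm: tuple
    sigmas_S_m: tuple
    anode_dir: tuple = (0.0, 0.0, 1.0)
    cathode_dir: tuple = (0.0, 0.0, -1.0)
    current_mA: float = 2.0
    L: int = 200
    tol: float = 1e-8

    def __post_init__(self):
        r = np.asarray(self.radii_mm, dtype=float)
        s = np.asarray(self.sigmas_S_m, dtype=float)
        if len(r) != len(s):
            raise ValueError("one conductivity per layer required")
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("radii must be strictly increasing and positive")
        if np.any(s <= 0):
            raise ValueError("conductivities must be > 0")
        if self.L < 1:
            raise ValueError("series truncation order L must be >= 1")

    @property
    def R_mm(self) -> float:
        return float(self.radii_mm[-1])


def default_oracle_spec(current_mA: float = 2.0, L: int = 200) -> LayeredSphereSpec:
    """4-layer verification geometry: brain 80, CSF 83, skull 87, scalp 92 mm
    with the standard gray-matter / CSF / compact-bone / skin-fat
    conductivities."""
    return LayeredSphereSpec(
        radii_mm=(80.0, 83.0, 87.0, 92.0),
        sigmas_S_m=(0.2, 1.8, 0.008, 0.08),
        current_mA=current_mA,
        L=L,
    )


def oracle_voxel_model(spec: LayeredSphereSpec, h_mm: float, pad_mm: float = 6.0) -> VoxelModel:
    """Voxelization of the 4-layer oracle geometry (gray matter core, CSF,
    compact bone, skin/fat shells) for FEM comparison."""
    from .phantom import SphereLayerSpec, build_sphere_phantom

    labels = (Tissue.SKIN_FAT, Tissue.COMPACT_BONE, Tissue.CSF, Tissue.GRAY_MATTER)
    if len(spec.radii_mm) != 4:
        raise ValueError("oracle_voxel_model expects the 4-layer geometry")
    sspec = SphereLayerSpec(tuple(spec.radii_mm[::-1]), labels)
    return build_sphere_phantom(sspec, h_mm, pad_mm=pad_mm, phantom_id="oracle-4layer")


def _coefficients(spec: LayeredSphereSpec) -> tuple:
    """Per-degree radial coefficients for a UNIT surface point source.

    Layer j (1-based, radii bounds r_{j-1}..r_j, r_0 = 0) uses the scaled basis
    u_j(r) = (r/r_j)^l and, for j >= 2, v_j(r) = (r_{j-1}/r)^(l+1); both lie in
    [0, 1] within their layer.  Returns (alpha, beta) of shape (L+1, N).
    """
    radii = np.asarray(spec.radii_mm, dtype=float) * 1e-3
    sig = np.asarray(spec.sigmas_S_m, dtype=float)
    N = len(radii)
    R = radii[-1]
    L = spec.L
    alpha = np.zeros((L + 1, N))
    beta = np.zeros((L + 1, N))
    nunk = 2 * N - 1

    for l in range(1, L + 1):
        M = np.zeros((nunk, nunk))
        rhs = np.zeros(nunk)

        def col_u(j):  # 0-based layer
            return 0 if j == 0 else 2 * j - 1

        def col_v(j):
            return 2 * j

        # interfaces at r_j between layer j and j+1 (0-based j = 0..N-2)
        for j in range(N - 1):
            r = radii[j]
            rin = radii[j - 1] if j > 0 else 0.0
            row_c, row_f = 2 * j, 2 * j + 1
            u_j, v_j = 1.0, (rin / r) ** (l + 1) if j > 0 else 0.0
            du_j = l / r
            dv_j = -(l + 1) / r * v_j
            u_n = (r / radii[j + 1]) ** l
            v_n = 1.0
            du_n = (l / r) * u_n
            dv_n = -(l + 1) / r
            M[row_c, col_u(j)] = u_j
            M[row_c, col_u(j + 1)] = -u_n
            M[row_c, col_v(j + 1)] = -v_n
            M[row_f, col_u(j)] = sig[j] * du_j
            M[row_f, col_u(j + 1)] = -sig[j + 1] * du_n
            M[row_f, col_v(j + 1)] = -sig[j + 1] * dv_n
            if j > 0:
                M[row_c, col_v(j)] = v_j
                M[row_f, col_v(j)] = sig[j] * dv_j
        # outer Neumann: sigma_N dphi/dr |_R = (2l+1) / (4 pi R^2) per unit I
        jN = N - 1
        vN = (radii[jN - 1] / R) ** (l + 1) if N > 1 else 0.0
        M[-1, col_u(jN)] = sig[jN] * l / R
        if N > 1:
            M[-1, col_v(jN)] = sig[jN] * (-(l + 1) / R) * vN
        rhs[-1] = (2 * l + 1) / (4 * math.pi * R**2)

        sol = np.linalg.solve(M, rhs)
        alpha[l, 0] = sol[0]
        for j in range(1, N):
            alpha[l, j] = sol[col_u(j)]
            beta[l, j] = sol[col_v(j)]
    return alpha, beta


def _legendre_sum(x, coeffs):
    """Σ_l coeffs[l, pt] P_l(x[pt]) via the three-term recurrence."""
    L = coeffs.shape[0] - 1
    total = np.zeros_like(x)
    Pm1 = np.ones_like(x)
    P = x.copy()
    total += coeffs[1] * P if L >= 1 else 0.0
    for l in range(2, L + 1):
        P, Pm1 = ((2 * l - 1) * x * P - (l - 1) * Pm1) / l, P
        total += coeffs[l] * P
    return total


def oracle_potential(spec: LayeredSphereSpec, points_mm: np.ndarray, check_tail: bool = True) -> np.ndarray:
    """Potential (V) at interior query points for the ±I point-electrode pair.

    Points must lie strictly inside the outer radius and more than 1 degree
    (angular) away from each electrode; raises if the Legendre series has not
    converged at the truncation order.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    radii = np.asarray(spec.radii_mm, dtype=float)
    r = np.linalg.norm(pts, axis=1)
    if np.any(r >= radii[-1]):
        raise ValueError("query points must lie strictly inside the outer radius")
    a = np.asarray(spec.anode_dir, dtype=float)
    a = a / np.linalg.norm(a)
    c = np.asarray(spec.cathode_dir, dtype=float)
    c = c / np.linalg.norm(c)
    with np.errstate(invalid="ignore"):
        unit = np.where(r[:, None] > 0, pts / np.maximum(r, 1e-300)[:, None], 0.0)
    mu_a = np.clip(unit @ a, -1.0, 1.0)
    mu_c = np.clip(unit @ c, -1.0, 1.0)
    near = (r > 0.99 * radii[-1]) & (
        (np.degrees(np.arccos(mu_a)) < 1.0) | (np.degrees(np.arccos(mu_c)) < 1.0)
    )
    if np.any(near):
        raise ValueError("query point within 1 degree of an electrode singularity")

    alpha, beta = _coefficients(spec)
    layer = np.searchsorted(radii, r, side="left")  # 0-based layer index
    L = spec.L
    r_m = r * 1e-3
    radii_m = radii * 1e-3
    # radial factor f[l, pt]
    f = np.zeros((L + 1, len(r)))
    for j in range(len(radii)):
        m = layer == j
        if not np.any(m):
            continue
        rj = radii_m[j]
        rin = radii_m[j - 1] if j > 0 else 0.0
        rr = r_m[m]
        ls = np.arange(L + 1)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (rr[None, :] / rj) ** ls
            f[:, m] = alpha[:, j][:, None] * u
            if j > 0:
                v = (rin / np.maximum(rr, 1e-300))[None, :] ** (ls + 1)
                f[:, m] += beta[:, j][:, None] * v

    I_A = spec.current_mA * 1e-3
    phi = I_A * (_legendre_sum(mu_a, f) - _legendre_sum(mu_c, f))
    if check_tail and L >= 20:
        tail = I_A * (
            np.abs(_legendre_sum(mu_a, np.vstack([np.zeros((L - 9, len(r))), f[-10:]])))
            + np.abs(_legendre_sum(mu_c, np.vstack([np.zeros((L - 9, len(r))), f[-10:]])))
        )
        scale = max(np.max(np.abs(phi)), 1e-300)
        if np.max(tail) > max(spec.tol * scale, 1e-12):
            raise RuntimeError(
                f"Legendre series not converged at L={L} "
                f"(tail/peak = {np.max(tail) / scale:.2e}); increase L"
            )
    return phi


def homogeneous_sphere_potential(R_mm, sigma, points_mm, anode_dir, cathode_dir, I_mA) -> np.ndarray:
    """Independent closed form for a homogeneous sphere with two surface point
    electrodes: for one unit source at the surface,
    φ = I/(4πσR) [ 2/d̂ + ln( 2 / (1 - xμ + d̂) ) ] with x = r/R, d̂ = |x - r̂_a|
    (constants are gauge and cancel in the source-sink difference)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    R = R_mm * 1e-3
    r = np.linalg.norm(pts, axis=1) * 1e-3
    x = r / R

    def one(dir_):
        d = np.asarray(dir_, dtype=float)
        d = d / np.linalg.norm(d)
        mu = np.clip((pts * 1e-3) @ d / np.maximum(r, 1e-300), -1.0, 1.0)
        mu = np.where(r > 0, mu, 1.0)
        dd = np.sqrt(1.0 - 2.0 * x * mu + x**2)
        return 2.0 / dd + np.log(2.0 / (1.0 - x * mu + dd))

    I_A = I_mA * 1e-3
    return I_A / (4.0 * math.pi * sigma * R) * (one(anode_dir) - one(cathode_dir))


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-angle lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), z])


def compare_with_fem(
    spec: LayeredSphereSpec,
    model: VoxelModel,
    phi_fem,
    efield=None,
    shell_radius_mm: float | None = None,
    n_points: int = 2000,
    exclusion_deg: float = 10.0,
) -> dict:
    """Relative L2 and max errors of φ (gauge-aligned) and |E| between the FEM
    solution and the series oracle, over a spherical shell (default: 1 mm below
    the innermost 'gray matter' layer boundary), excluding caps around the two
    electrodes."""
    from .cortex import _trilinear_vector
    from .fem import compute_efield

    if model.spec.outer_radius_mm != spec.R_mm:
        raise ValueError("voxel model does not match the oracle geometry")
    rs = shell_radius_mm if shell_radius_mm is not None else spec.radii_mm[0] - 1.0
    dirs = fibonacci_directions(n_points)
    a = np.asarray(spec.anode_dir, dtype=float)
    a /= np.linalg.norm(a)
    c = np.asarray(spec.cathode_dir, dtype=float)
    c /= np.linalg.norm(c)
    cosmax = math.cos(math.radians(exclusion_deg))
    keep = (dirs @ a < cosmax) & (dirs @ c < cosmax)
    pts = rs * dirs[keep]

    phi_o = oracle_potential(spec, pts)
    # oracle field by central differences (0.2 mm step), well clear of interfaces
    step = 0.2
    E_o = np.empty((len(pts), 3))
    for ax in range(3):
        dp = np.zeros(3)
        dp[ax] = step
        E_o[:, ax] = -(oracle_potential(spec, pts + dp, check_tail=False)
                       - oracle_potential(spec, pts - dp, check_tail=False)) / (2 * step * 1e-3)
    mag_o = np.linalg.norm(E_o, axis=1)

    # FEM potential sampled at grid nodes (trilinear on the node lattice)
    node_origin = model.origin_mm
    coords = (pts - node_origin) / model.h_mm
    from scipy.ndimage import map_coordinates

    phi_f = map_coordinates(phi_fem.phi, coords.T, order=1, mode="nearest")
    ef = efield if efield is not None else compute_efield(phi_fem, model)
    mag_f = np.linalg.norm(_trilinear_vector(ef.E, pts, model), axis=1)

    phi_o = phi_o - phi_o.mean()
    phi_f = phi_f - phi_f.mean()

    def rel_l2(x, y):
        return float(np.linalg.norm(x - y) / np.linalg.norm(y))

    def rel_max(x, y):
        return float(np.max(np.abs(x - y)) / np.max(np.abs(y)))

    return {
        "n_points": int(len(pts)),
        "shell_radius_mm": float(rs),
        "phi_rel_l2": rel_l2(phi_f, phi_o),
        "phi_rel_max": rel_max(phi_f, phi_o),
        "emag_rel_l2": rel_l2(mag_f, mag_o),
        "emag_rel_max": rel_max(mag_f, mag_o),
    }
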