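"""Cortical-surface field sampling and M1/SMA region-of-interest means.

The field magnitude is sampled on the spherical surface 1 mm below the
gray-matter outer boundary on a deterministic Fibonacci lattice, which gives
every phantom of a population the same angular parametrization — the
surrogate for surface registration of real cortices to a common template.
ROI centers given in template coordinates (mm; x right, y anterior,
z superior, origin at the anterior commissure) are mapped into phantom
space by a declared isotropic affine and projected onto the sampling
surface; ROI membership is geodesic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import Tissue, VoxelModel

#: Declared template->phantom mapping: template-space offset of the brain
#: center and the template cortical extent that is scaled onto the phantom's
#: gray-matter sphere.
TEMPLATE_CENTER_MM = np.array([0.0, -17.0, 9.0])
TEMPLATE_CORTICAL_EXTENT_MM = 90.0


def mirrored_fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors that are exactly mirror-symmetric about the
    midsagittal (x = 0) plane: a golden-angle lattice wound around the x axis
    is built on the x > 0 hemisphere and reflected.  Exact symmetry makes
    left/right ROI point sets mirror images, so bilateral means of a
    symmetric field agree to solver precision rather than to quadrature
    noise.  ``n`` is rounded up to even; no point lies on the plane itself.
    """
    half = (int(n) + 1) // 2
    i = np.arange(half) + 0.5
    x = 1.0 - i / half  # x in (0, 1): the positive hemisphere
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    s = np.sqrt(1.0 - x**2)
    plus = np.column_stack([x, s * np.cos(theta), s * np.sin(theta)])
    minus = plus * np.array([-1.0, 1.0, 1.0])
    return np.concatenate([plus, minus])


@dataclass
class CorticalSurfaceSamples:
    """|E| sample support on the surface ``depth_mm`` below the gray-matter
    boundary; ``directions`` is the shared angular parametrization."""

    points_mm: np.ndarray  # (n, 3) world coordinates
    directions: np.ndarray  # (n, 3) unit vectors, identical across a population
    radius_mm: float
    depth_mm: float
    model_id: str


@dataclass(frozen=True)
class RoiSpec:
    """Geodesic disc ROI on the sampling surface, centered at a template-space
    coordinate."""

    name: str
    center_template_mm: tuple
    radius_mm: float = 10.0


def default_rois() -> list:
    """Bilateral M1 ([±9, -39, 54]) and SMA ([±3, -9, 60]) discs, 1 cm radius."""
    return [
        RoiSpec("M1_left", (-9.0, -39.0, 54.0)),
        RoiSpec("M1_right", (9.0, -39.0, 54.0)),
        RoiSpec("SMA_left", (-3.0, -9.0, 60.0)),
        RoiSpec("SMA_right", (3.0, -9.0, 60.0)),
    ]


def cortical_samples(model: VoxelModel, d_mm: float = 1.0, n_points: int = 10000) -> CorticalSurfaceSamples:
    """Quasi-uniform sample points on the sphere of radius r_GM - d
    (mirror-symmetric golden-angle lattice, see
    :func:`mirrored_fibonacci_directions`).

    Deterministic for fixed ``n_points``; raises if the gray-matter shell is
    thinner than the sampling depth.
    """
    spec = model.spec
    r_gm = spec.layer_radius(Tissue.GRAY_MATTER)
    idx = [Tissue(t) for t in spec.labels].index(Tissue.GRAY_MATTER)
    gm_thickness = spec.thicknesses_mm()[idx]
    if gm_thickness <= d_mm:
        raise ValueError(
            f"gray-matter shell ({gm_thickness:.2f} mm) is thinner than sampling depth {d_mm} mm"
        )
    dirs = mirrored_fibonacci_directions(n_points)
    radius = r_gm - d_mm
    pts = model.center_mm + radius * dirs
    return CorticalSurfaceSamples(pts, dirs, radius, d_mm, model.model_id)


def _trilinear_vector(E: np.ndarray, points_mm: np.ndarray, model: VoxelModel) -> np.ndarray:
    """Trilinear interpolation of an element-center vector field at world
    points (component-wise; callers take the norm afterwards)."""
    pts = np.atleast_2d(points_mm)
    coords = (pts - model.origin_mm) / model.h_mm - 0.5  # element-center lattice
    if np.any(coords < -0.5) or np.any(coords > np.asarray(E.shape[:3]) - 0.5):
        raise ValueError("interpolation point outside the solved grid")
    out = np.empty((len(pts), 3))
    for c in range(3):
        out[:, c] = map_coordinates(E[..., c], coords.T, order=1, mode="nearest")
    return out


def interpolate_ef_magnitude(efield, points_mm: np.ndarray) -> np.ndarray:
    """|E| at world points: trilinear interpolation of the three components
    from element centers, then the Euclidean norm (component-then-norm
    convention)."""
    vec = _trilinear_vector(efield.E, points_mm, efield.model)
    return np.linalg.norm(vec, axis=1)


def map_roi_to_model(
    roi: RoiSpec,
    model: VoxelModel,
    samples: CorticalSurfaceSamples,
    template_center_mm: np.ndarray | None = None,
    template_extent_mm: float | None = None,
) -> np.ndarray:
    """Indices of the cortical sample points within the ROI.

    The template coordinate is re-centered, isotropically scaled so the
    template cortical extent matches the phantom's gray-matter sphere, and
    projected radially onto the sampling surface; membership is geodesic
    distance <= roi.radius_mm on that surface.
    """
    c0 = TEMPLATE_CENTER_MM if template_center_mm is None else np.asarray(template_center_mm)
    ext = TEMPLATE_CORTICAL_EXTENT_MM if template_extent_mm is None else float(template_extent_mm)
    q = np.asarray(roi.center_template_mm, dtype=float) - c0
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("ROI center coincides with the template center")
    c_hat = q / nq
    cosd = np.clip(samples.directions @ c_hat, -1.0, 1.0)
    geodesic = samples.radius_mm * np.arccos(cosd)
    idx = np.nonzero(geodesic <= roi.radius_mm)[0]
    if len(idx) == 0:
        # degenerate radius: fall back to the single nearest point
        if roi.radius_mm <= 0:
            return np.array([int(np.argmin(geodesic))])
        raise ValueError(f"ROI {roi.name!r} is empty at radius {roi.radius_mm} mm")
    return idx


def roi_mean_ef(ef_values: np.ndarray, roi_idx: np.ndarray) -> float:
    """Arithmetic mean of |E| over the ROI sample points (V/m)."""
    if len(roi_idx) == 0:
        raise ValueError("empty ROI")
    return float(np.mean(np.asarray(ef_values)[roi_idx]))


def roi_means_for_model(efield, model: VoxelModel, rois, d_mm: float = 1.0, n_points: int = 10000) -> dict:
    """Convenience: sample the surface, interpolate |E| and average per ROI."""
    samples = cortical_samples(model, d_mm, n_points)
    mags = interpolate_ef_magnitude(efield, samples.points_mm)
    return {roi.name: roi_mean_ef(mags, map_roi_to_model(roi, model, samples)) for roi in rois}


def surface_vectors_csv(samples: CorticalSurfaceSamples, efield, path) -> None:
    """Export the field vectors at the surface samples as CSV
    (x, y, z, Ex, Ey, Ez) — a plain-text stand-in for streamline renderings."""
    import pandas as pd

    vec = _trilinear_vector(efield.E, samples.points_mm, efield.model)
    pd.DataFrame(
        {
            "x_mm": samples.points_mm[:, 0],
            "y_mm": samples.points_mm[:, 1],
            "z_mm": samples.points_mm[:, 2],
            "Ex_V_per_m": vec[:, 0],
            "Ey_V_per_m": vec[:, 1],
            "Ez_V_per_m": vec[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.6g")


def surface_ply(samples: CorticalSurfaceSamples, mags: np.ndarray, path) -> None:
    """Write the sample points with |E| as a scalar property to ASCII PLY
    (point cloud, no faces) for visualization."""
    pts = samples.points_mm
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float ef_magnitude\nend_header\n")
        for (x, y, z), m in zip(pts, mags):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {m:.6g}\n")


def surface_csv(samples: CorticalSurfaceSamples, mags: np.ndarray, path) -> None:
    """Export surface samples as CSV (x, y, z, |E|)."""
    import pandas as pd

    pd.DataFrame(
        {
            "x_mm": samples.points_mm[:, 0],
            "y_mm": samples.points_mm[:, 1],
            "z_mm": samples.points_mm[:, 2],
            "E_V_per_m": mags,
        }
    ).to_csv(path, index=False, float_format="%.6g")
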