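"""Synthetic layered-sphere head phantoms and tissue conductivities.

Real tDCS field modelling segments individual MRI into ten-odd tissue
compartments.  This module generates concentric-sphere surrogates for such
anatomies: a voxelized label volume per phantom, plus phantom *populations*
whose layer thicknesses and overall size are jittered with truncated-normal
multipliers to emulate inter-individual anatomical variability.  It also
owns the tissue conductivity table used by the solver.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np


class Tissue(IntEnum):
    """Voxel labels. AIR is outside the conducting domain."""

    AIR = 0
    SKIN_FAT = 1
    MUSCLE = 2
    COMPACT_BONE = 3
    SPONGY_BONE = 4
    DURA = 5
    BLOOD = 6
    CSF = 7
    GRAY_MATTER = 8
    WHITE_MATTER = 9
    EYE = 10
    SALINE_SPONGE = 11
    RUBBER_SHEET = 12


#: Literature conductivity assignments, S/m.  Skin and subcutaneous fat share
#: one label and one value.  The rubber electrode sheet has no published
#: value; with uniform volumetric current injection over the sheet its
#: conductivity has negligible effect on the tissue field (see docs).
DEFAULT_CONDUCTIVITIES: Mapping[Tissue, float] = MappingProxyType(
    {
        Tissue.SKIN_FAT: 0.08,
        Tissue.MUSCLE: 0.16,
        Tissue.COMPACT_BONE: 0.008,
        Tissue.SPONGY_BONE: 0.027,
        Tissue.DURA: 0.16,
        Tissue.BLOOD: 0.7,
        Tissue.CSF: 1.8,
        Tissue.GRAY_MATTER: 0.2,
        Tissue.WHITE_MATTER: 0.14,
        Tissue.EYE: 1.5,
        Tissue.SALINE_SPONGE: 1.6,
        Tissue.RUBBER_SHEET: 0.1,
    }
)


class TissueConductivityTable:
    """Mapping tissue label -> conductivity sigma (S/m).

    Defaults are immutable; :meth:`with_overrides` and :meth:`scaled`
    return modified copies.
    """

    def __init__(self, values: Mapping[Tissue, float] | None = None):
        vals = dict(DEFAULT_CONDUCTIVITIES if values is None else values)
        for tissue, sigma in vals.items():
            if sigma <= 0:
                raise ValueError(f"conductivity of {Tissue(tissue).name} must be > 0, got {sigma}")
        self._values = MappingProxyType(vals)

    def __getitem__(self, tissue: Tissue | str) -> float:
        if isinstance(tissue, str):
            tissue = Tissue[tissue.upper()]
        return self._values[Tissue(tissue)]

    def __contains__(self, tissue) -> bool:
        try:
            self[tissue]
            return True
        except KeyError:
            return False

    def items(self):
        return self._values.items()

    def with_overrides(self, overrides: Mapping[Tissue | str, float]) -> "TissueConductivityTable":
        vals = dict(self._values)
        for key, sigma in overrides.items():
            tissue = Tissue[key.upper()] if isinstance(key, str) else Tissue(key)
            vals[tissue] = float(sigma)
        return TissueConductivityTable(vals)

    def scaled(self, factors: Mapping[Tissue | str, float] | float) -> "TissueConductivityTable":
        """Multiply conductivities by per-tissue factors (or one global factor)."""
        if isinstance(factors, (int, float)):
            return TissueConductivityTable({t: s * factors for t, s in self._values.items()})
        vals = dict(self._values)
        for key, f in factors.items():
            tissue = Tissue[key.upper()] if isinstance(key, str) else Tissue(key)
            if f <= 0:
                raise ValueError(f"conductivity multiplier for {tissue.name} must be > 0")
            vals[tissue] = vals[tissue] * float(f)
        return TissueConductivityTable(vals)

    def as_array(self, n_labels: int | None = None) -> np.ndarray:
        """Dense lookup array sigma[label]; air (and unused labels) map to 0."""
        n = max(int(t) for t in self._values) + 1
        if n_labels is not None:
            n = max(n, int(n_labels))
        arr = np.zeros(n)
        for t, s in self._values.items():
            arr[int(t)] = s
        return arr

    def signature(self) -> tuple:
        """Hashable identity used for solution caching."""
        return tuple(sorted((int(t), float(s)) for t, s in self._values.items()))


def conductivity_table() -> TissueConductivityTable:
    """The default tissue conductivity table (S/m)."""
    return TissueConductivityTable()


@dataclass(frozen=True)
class SphereLayerSpec:
    """Concentric-shell head phantom specification.

    ``outer_radii_mm`` are strictly decreasing toward the core; ``labels``
    give one tissue per shell, outermost first.  The innermost entry is the
    core sphere.  The nasion-inion midline scalp arc of a sphere is half its
    circumference.
    """

    outer_radii_mm: tuple
    labels: tuple
    center_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        radii = np.asarray(self.outer_radii_mm, dtype=float)
        if len(radii) != len(self.labels):
            raise ValueError("one tissue label required per shell")
        if len(radii) == 0 or np.any(np.diff(radii) >= 0) or radii[-1] <= 0:
            raise ValueError("outer radii must be strictly decreasing and positive")

    @property
    def outer_radius_mm(self) -> float:
        return float(self.outer_radii_mm[0])

    @property
    def midline_arc_mm(self) -> float:
        """Nasion-inion scalp arc length (half great circle)."""
        return math.pi * self.outer_radius_mm

    def thicknesses_mm(self) -> np.ndarray:
        """Shell thicknesses, outermost first; last entry is the core radius."""
        radii = np.asarray(self.outer_radii_mm, dtype=float)
        return np.append(-np.diff(radii), radii[-1])

    def shell_volumes_mm3(self) -> np.ndarray:
        """Analytic shell volumes, outermost first."""
        radii = np.asarray(self.outer_radii_mm, dtype=float)
        vols = 4.0 / 3.0 * np.pi * radii**3
        return np.append(-np.diff(vols), vols[-1])

    def layer_radius(self, tissue: Tissue) -> float:
        """Outer radius of the shell labelled ``tissue``."""
        for r, lab in zip(self.outer_radii_mm, self.labels):
            if Tissue(lab) == tissue:
                return float(r)
        raise KeyError(f"no shell labelled {Tissue(tissue).name}")


def default_head_spec(outer_radius_mm: float = 92.0, spongy_bone: bool = False) -> SphereLayerSpec:
    """Six-shell head phantom: skin/fat 6, compact bone 4 (optionally with a
    2 mm spongy mid-layer), dura 1.5, CSF 3, gray matter 4 mm; white-matter core.
    """
    R = float(outer_radius_mm)
    if spongy_bone:
        radii = (R, R - 6.0, R - 7.0, R - 9.0, R - 10.0, R - 11.5, R - 14.5, R - 18.5)
        labels = (
            Tissue.SKIN_FAT,
            Tissue.COMPACT_BONE,
            Tissue.SPONGY_BONE,
            Tissue.COMPACT_BONE,
            Tissue.DURA,
            Tissue.CSF,
            Tissue.GRAY_MATTER,
            Tissue.WHITE_MATTER,
        )
    else:
        radii = (R, R - 6.0, R - 10.0, R - 11.5, R - 14.5, R - 18.5)
        labels = (
            Tissue.SKIN_FAT,
            Tissue.COMPACT_BONE,
            Tissue.DURA,
            Tissue.CSF,
            Tissue.GRAY_MATTER,
            Tissue.WHITE_MATTER,
        )
    spec = SphereLayerSpec(radii, labels)
    if Tissue(spec.labels[-1]) != Tissue.WHITE_MATTER or Tissue(spec.labels[0]) != Tissue.SKIN_FAT:
        raise ValueError("default head spec must run skin_fat -> white_matter")
    return spec


@dataclass
class VoxelModel:
    """Voxelized tissue-label volume — the FEM domain.

    ``labels`` is an int16 array indexed [i, j, k] along world x (right),
    y (anterior), z (superior).  ``origin_mm`` is the world coordinate of the
    corner of voxel (0, 0, 0); voxel centers sit at origin + (index + 1/2) h.
    ``provenance`` records phantom id, generation seed and the generating
    sphere spec so that downstream geometry (scalp arc, cortical radius) is
    available without re-deriving it from the voxels.

    ``mixed`` optionally carries partial-volume information for voxels
    straddling a tissue interface, as a tuple ``(indices, tissues, fractions)``
    with ``indices`` of shape (n, 3), ``tissues`` the tissue labels of the
    fraction columns and ``fractions`` of shape (n, len(tissues)) summing to 1
    (an air column may be included).  When present, the solver uses the
    volume-weighted element conductivity for these voxels instead of the
    label conductivity.
    """

    labels: np.ndarray
    h_mm: float
    origin_mm: np.ndarray
    provenance: dict = field(default_factory=dict)
    mixed: tuple | None = None

    def __post_init__(self):
        if self.h_mm <= 0:
            raise ValueError("voxel edge length must be > 0")
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def model_id(self) -> str:
        return self.provenance.get("phantom_id", "model")

    @property
    def spec(self) -> SphereLayerSpec:
        return self.provenance["spec"]

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.provenance.get("center_mm", (0.0, 0.0, 0.0)), dtype=float)

    @property
    def outer_radius_mm(self) -> float:
        return self.spec.outer_radius_mm

    def voxel_centers_1d(self):
        """Per-axis voxel-center world coordinates (cx, cy, cz)."""
        return tuple(
            self.origin_mm[a] + (np.arange(self.labels.shape[a]) + 0.5) * self.h_mm
            for a in range(3)
        )

    def label_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Tissue label at world points (nearest voxel)."""
        pts = np.atleast_2d(points_mm)
        idx = np.floor((pts - self.origin_mm) / self.h_mm).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.labels.shape) - 1)
        return self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]

    def fingerprint(self) -> str:
        """Content hash of the voxel grid (labels, spacing, origin), used to
        key solution caches; distinct phantoms never share a fingerprint even
        if their ids coincide across populations."""
        import hashlib

        md = hashlib.sha1()
        md.update(self.labels.tobytes())
        md.update(np.asarray([self.h_mm], dtype=float).tobytes())
        md.update(self.origin_mm.astype(float).tobytes())
        if self.mixed is not None:
            idx, tissues, fracs = self.mixed
            md.update(idx.tobytes())
            md.update(np.asarray(tissues).tobytes())
            md.update(fracs.tobytes())
        return md.hexdigest()

    def copy(self) -> "VoxelModel":
        mixed = None
        if self.mixed is not None:
            idx, tissues, fracs = self.mixed
            mixed = (idx.copy(), tissues, fracs.copy())
        return VoxelModel(
            self.labels.copy(), self.h_mm, self.origin_mm.copy(), dict(self.provenance), mixed
        )

    def drop_mixed_at(self, mask: np.ndarray) -> None:
        """Remove partial-volume entries where ``mask`` is True (used when
        voxels are relabelled, e.g. by electrode placement)."""
        if self.mixed is None:
            return
        idx, tissues, fracs = self.mixed
        keep = ~mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        self.mixed = (idx[keep], tissues, fracs[keep]) if keep.any() else None

    def to_nifti(self, path) -> None:
        """Write the label volume as int16 NIfTI; affine carries h and origin."""
        import nibabel as nib

        affine = np.diag([self.h_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm + 0.5 * self.h_mm  # voxel-center convention
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


def load_nifti_labels(path, provenance: dict | None = None) -> VoxelModel:
    """Read an externally supplied int label volume (isotropic voxels)."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    steps = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(steps, steps[0], rtol=1e-4):
        raise ValueError("label volume must have isotropic voxels")
    h = float(steps[0])
    origin = affine[:3, 3] - 0.5 * h
    labels = np.asarray(img.dataobj).astype(np.int16)
    return VoxelModel(labels, h, origin, provenance or {"phantom_id": str(path)})


def build_sphere_phantom(
    spec: SphereLayerSpec,
    h_mm: float,
    pad_mm: float = 16.0,
    phantom_id: str = "phantom",
    seed: int | None = None,
    strict: bool = False,
    partial_volume: int = 4,
) -> VoxelModel:
    """Voxelize a layered sphere: each voxel takes the label of the shell
    containing its center; air outside the outermost radius.

    The grid is symmetric about the sphere center (the center falls on a grid
    node), so a mirror-symmetric spec voxelizes to a mirror-symmetric label
    array.  ``pad_mm`` of air is left around the head for electrode assemblies.

    A layer thinner than 2h cannot be resolved as a contiguous shell; by
    default this is logged as a warning (the voxelization still captures the
    layer's average radial extent, which is adequate for coarse exploratory
    grids), with ``strict=True`` it raises.  A layer that vanishes from the
    voxelization entirely always raises.

    ``partial_volume`` > 1 additionally records per-voxel tissue volume
    fractions for interface-straddling voxels, estimated from a
    ``partial_volume``^3 subsampling of the continuous geometry; the solver
    then uses volume-weighted element conductivities there, which markedly
    reduces the staircase error of thin shells on coarse grids.  Pass 0 to
    disable (plain label-per-voxel conductivities).
    """
    h = float(h_mm)
    thick = spec.thicknesses_mm()
    thin = int(np.argmin(thick))
    if thick[thin] < 2.0 * h:
        name = Tissue(spec.labels[thin]).name
        msg = (
            f"layer {name!r} ({thick[thin]:.2f} mm) is thinner than 2h = {2 * h:.2f} mm; "
            "reduce h or thicken the layer"
        )
        if strict:
            raise ValueError(msg)
        logging.getLogger(__name__).warning(msg)
    R = spec.outer_radius_mm
    center = np.asarray(spec.center_mm, dtype=float)
    half = math.ceil((R + pad_mm) / h) * h
    n = int(round(2 * half / h))
    origin = center - half
    coords = origin[0] + (np.arange(n) + 0.5) * h - center[0]  # symmetric by construction
    cx = coords
    cy = origin[1] + (np.arange(n) + 0.5) * h - center[1]
    cz = origin[2] + (np.arange(n) + 0.5) * h - center[2]
    r2 = cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
    r = np.sqrt(r2)

    inc_radii = np.asarray(spec.outer_radii_mm, dtype=float)[::-1]
    inc_labels = np.asarray([int(t) for t in spec.labels[::-1]] + [int(Tissue.AIR)], dtype=np.int16)
    shell_idx = np.searchsorted(inc_radii, r, side="left")
    labels = inc_labels[shell_idx]

    present = np.unique(shell_idx)
    for k in range(len(inc_radii)):
        if k not in present:
            name = Tissue(spec.labels[::-1][k]).name
            raise ValueError(f"layer {name!r} vanished from the voxelization at h = {h} mm")

    mixed = None
    if partial_volume and partial_volume > 1:
        mixed = _interface_fractions(spec, r, inc_radii, inc_labels, h, int(partial_volume))

    return VoxelModel(
        labels,
        h,
        origin,
        provenance={
            "phantom_id": phantom_id,
            "seed": seed,
            "spec": spec,
            "center_mm": tuple(center),
            "anterior_axis": "+y",
        },
        mixed=mixed,
    )


def _interface_fractions(spec, r, inc_radii, inc_labels, h, sub):
    """Tissue volume fractions, from a sub^3 lattice of sample points per
    voxel, for voxels whose center lies within half a voxel diagonal of any
    shell interface (all other voxels are single-tissue)."""
    half_diag = 0.5 * math.sqrt(3.0) * h
    near = np.zeros(r.shape, dtype=bool)
    for rad in inc_radii:
        near |= np.abs(r - rad) <= half_diag
    idx = np.argwhere(near)
    if len(idx) == 0:
        return None
    # sample offsets relative to the voxel center, symmetric about 0
    offs = ((np.arange(sub) + 0.5) / sub - 0.5) * h
    # voxel-center coordinates relative to the sphere center: recover from r is
    # not possible per-axis, so rebuild from indices (grid is cubic, symmetric)
    n = r.shape[0]
    rel = (np.arange(n) + 0.5) * h - n * h / 2.0
    cxs, cys, czs = rel[idx[:, 0]], rel[idx[:, 1]], rel[idx[:, 2]]
    tissues = tuple(sorted({int(t) for t in inc_labels}))
    col = {t: k for k, t in enumerate(tissues)}
    counts = np.zeros((len(idx), len(tissues)), dtype=np.int32)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                rr = np.sqrt((cxs + ox) ** 2 + (cys + oy) ** 2 + (czs + oz) ** 2)
                lab = inc_labels[np.searchsorted(inc_radii, rr, side="left")]
                for t in tissues:
                    counts[:, col[t]] += lab == t
    fracs = (counts / float(sub**3)).astype(np.float32)
    return idx.astype(np.int32), tissues, fracs


def add_extended_compartments(model: VoxelModel) -> VoxelModel:
    """Optional anatomical extras: split the inner half of the scalp shell into
    muscle over the lower head, and insert two eye spheres anteriorly.

    These compartments barely affect midline-montage ranking; they exist so the
    full conductivity table is exercisable.
    """
    spec = model.spec
    out = model.copy()
    cx, cy, cz = out.voxel_centers_1d()
    center = out.center_mm
    X = cx[:, None, None] - center[0]
    Y = cy[None, :, None] - center[1]
    Z = cz[None, None, :] - center[2]
    r = np.sqrt(X**2 + Y**2 + Z**2)

    skin_outer = spec.layer_radius(Tissue.SKIN_FAT)
    skin_inner = skin_outer - spec.thicknesses_mm()[0]
    mid = 0.5 * (skin_outer + skin_inner)
    muscle = (out.labels == Tissue.SKIN_FAT) & (r <= mid) & (Z < 0)
    out.labels[muscle] = Tissue.MUSCLE

    eye_r = 10.0
    dist = skin_outer - 10.0
    for sx in (-1.0, 1.0):
        c = center + dist * np.array([sx * math.sin(math.radians(18)), math.cos(math.radians(18)), 0.0])
        d2 = (cx[:, None, None] - c[0]) ** 2 + (cy[None, :, None] - c[1]) ** 2 + (cz[None, None, :] - c[2]) ** 2
        out.labels[(d2 <= eye_r**2) & (out.labels != Tissue.AIR)] = Tissue.EYE
    out.provenance["extended"] = True
    return out


@dataclass(frozen=True)
class PopulationSpec:
    """Population of jittered phantoms standing in for a cohort of MRI-derived
    anatomies (cohort size 62 in the motivating application).

    ``thickness_cv`` is the coefficient of variation applied multiplicatively
    to each shell thickness and the core radius; ``size_cv`` scales the whole
    head.  Truncated-normal draws are resampled until every layer remains
    thick enough to voxelize.
    """

    base: SphereLayerSpec
    n: int = 62
    thickness_cv: float = 0.08
    size_cv: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.thickness_cv < 0 or self.size_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


def sample_population(pop: PopulationSpec, h_mm: float, max_resample: int = 100) -> list:
    """Draw ``pop.n`` phantoms; deterministic for a fixed seed.

    Each model's shell thicknesses t_k are multiplied by independent
    truncated-normal factors ~ N(1, thickness_cv) and the whole head by a
    N(1, size_cv) factor; a draw is rejected and redrawn if any layer would
    end up thinner than 2h (unvoxelizable).
    """
    rng = np.random.default_rng(pop.seed)
    base_thick = pop.base.thicknesses_mm()
    # a draw may not thin any layer below half a voxel (it would vanish from
    # the grid) unless the base spec itself is already that thin
    floor = np.minimum(0.5 * h_mm, base_thick)
    models = []
    for m in range(pop.n):
        ok = False
        for _ in range(max_resample):
            tf = rng.normal(1.0, pop.thickness_cv, size=base_thick.shape) if pop.thickness_cv > 0 else np.ones_like(base_thick)
            gf = rng.normal(1.0, pop.size_cv) if pop.size_cv > 0 else 1.0
            if np.any(tf <= 0.0) or gf <= 0.0:  # truncate at zero, redraw
                continue
            thick = base_thick * tf * gf
            if np.all(thick >= floor):
                ok = True
                break
        if not ok:
            thin = Tissue(pop.base.labels[int(np.argmin(base_thick))]).name
            raise RuntimeError(
                f"model {m}: layer {thin!r} vanished under perturbation after {max_resample} resampling attempts"
            )
        radii_inc = np.cumsum(thick[::-1])
        spec_m = replace(pop.base, outer_radii_mm=tuple(radii_inc[::-1]))
        models.append(
            build_sphere_phantom(
                spec_m, h_mm, phantom_id=f"phantom-{m:03d}", seed=pop.seed
            )
        )
    return models
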