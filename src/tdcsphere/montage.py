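"""10-10 midline scalp sites, sponge-electrode assemblies and montage
enumeration with the footprint-overlap exclusion rule.

Midline 10-10 sites sit at fixed fractions of the nasion-inion scalp arc
(Fpz 10% ... Iz 100%, adjacent named sites 10% apart).  Candidate montages
pair a central first electrode (Fz..Pz) with a frontal, posterior, nearby or
extracephalic return; pairs whose 5 cm sponge footprints would overlap on
the scalp are excluded, which leaves 23 montages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .phantom import Tissue, VoxelModel

log = logging.getLogger(__name__)

#: Arc fraction of the nasion-inion midline arc for each named midline site.
MIDLINE_ARC_FRACTIONS = {
    "Fpz": 0.10,
    "Fz": 0.30,
    "FCz": 0.40,
    "Cz": 0.50,
    "CPz": 0.60,
    "Pz": 0.70,
    "POz": 0.80,
    "Oz": 0.90,
    "Iz": 1.00,
}

EXTRACEPHALIC = "Extracephalic"

#: First/second electrode site sets generating the candidate montages, and the
#: presentation order of the resulting table (second-electrode major).
FIRST_SITES = ("Fz", "FCz", "Cz", "CPz", "Pz")
SECOND_SITES = (EXTRACEPHALIC, "Iz", "Fpz", "POz", "Pz")


@dataclass(frozen=True)
class ScalpSite:
    """A named stimulation site on the outer scalp surface."""

    name: str
    arc_fraction: float | None  # None for the extracephalic patch
    direction: tuple  # unit vector from head center
    position_mm: tuple  # on the scalp surface
    normal: tuple  # outward normal (= direction on a sphere)

    @property
    def is_extracephalic(self) -> bool:
        return self.arc_fraction is None


@dataclass(frozen=True)
class ElectrodeSpec:
    """35 cm^2 sponge electrode (7 cm x 5 cm) with an embedded rubber sheet.

    The long (7 cm) edge is oriented perpendicular to the posterior-anterior
    direction, so the footprint extends 5 cm along the midline arc.  The
    rubber current-feeding sheet sits at mid-sponge depth; nominal sheet
    thickness is 1 mm but it occupies at least one voxel layer.
    """

    length_mm: float = 70.0  # long edge, left-right
    width_mm: float = 50.0  # along the midline arc
    sponge_below_mm: float = 5.0
    sponge_above_mm: float = 5.0
    rubber_thickness_mm: float = 1.0

    @property
    def footprint_area_cm2(self) -> float:
        return self.length_mm * self.width_mm / 100.0

    def total_thickness_mm(self, h_mm: float) -> float:
        return self.sponge_below_mm + max(self.rubber_thickness_mm, h_mm) + self.sponge_above_mm


@dataclass(frozen=True)
class MontageSpec:
    """Ordered (anode, cathode) site pair with injected current.

    Order encodes polarity: FCz-POz drives anterior-to-posterior current,
    POz-FCz the reverse.
    """

    anode: str
    cathode: str
    current_mA: float = 2.0

    def __post_init__(self):
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")
        if self.current_mA < 0:
            raise ValueError("injected current must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.anode}-{self.cathode}"

    def swapped(self) -> "MontageSpec":
        return MontageSpec(self.cathode, self.anode, self.current_mA)


def _site_direction(name: str) -> np.ndarray:
    """Unit direction of a site: nasion at +y (anterior), arc over the vertex
    (+z) to the inion at -y; the extracephalic patch is antipodal to Cz."""
    if name == EXTRACEPHALIC:
        return np.array([0.0, 0.0, -1.0])
    frac = MIDLINE_ARC_FRACTIONS[name]
    psi = frac * math.pi
    return np.array([0.0, math.cos(psi), math.sin(psi)])


def midline_sites(model: VoxelModel) -> list:
    """All named midline sites plus the extracephalic patch on ``model``.

    Sites are placed at their arc fractions along the anterior-posterior
    great-circle scalp arc; coordinates lie on the continuous scalp sphere of
    the generating spec.
    """
    if "spec" not in model.provenance:
        raise ValueError("model lacks a generating sphere spec (no scalp surface defined)")
    if not np.any(model.labels == Tissue.SKIN_FAT) or not np.any(model.labels == Tissue.AIR):
        raise ValueError("model has no scalp/air boundary")
    R = model.outer_radius_mm
    center = model.center_mm
    sites = []
    for name in list(MIDLINE_ARC_FRACTIONS) + [EXTRACEPHALIC]:
        d = _site_direction(name)
        frac = None if name == EXTRACEPHALIC else MIDLINE_ARC_FRACTIONS[name]
        sites.append(
            ScalpSite(name, frac, tuple(d), tuple(center + R * d), tuple(d))
        )
    return sites


def arc_distance_mm(a: str, b: str, arc_length_mm: float) -> float:
    """Great-circle scalp distance between two named sites.

    For two midline sites this is the arc-fraction difference times the
    nasion-inion arc; the extracephalic patch is antipodal to Cz, i.e. a full
    arc length away from the vertex.
    """
    da, db = _site_direction(a), _site_direction(b)
    angle = math.acos(float(np.clip(np.dot(da, db), -1.0, 1.0)))
    # midline arc = pi radians of great circle
    return angle / math.pi * arc_length_mm


def electrodes_overlap(
    a: str | ScalpSite,
    b: str | ScalpSite,
    e: ElectrodeSpec | None = None,
    arc_length_mm: float = math.pi * 92.0,
) -> bool:
    """True iff the two electrodes' midline footprints intersect on the scalp:
    center-to-center arc distance < the footprint extent along the arc
    (5 cm by default).  The extracephalic patch never overlaps a cephalic site.
    """
    e = e or ElectrodeSpec()
    na = a.name if isinstance(a, ScalpSite) else a
    nb = b.name if isinstance(b, ScalpSite) else b
    if EXTRACEPHALIC in (na, nb):
        return False
    return arc_distance_mm(na, nb, arc_length_mm) < e.width_mm


def enumerate_candidates(
    e: ElectrodeSpec | None = None,
    current_mA: float = 2.0,
    arc_length_mm: float = math.pi * 92.0,
) -> list:
    """Candidate montage set: {Fz, FCz, Cz, CPz, Pz} crossed with
    {extracephalic, Iz, Fpz, POz, Pz} plus POz-Fpz; same-site and overlapping
    pairs removed, unordered pairs deduplicated.  Returns 23 montages for the
    default electrode on any plausible head (midline arc 25-50 cm).
    """
    e = e or ElectrodeSpec()
    montages = []
    seen = set()
    for second in SECOND_SITES:
        firsts = FIRST_SITES + (("POz",) if second == "Fpz" else ())
        for first in firsts:
            if first == second:
                continue
            if electrodes_overlap(first, second, e, arc_length_mm):
                continue
            key = frozenset((first, second))
            if key in seen:
                continue
            seen.add(key)
            montages.append(MontageSpec(first, second, current_mA))
    return montages


@dataclass
class ElectrodePlacement:
    """Result of placing one montage on a model: the augmented label volume and
    the rubber-sheet voxel index sets feeding the current source."""

    model: VoxelModel
    anode_voxels: np.ndarray  # (n, 3) int indices into model.labels
    cathode_voxels: np.ndarray
    montage: MontageSpec
    electrode: ElectrodeSpec


def _electrode_masks(model: VoxelModel, site: ScalpSite, e: ElectrodeSpec):
    """Sponge and rubber voxel masks for one electrode conforming to the scalp
    sphere: radial extent (R, R + thickness], tangential footprint bounded by
    scalp-arc coordinates |u| <= width/2 (midline), |v| <= length/2 (lateral).
    """
    R = model.outer_radius_mm
    center = model.center_mm
    h = model.h_mm
    n_hat = np.asarray(site.direction, dtype=float)
    # local tangent frame: u along the midline arc, v lateral (left-right)
    t_v = np.array([1.0, 0.0, 0.0])
    t_u = np.cross(t_v, n_hat)  # tangent within the midsagittal plane
    t_u /= np.linalg.norm(t_u)

    cx, cy, cz = model.voxel_centers_1d()
    X = cx[:, None, None] - center[0]
    Y = cy[None, :, None] - center[1]
    Z = cz[None, None, :] - center[2]
    r = np.sqrt(X**2 + Y**2 + Z**2)
    thickness = e.total_thickness_mm(h)
    radial = (r > R) & (r <= R + thickness)
    if not np.any(radial):
        return np.zeros_like(radial), np.zeros_like(radial)

    pn = X * n_hat[0] + Y * n_hat[1] + Z * n_hat[2]
    pu = X * t_u[0] + Y * t_u[1] + Z * t_u[2]
    pv = X * t_v[0] + Y * t_v[1] + Z * t_v[2]
    # scalp-arc coordinates of the voxel direction relative to the site center
    u = R * np.arctan2(pu, pn)
    v = R * np.arctan2(pv, pn)
    footprint = (np.abs(u) <= e.width_mm / 2) & (np.abs(v) <= e.length_mm / 2) & (pn > 0)
    assembly = radial & footprint
    rubber_lo = R + e.sponge_below_mm
    rubber_hi = rubber_lo + max(e.rubber_thickness_mm, h)
    rubber = assembly & (r > rubber_lo) & (r <= rubber_hi)
    return assembly, rubber


def place_electrodes(
    model: VoxelModel, m: MontageSpec, e: ElectrodeSpec | None = None
) -> ElectrodePlacement:
    """Add the two sponge/rubber electrode assemblies of montage ``m`` to a
    copy of ``model`` and record the rubber voxel sets for source construction.

    Raises if the two assemblies intersect (overlapping footprints); warns if a
    footprint hangs over an air gap for more than 20% of its area.
    """
    e = e or ElectrodeSpec()
    sites = {s.name: s for s in midline_sites(model)}
    for name in (m.anode, m.cathode):
        if name not in sites:
            raise KeyError(f"unknown scalp site {name!r}")
    if electrodes_overlap(m.anode, m.cathode, e, model.spec.midline_arc_mm):
        raise ValueError(
            f"electrodes at {m.anode} and {m.cathode} overlap "
            f"(arc distance < {e.width_mm:.0f} mm footprint)"
        )
    out = model.copy()
    masks = {}
    for name in (m.anode, m.cathode):
        assembly, rubber = _electrode_masks(model, sites[name], e)
        if not np.any(rubber):
            raise ValueError(f"electrode at {name} produced no rubber voxels (grid too coarse?)")
        masks[name] = (assembly, rubber)
    if np.any(masks[m.anode][0] & masks[m.cathode][0]):
        raise ValueError(f"electrode assemblies of {m.name} overlap after placement")

    for name in (m.anode, m.cathode):
        assembly, rubber = masks[name]
        if np.any(out.labels[assembly] != Tissue.AIR):
            raise ValueError(f"electrode at {name} intersects head tissue")
        out.labels[assembly] = Tissue.SALINE_SPONGE
        out.labels[rubber] = Tissue.RUBBER_SHEET
        out.drop_mixed_at(assembly)  # relabelled voxels are pure electrode material
        # support check: fraction of sponge columns with scalp directly beneath
        support = _support_fraction(model, assembly)
        if support < 0.8:
            log.warning(
                "electrode at %s hangs over an air gap for %.0f%% of its footprint",
                name,
                100 * (1 - support),
            )
    anode_idx = np.argwhere(masks[m.anode][1])
    cathode_idx = np.argwhere(masks[m.cathode][1])
    out.provenance["montage"] = m.name
    return ElectrodePlacement(out, anode_idx, cathode_idx, m, e)


def sites_csv(model: VoxelModel, path) -> None:
    """Export the model's scalp sites as CSV (site, x, y, z, arc_fraction)."""
    import pandas as pd

    rows = [
        {
            "site": s.name,
            "x_mm": s.position_mm[0],
            "y_mm": s.position_mm[1],
            "z_mm": s.position_mm[2],
            "arc_fraction": "" if s.arc_fraction is None else s.arc_fraction,
        }
        for s in midline_sites(model)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def _support_fraction(model: VoxelModel, assembly: np.ndarray) -> float:
    """Fraction of the assembly's voxels adjacent (6-connectivity) to head
    tissue or to other assembly voxels — 1.0 for a fully conforming electrode."""
    head_or_assembly = (model.labels != Tissue.AIR) | assembly
    padded = np.pad(head_or_assembly, 1)
    neigh = np.zeros_like(assembly, dtype=bool)
    for axis in range(3):
        for shift in (-1, 1):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(1 + shift, padded.shape[axis] - 1 + shift)
            neigh |= padded[tuple(sl)]
    touching = assembly & neigh
    return float(touching.sum()) / float(assembly.sum())
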