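"""Pocket detection on a 0.5 Å grid, and pocket-void / pocket-lining features.

The cavity around a metal site is detected with a LIGSITE-style burial scan:
grid cells within (van der Waals radius + probe) of a protein heavy atom are
*occupied*; an unoccupied cell is a *candidate* pocket cell when at least
``burial_min`` of seven scan axes (x, y, z and the four cube diagonals) are
blocked by protein in both directions within the scan range.  The pocket is
the 26-connected flood-fill component of candidate cells nearest the anchor
residue (the residue closest to the site center).  Cells of the pocket that
touch unburied space form the *opening*; the frame used for slice features
rotates the pocket so +z runs from the site center to the opening center.

The site's own metal atoms and waters do not occlude — otherwise the metal's
own exclusion sphere would hollow out the pocket center.

All thresholds live in :class:`PocketConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import skew as _skew

from .sites import MetalSite
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

# Bondi van der Waals radii (Å) by element; 1.7 fallback
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
             "SE": 1.90}
DEFAULT_VDW = 1.70

#: Kyte–Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

#: Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}

HYDROPHOBICITY_SCALES = {"eisenberg": EISENBERG, "kd": KYTE_DOOLITTLE}


def _load_residue_volumes() -> dict[str, float]:
    with resources.files("metalsite.data").joinpath(
            "residue_volumes.json").open() as fh:
        table = json.load(fh)
    return {k: float(v) for k, v in table.items() if not k.startswith("_")}


RESIDUE_VDW_VOLUME = _load_residue_volumes()
_BACKBONE_VOLUME = RESIDUE_VDW_VOLUME["GLY"]


def sidechain_volume(res_name: str) -> float:
    total = RESIDUE_VDW_VOLUME.get(res_name)
    if total is None:
        return 0.0
    return max(total - _BACKBONE_VOLUME, 0.0)


@dataclass
class PocketConfig:
    spacing: float = 0.5          # grid interval, Å
    box_r: float = 16.0           # half-width of the grid box, Å
    probe: float = 1.4            # solvent probe radius, Å
    burial_min: int = 4           # scan axes blocked both ways required
    scan_range: float = 12.0      # how far each scan ray looks, Å
    lining_cutoff: float = 2.2    # atom–gridpoint adjacency, Å


# the seven scan axes: grid steps and physical step length multiplier
_SCAN_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


@dataclass
class PocketGrid:
    spacing: float
    site_center: np.ndarray
    protein_centroid: np.ndarray
    anchor_residue: Residue | None
    points: np.ndarray                 # (n, 3) world coords of pocket cells
    opening_points: np.ndarray         # (m, 3) subset on the solvent boundary
    opening_center: np.ndarray | None  # centroid of opening points
    rotation: np.ndarray               # 3x3, world -> frame (z: center→opening)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def volume(self) -> float:
        """Å³; each 0.5 Å cell contributes 0.125 Å³."""
        return self.spacing ** 3 * self.n_points

    def frame_coords(self) -> np.ndarray:
        """Pocket points in the rotated frame centered at the site center."""
        if self.n_points == 0:
            return np.empty((0, 3))
        return (self.points - self.site_center) @ self.rotation.T


def _shift(mask: np.ndarray, step: tuple[int, int, int]) -> np.ndarray:
    """mask looked-up one step ahead along ``step`` (zero padded)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(step):
        if d == 1:
            dst[ax], src[ax] = slice(0, -1), slice(1, None)
        elif d == -1:
            dst[ax], src[ax] = slice(1, None), slice(0, -1)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _blocked(occupied: np.ndarray, step: tuple[int, int, int],
             n_steps: int) -> np.ndarray:
    """Cells with an occupied cell within ``n_steps`` along ``step``."""
    out = np.zeros_like(occupied)
    rolling = occupied
    for _ in range(n_steps):
        rolling = _shift(rolling, step)
        out |= rolling
    return out


def _occupancy(shape: tuple[int, int, int], origin: np.ndarray, spacing: float,
               atoms: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean grid of cells within (vdW + probe already folded into radii)."""
    occ = np.zeros(shape, dtype=bool)
    n = np.array(shape)
    for pos, r in zip(atoms, radii):
        idx = (pos - origin) / spacing
        lo = np.maximum(np.ceil(idx - r / spacing).astype(int), 0)
        hi = np.minimum(np.floor(idx + r / spacing).astype(int), n - 1)
        if np.any(hi < lo):
            continue
        ax = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        d2 = ((gx - idx[0]) ** 2 + (gy - idx[1]) ** 2
              + (gz - idx[2]) ** 2) * spacing ** 2
        sub = d2 <= r * r
        occ[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= sub
    return occ


def _is_site_residue(res: Residue, site: MetalSite) -> bool:
    if not res.is_metal_code:
        return False
    for atom in res.atoms:
        d = np.linalg.norm(site.metal_coords - atom.xyz, axis=1)
        if np.any(d < 1e-3):
            return True
    return False


def _occluder_atoms(s: Structure, site: MetalSite,
                    exclude_sidechains_of: set[tuple] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom coordinates + vdW radii of everything that occludes space."""
    coords, radii = [], []
    skip_sidechains = exclude_sidechains_of or set()
    for res in s.residues():
        if res.is_water or _is_site_residue(res, site):
            continue
        for atom in res.heavy_atoms():
            if res.id in skip_sidechains and res.is_amino_acid \
                    and atom.name not in ("N", "CA", "C", "O", "OXT"):
                continue
            coords.append(atom.xyz)
            radii.append(VDW_RADII.get(atom.element, DEFAULT_VDW))
    if not coords:
        return np.empty((0, 3)), np.empty(0)
    return np.vstack(coords), np.array(radii)


def _detect(site: MetalSite, coords: np.ndarray, radii: np.ndarray,
            anchor_xyz: np.ndarray | None, cfg: PocketConfig,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Core detection: returns (pocket points, opening points), world coords."""
    h = cfg.spacing
    n = int(round(2 * cfg.box_r / h)) + 1
    origin = site.center - cfg.box_r
    shape = (n, n, n)
    if len(coords) == 0 or anchor_xyz is None:
        return np.empty((0, 3)), np.empty((0, 3))
    occ = _occupancy(shape, origin, h, coords, radii + cfg.probe)

    burial = np.zeros(shape, dtype=np.int8)
    for step in _SCAN_DIRECTIONS:
        step_len = h * np.sqrt(sum(abs(c) for c in step))
        n_steps = max(int(cfg.scan_range / step_len), 1)
        fwd = _blocked(occ, step, n_steps)
        bwd = _blocked(occ, tuple(-c for c in step), n_steps)
        burial += (fwd & bwd)
    unburied = ~occ & (burial < cfg.burial_min)
    candidate = ~occ & (burial >= cfg.burial_min)
    if not candidate.any():
        return np.empty((0, 3)), np.empty((0, 3))

    labels, _ = ndimage.label(candidate, structure=np.ones((3, 3, 3)))
    cand_idx = np.argwhere(candidate)
    cand_xyz = origin + cand_idx * h
    nearest = np.argmin(np.linalg.norm(cand_xyz - anchor_xyz, axis=1))
    seed = tuple(cand_idx[nearest])
    pocket = labels == labels[seed]

    # opening: pocket cells 26-adjacent to unburied space (box edge counts)
    padded = np.pad(unburied, 1, constant_values=True)
    near_open = ndimage.binary_dilation(
        padded, structure=np.ones((3, 3, 3)))[1:-1, 1:-1, 1:-1]
    opening = pocket & near_open

    pocket_xyz = origin + np.argwhere(pocket) * h
    opening_xyz = origin + np.argwhere(opening) * h
    return pocket_xyz, opening_xyz


def _frame_rotation(site_center: np.ndarray,
                    opening_center: np.ndarray | None) -> np.ndarray:
    if opening_center is None:
        return np.eye(3)
    v = opening_center - site_center
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        return np.eye(3)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [v / norm])
    return rot.as_matrix()


def build_pocket(site: MetalSite, s: Structure,
                 cfg: PocketConfig | None = None) -> PocketGrid:
    """Detect the pocket for one site.

    A fully exposed site (burial threshold never met, or no candidate cell
    reachable from the anchor) yields a degenerate pocket with zero points;
    all void features are then 0 and lining features use empty-set
    conventions.
    """
    cfg = cfg or PocketConfig()
    coords, radii = _occluder_atoms(s, site)
    anchor = None
    anchor_xyz = None
    best = np.inf
    for info in site.residue_index:
        if info.min_heavy_distance < best:
            best = info.min_heavy_distance
            anchor = info.residue
    if anchor is not None:
        atoms = anchor.coords(heavy_only=True)
        anchor_xyz = atoms[np.argmin(
            np.linalg.norm(atoms - site.center, axis=1))]
    pocket_xyz, opening_xyz = _detect(site, coords, radii, anchor_xyz, cfg)
    opening_center = (opening_xyz.mean(axis=0)
                      if len(opening_xyz) else None)
    return PocketGrid(
        spacing=cfg.spacing,
        site_center=np.asarray(site.center, dtype=float),
        protein_centroid=s.protein_centroid(),
        anchor_residue=anchor,
        points=pocket_xyz,
        opening_points=opening_xyz,
        opening_center=opening_center,
        rotation=_frame_rotation(site.center, opening_center),
    )


# ---------------------------------------------------------------------------
# Void features
# ---------------------------------------------------------------------------

SLICE_NAMES = ("bottom", "middle", "top")


@dataclass
class SliceMetrics:
    farthest_distance: float = 0.0
    hull_area: float = 0.0
    ellipse_offset: float = 0.0
    ellipse_r_major: float = 0.0
    ellipse_r_minor: float = 0.0


@dataclass
class PocketVoidFeatures:
    volume: float = 0.0
    depth: float = 0.0
    cityblock_to_opening: float = 0.0
    centroid_offset: float = 0.0
    slices: dict[str, SliceMetrics] = field(default_factory=dict)

    def as_dict(self, prefix: str = "pok_") -> dict[str, float]:
        out = {
            f"{prefix}volume": self.volume,
            f"{prefix}depth": self.depth,
            f"{prefix}cityblock_to_opening": self.cityblock_to_opening,
            f"{prefix}centroid_offset": self.centroid_offset,
        }
        for name in SLICE_NAMES:
            m = self.slices.get(name, SliceMetrics())
            out[f"{prefix}{name}_farthest"] = m.farthest_distance
            out[f"{prefix}{name}_hull_area"] = m.hull_area
            out[f"{prefix}{name}_ellipse_offset"] = m.ellipse_offset
            out[f"{prefix}{name}_ellipse_r_major"] = m.ellipse_r_major
            out[f"{prefix}{name}_ellipse_r_minor"] = m.ellipse_r_minor
        return out


def _slice_metrics(xy: np.ndarray) -> SliceMetrics:
    m = SliceMetrics()
    if len(xy) == 0:
        return m
    if len(xy) == 1:
        m.ellipse_offset = float(np.linalg.norm(xy[0]))
        return m
    try:
        hull = ConvexHull(xy)
        verts = xy[hull.vertices]
        m.hull_area = float(hull.volume)   # 2-D: .volume is the area
    except QhullError:                      # collinear/degenerate slice
        verts = xy
    # farthest pairwise distance over hull vertices (== over all points)
    diffs = verts[:, None, :] - verts[None, :, :]
    m.farthest_distance = float(np.sqrt((diffs ** 2).sum(-1)).max())
    center = verts.mean(axis=0)
    m.ellipse_offset = float(np.linalg.norm(center))
    if len(verts) >= 3 and m.hull_area > 0:
        cov = np.cov((verts - center).T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        m.ellipse_r_major = float(2 * np.sqrt(eig[0]))
        m.ellipse_r_minor = float(2 * np.sqrt(eig[1]))
    return m


def void_features(p: PocketGrid) -> PocketVoidFeatures:
    """Pocket-void geometry: volume, depth, opening distances, slice shapes.

    Pocket points are rotated so +z runs from site center to opening center,
    split into three equal-thickness z bands (bottom/middle/top), each
    projected to the xy-plane; per band the farthest point pair distance,
    convex-hull area, and the second-moment ellipse of the hull vertices
    (radii = 2·sqrt eigenvalues, center offset from the frame origin).
    """
    feats = PocketVoidFeatures()
    feats.slices = {name: SliceMetrics() for name in SLICE_NAMES}
    if p.n_points == 0:
        # degenerate pocket: the whole void category is zero
        return feats
    feats.volume = p.volume
    feats.centroid_offset = float(
        np.linalg.norm(p.site_center - p.protein_centroid))
    if p.opening_center is not None:
        delta = p.opening_center - p.site_center
        feats.depth = float(np.linalg.norm(delta))
        feats.cityblock_to_opening = float(np.abs(delta).sum())
    pts = p.frame_coords()
    z = pts[:, 2]
    zmin, zmax = z.min(), z.max()
    h = (zmax - zmin) / 3 if zmax > zmin else 1.0
    for i, name in enumerate(SLICE_NAMES):
        lo = zmin + i * h
        hi = zmin + (i + 1) * h if i < 2 else np.inf
        band = pts[(z >= lo) & (z < hi)] if i < 2 else pts[z >= lo]
        feats.slices[name] = _slice_metrics(band[:, :2])
    return feats


# ---------------------------------------------------------------------------
# Lining features
# ---------------------------------------------------------------------------

@dataclass
class PocketLiningFeatures:
    hydrophobicity: dict[str, dict[str, float]] = field(default_factory=dict)
    n_backbone_lining: int = 0
    n_sidechain_lining: int = 0
    occluding_volume: float = 0.0
    pocket_volume_no_sidechains: float = 0.0
    lj_volume_occupied: float = 0.0
    wall_surface_area: float = 0.0

    def as_dict(self, prefix: str = "lin_") -> dict[str, float]:
        out: dict[str, float] = {}
        for scale in ("eisenberg", "kd"):
            stats = self.hydrophobicity.get(scale, {})
            for stat in ("mean", "min", "max", "skew", "sd"):
                out[f"{prefix}{scale}_{stat}"] = stats.get(stat, 0.0)
        out[f"{prefix}n_backbone"] = float(self.n_backbone_lining)
        out[f"{prefix}n_sidechain"] = float(self.n_sidechain_lining)
        out[f"{prefix}occluding_volume"] = self.occluding_volume
        out[f"{prefix}volume_no_sidechains"] = self.pocket_volume_no_sidechains
        out[f"{prefix}lj_volume_occupied"] = self.lj_volume_occupied
        out[f"{prefix}wall_sasa"] = self.wall_surface_area
        return out


def _hydro_stats(values: list[float]) -> dict[str, float]:
    if not values:
        return {"mean": 0.0, "min": 0.0, "max": 0.0, "skew": 0.0, "sd": 0.0}
    arr = np.asarray(values)
    sk = float(_skew(arr)) if len(arr) >= 3 and arr.std() > 0 else 0.0
    return {"mean": float(arr.mean()), "min": float(arr.min()),
            "max": float(arr.max()), "skew": sk, "sd": float(arr.std())}


def _residue_sasa(s: Structure, residues: set[tuple]) -> float:
    """Shrake–Rupley solvent-accessible surface area (probe 1.4 Å) summed
    over the given residues, via biotite."""
    import biotite.structure as struc

    entries = []
    for res in s.residues():
        if res.is_water:
            continue
        for atom in res.heavy_atoms():
            entries.append((res, atom))
    if not entries:
        return 0.0
    arr = struc.AtomArray(len(entries))
    arr.coord = np.vstack([a.xyz for _, a in entries]).astype(np.float32)
    arr.chain_id = np.array([r.chain_id for r, _ in entries], dtype="U4")
    arr.res_id = np.array([r.seq_number for r, _ in entries])
    arr.res_name = np.array([r.name for r, _ in entries], dtype="U5")
    arr.atom_name = np.array([a.name for _, a in entries], dtype="U6")
    arr.element = np.array([a.element.capitalize() for _, a in entries],
                           dtype="U2")
    arr.hetero = np.array([r.is_hetero for r, _ in entries])
    sasa = struc.sasa(arr, probe_radius=1.4, vdw_radii="Single")
    total = 0.0
    for (res, _), value in zip(entries, sasa):
        if res.id in residues and np.isfinite(value):
            total += float(value)
    return total


def lining_features(p: PocketGrid, s: Structure, site: MetalSite,
                    cfg: PocketConfig | None = None) -> PocketLiningFeatures:
    """Pocket lining: residues with a heavy atom within 2.2 Å of a pocket cell.

    A residue is *sidechain-lining* when any sidechain atom qualifies (its
    backbone atoms then count with it), *backbone-only* when exclusively
    backbone atoms are adjacent (glycine can only ever be backbone-only).
    Adjacency is measured from the atom's van der Waals surface (distance
    to a pocket point minus the vdW radius ≤ 2.2 Å) — grid cells are
    already eroded by vdW + probe, so center-to-center distances never get
    that close.  Hydrophobicity statistics run over the sidechain-lining
    residues on the Eisenberg and Kyte–Doolittle scales.
    """
    cfg = cfg or PocketConfig()
    feats = PocketLiningFeatures()
    feats.hydrophobicity = {k: _hydro_stats([]) for k in HYDROPHOBICITY_SCALES}
    if p.n_points == 0:
        return feats
    tree = cKDTree(p.points)

    def _adjacent(atom) -> bool:
        radius = VDW_RADII.get(atom.element, DEFAULT_VDW) + cfg.lining_cutoff
        return bool(tree.query_ball_point(atom.xyz, radius))

    sidechain_lining: list[Residue] = []
    backbone_only: list[Residue] = []
    for res in s.residues():
        if not res.is_amino_acid:
            continue
        sc_hit = any(_adjacent(a) for a in res.sidechain_atoms())
        bb_hit = any(_adjacent(a) for a in res.backbone_atoms())
        if sc_hit:
            sidechain_lining.append(res)
        elif bb_hit:
            backbone_only.append(res)

    feats.n_sidechain_lining = len(sidechain_lining)
    feats.n_backbone_lining = len(backbone_only)
    for scale_name, scale in HYDROPHOBICITY_SCALES.items():
        values = [scale[r.name] for r in sidechain_lining if r.name in scale]
        feats.hydrophobicity[scale_name] = _hydro_stats(values)
    feats.occluding_volume = sum(sidechain_volume(r.name)
                                 for r in sidechain_lining)

    # pocket re-detected with lining sidechains removed
    lining_ids = {r.id for r in sidechain_lining}
    coords, radii = _occluder_atoms(s, site, exclude_sidechains_of=lining_ids)
    anchor_xyz = None
    if p.anchor_residue is not None:
        atoms = p.anchor_residue.coords(heavy_only=True)
        anchor_xyz = atoms[np.argmin(
            np.linalg.norm(atoms - p.site_center, axis=1))]
    open_xyz, _ = _detect(site, coords, radii, anchor_xyz, cfg)
    vol_no_sc = cfg.spacing ** 3 * len(open_xyz)
    feats.pocket_volume_no_sidechains = max(vol_no_sc, p.volume)

    # share of that enlarged pocket filled by lining sidechain atoms at vdW
    if len(open_xyz):
        sc_atoms = [(a.xyz, VDW_RADII.get(a.element, DEFAULT_VDW))
                    for r in sidechain_lining for a in r.sidechain_atoms()]
        if sc_atoms:
            open_tree = cKDTree(open_xyz)
            filled: set[int] = set()
            for xyz, r in sc_atoms:
                filled.update(open_tree.query_ball_point(xyz, r))
            feats.lj_volume_occupied = cfg.spacing ** 3 * len(filled)

    feats.wall_surface_area = _residue_sasa(
        s, {r.id for r in sidechain_lining})
    return feats


def write_pocket_pdb(p: PocketGrid, path: str | Path) -> None:
    """Debug export: pocket points as HETATM pseudo-atoms for visualization."""
    lines = []
    for i, (x, y, z) in enumerate(p.points, start=1):
        lines.append(
            f"HETATM{i % 100000:>5d}  O   POC P   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
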