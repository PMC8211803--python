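"""Metal coordination geometry classification and coordination-sphere features.

The coordination polyhedron of each metal is matched against a library of 36
idealized geometries (coordination numbers 2–9, including *vacant* variants —
parent geometries missing one vertex).  The match minimizes the RMSD between
the unit coordination vectors and the ideal vertex vectors over vertex
permutations and rigid rotations (Kabsch superposition); the best entry names
the geometry, decides whether a vacancy is present, and — through RMSD
thresholds — whether the geometry is regular, distorted or irregular.

Further coordination-sphere descriptors: donor-atom counts by element
(N/O/S/other), angular deviations from the ideal vertices, the bond valence
sum ``Σ exp((R0 − d)/b)`` with ``b = 0.37 Å`` and tabulated per-pair ``R0``,
and the bond valence normalized by the metal's nominal oxidation state
(ideal coordination gives a normalized bond valence of 1).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .sites import MetalSite
from .structure import (METAL_CODE_OXIDATION_STATE, METAL_ELEMENTS,
                        Structure)

logger = logging.getLogger(__name__)

BOND_VALENCE_B = 0.37
GENERIC_R0 = 1.8
DEFAULT_COORDINATION_CUTOFF = 2.8

REGULAR_RMSD = 0.25
DISTORTED_RMSD = 0.55


# ---------------------------------------------------------------------------
# Geometry library
# ---------------------------------------------------------------------------

def _sph(polar_deg: float, azimuth_deg: float) -> list[float]:
    t, p = math.radians(polar_deg), math.radians(azimuth_deg)
    return [math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)]


def _ring(n: int, polar_deg: float = 90.0, phase_deg: float = 0.0
          ) -> list[list[float]]:
    return [_sph(polar_deg, phase_deg + 360.0 * i / n) for i in range(n)]


def _tetrahedron() -> list[list[float]]:
    s = 1 / math.sqrt(3)
    return [[s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]


def _octahedron() -> list[list[float]]:
    return [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
            [0, 0, -1]]


def _cube() -> list[list[float]]:
    s = 1 / math.sqrt(3)
    return [[sx * s, sy * s, sz * s]
            for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]


def _trigonal_prism() -> list[list[float]]:
    return _ring(3, 54.7356, 0.0) + _ring(3, 125.2644, 0.0)


def _square_antiprism() -> list[list[float]]:
    return _ring(4, 60.0, 0.0) + _ring(4, 120.0, 45.0)


def _square_pyramid() -> list[list[float]]:
    # apex plus four basal vertices pushed slightly below the equator
    return [[0.0, 0.0, 1.0]] + _ring(4, 104.0, 0.0)


def _triangular_dodecahedron() -> list[list[float]]:
    # D2d snub-disphenoid arrangement: two orthogonal trapezoids
    a, b = 36.85, 69.46
    return [_sph(a, 0), _sph(a, 180), _sph(180 - a, 90), _sph(180 - a, 270),
            _sph(b, 90), _sph(b, 270), _sph(180 - b, 0), _sph(180 - b, 180)]


def _tricapped_trigonal_prism() -> list[list[float]]:
    return _trigonal_prism() + _ring(3, 90.0, 60.0)


@dataclass(frozen=True)
class GeometryEntry:
    name: str
    coordination_number: int
    vertices: np.ndarray          # (cn, 3), unit vectors
    vacancy_parent: str | None = None    # parent geometry when vacant variant

    @property
    def is_vacant(self) -> bool:
        return self.vacancy_parent is not None


def _entry(name: str, verts: list[list[float]],
           parent: str | None = None) -> GeometryEntry:
    arr = np.asarray(verts, dtype=float)
    arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    return GeometryEntry(name=name, coordination_number=len(arr),
                         vertices=arr, vacancy_parent=parent)


def _build_library() -> list[GeometryEntry]:
    tet = _tetrahedron()
    octa = _octahedron()
    cube = _cube()
    prism = _trigonal_prism()
    sap = _square_antiprism()
    spy = _square_pyramid()
    ttp = _tricapped_trigonal_prism()
    entries = [
        # CN 2
        _entry("linear", [[0, 0, 1], [0, 0, -1]]),
        _entry("bent", _ring(2, 90)[0:1] + [_sph(90, 120)],
               parent="trigonal_planar"),
        # CN 3
        _entry("trigonal_planar", _ring(3, 90)),
        _entry("trigonal_pyramid", tet[:3], parent="tetrahedron"),
        _entry("t_shape", [[1, 0, 0], [-1, 0, 0], [0, 1, 0]],
               parent="square_planar"),
        # three mutually orthogonal donors (a fac-octahedral fragment);
        # kept as a standalone ideal geometry, not a single-vacancy variant
        _entry("orthogonal_tripod", [[1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        # CN 4
        _entry("tetrahedron", tet),
        _entry("square_planar", _ring(4, 90)),
        _entry("trigonal_bipyramid_axial_vacancy",
               [[0, 0, 1]] + _ring(3, 90), parent="trigonal_bipyramid"),
        _entry("sawhorse", [[0, 0, 1], [0, 0, -1], _sph(90, 0), _sph(90, 120)],
               parent="trigonal_bipyramid"),
        _entry("square_pyramid_basal_vacancy", spy[:4],
               parent="square_pyramid"),
        # CN 5
        _entry("trigonal_bipyramid", [[0, 0, 1], [0, 0, -1]] + _ring(3, 90)),
        _entry("square_pyramid", spy),
        _entry("octahedron_vacancy", [[0, 0, 1]] + _ring(4, 90),
               parent="octahedron"),
        _entry("trigonal_prism_vacancy", prism[:5], parent="trigonal_prism"),
        _entry("pentagonal_planar", _ring(5, 90)),
        # CN 6
        _entry("octahedron", octa),
        _entry("trigonal_prism", prism),
        _entry("pentagonal_bipyramid_axial_vacancy",
               [[0, 0, 1]] + _ring(5, 90), parent="pentagonal_bipyramid"),
        _entry("pentagonal_bipyramid_equatorial_vacancy",
               [[0, 0, 1], [0, 0, -1]] + [_sph(90, 72 * i) for i in range(4)],
               parent="pentagonal_bipyramid"),
        # CN 7
        _entry("pentagonal_bipyramid",
               [[0, 0, 1], [0, 0, -1]] + _ring(5, 90)),
        _entry("capped_octahedron", octa + [[1 / math.sqrt(3)] * 3]),
        _entry("capped_trigonal_prism", prism + [_sph(90, 60)]),
        _entry("cube_vacancy", cube[:7], parent="cube"),
        _entry("square_antiprism_vacancy", sap[:7],
               parent="square_antiprism"),
        _entry("hexagonal_bipyramid_axial_vacancy",
               [[0, 0, 1]] + _ring(6, 90), parent="hexagonal_bipyramid"),
        # CN 8
        _entry("cube", cube),
        _entry("square_antiprism", sap),
        _entry("hexagonal_bipyramid", [[0, 0, 1], [0, 0, -1]] + _ring(6, 90)),
        _entry("bicapped_trigonal_prism",
               prism + [_sph(90, 60), _sph(90, 180)]),
        _entry("triangular_dodecahedron", _triangular_dodecahedron()),
        _entry("tricapped_trigonal_prism_vacancy", ttp[:8],
               parent="tricapped_trigonal_prism"),
        # CN 9
        _entry("tricapped_trigonal_prism", ttp),
        _entry("capped_square_antiprism", sap + [[0, 0, 1]]),
        _entry("capped_cube", cube + [[0, 0, 1]]),
        _entry("heptagonal_bipyramid", [[0, 0, 1], [0, 0, -1]] + _ring(7, 90)),
    ]
    assert len(entries) == 36
    return entries


@dataclass
class GeometryLibrary:
    entries: list[GeometryEntry] = field(default_factory=_build_library)

    def __len__(self) -> int:
        return len(self.entries)

    def by_cn(self, cn: int) -> list[GeometryEntry]:
        return [e for e in self.entries if e.coordination_number == cn]

    def get(self, name: str) -> GeometryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_json(self, path: str | Path) -> None:
        """Export the library as a versioned data file."""
        payload = {"version": 1, "entries": [
            {"name": e.name, "cn": e.coordination_number,
             "vacancy_parent": e.vacancy_parent,
             "vertices": e.vertices.round(6).tolist()}
            for e in self.entries]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeometryLibrary":
        payload = json.loads(Path(path).read_text())
        return cls(entries=[
            _entry(e["name"], e["vertices"], e.get("vacancy_parent"))
            for e in payload["entries"]])


_DEFAULT_LIBRARY: GeometryLibrary | None = None


def default_library() -> GeometryLibrary:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = GeometryLibrary()
    return _DEFAULT_LIBRARY


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Best-rotation RMSD between matched unit-vector sets (b onto a)."""
    rot, rssd = Rotation.align_vectors(a, b)
    return float(rssd / math.sqrt(len(a))), rot.as_matrix()


def _best_permutation_exhaustive(obs: np.ndarray, ideal: np.ndarray
                                 ) -> tuple[float, tuple[int, ...], np.ndarray]:
    best = (np.inf, tuple(range(len(obs))), np.eye(3))
    for perm in itertools.permutations(range(len(ideal))):
        rmsd, rot = _kabsch_rmsd(obs, ideal[list(perm)])
        if rmsd < best[0]:
            best = (rmsd, perm, rot)
    return best


def _best_permutation_iterative(obs: np.ndarray, ideal: np.ndarray,
                                n_seeds: int = 8, n_iter: int = 30
                                ) -> tuple[float, tuple[int, ...], np.ndarray]:
    """Greedy+refine for CN > 6: alternate optimal assignment (Hungarian on
    negative dot products) with Kabsch refitting from several seeded
    rotations."""
    rng = np.random.default_rng(20210617)
    seeds = [np.eye(3)] + [Rotation.random(random_state=rng).as_matrix()
                           for _ in range(n_seeds)]
    best = (np.inf, tuple(range(len(obs))), np.eye(3))
    for rot in seeds:
        perm_prev: tuple[int, ...] | None = None
        for _ in range(n_iter):
            rotated = ideal @ rot.T
            cost = -(obs @ rotated.T)
            _, cols = linear_sum_assignment(cost)
            perm = tuple(int(c) for c in cols)
            if perm == perm_prev:
                break
            perm_prev = perm
            rmsd, rot = _kabsch_rmsd(obs, ideal[list(perm)])
        rmsd, rot = _kabsch_rmsd(obs, ideal[list(perm_prev)])
        if rmsd < best[0]:
            best = (rmsd, perm_prev, rot)
    return best


@dataclass
class GeometryMatch:
    name: str
    rmsd: float
    regularity: str                  # regular | distorted | irregular | undetermined
    vacancy: bool
    coordination_number: int
    angle_deviations_deg: list[float] = field(default_factory=list)

    @property
    def angular_deviation_sum(self) -> float:
        return float(sum(self.angle_deviations_deg))

    @property
    def max_angle_deviation(self) -> float:
        return float(max(self.angle_deviations_deg, default=0.0))


def classify_geometry(vectors: np.ndarray,
                      lib: GeometryLibrary | None = None,
                      regular_rmsd: float = REGULAR_RMSD,
                      distorted_rmsd: float = DISTORTED_RMSD) -> GeometryMatch:
    """Match observed coordination unit vectors against the library.

    For each library entry of matching coordination number the RMSD is
    minimized over vertex permutations (exhaustive up to CN 6, greedy with
    refinement above) and the optimal rotation; the lowest-RMSD entry wins.
    Fewer than two vectors give the ``undetermined`` classification.
    """
    lib = lib or default_library()
    vectors = np.asarray(vectors, dtype=float)
    if len(vectors) < 2:
        return GeometryMatch(name="undetermined", rmsd=0.0,
                             regularity="undetermined", vacancy=False,
                             coordination_number=len(vectors))
    obs = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    cn = len(obs)
    best_entry: GeometryEntry | None = None
    best = (np.inf, (), np.eye(3))
    for entry in lib.by_cn(cn):
        if cn <= 6:
            result = _best_permutation_exhaustive(obs, entry.vertices)
        else:
            result = _best_permutation_iterative(obs, entry.vertices)
        if result[0] < best[0]:
            best = result
            best_entry = entry
    if best_entry is None:
        return GeometryMatch(name="undetermined", rmsd=0.0,
                             regularity="undetermined", vacancy=False,
                             coordination_number=cn)
    rmsd, perm, rot = best
    ideal_rot = best_entry.vertices[list(perm)] @ rot.T
    cosines = np.clip((obs * ideal_rot).sum(axis=1), -1.0, 1.0)
    angles = list(np.degrees(np.arccos(cosines)))
    if rmsd <= regular_rmsd:
        regularity = "regular"
    elif rmsd <= distorted_rmsd:
        regularity = "distorted"
    else:
        regularity = "irregular"
    return GeometryMatch(name=best_entry.name, rmsd=rmsd,
                         regularity=regularity, vacancy=best_entry.is_vacant,
                         coordination_number=best_entry.coordination_number,
                         angle_deviations_deg=angles)


# ---------------------------------------------------------------------------
# Coordinating atoms and bond valence
# ---------------------------------------------------------------------------

def _load_r0_table() -> dict[str, dict[str, float]]:
    with resources.files("metalsite.data").joinpath(
            "bond_valence_r0.json").open() as fh:
        table = json.load(fh)
    return {k: v for k, v in table.items() if not k.startswith("_")}


R0_TABLE = _load_r0_table()


@dataclass
class CoordinatingAtom:
    element: str
    xyz: np.ndarray
    distance: float
    residue_name: str


def coordinating_atoms(metal_xyz: np.ndarray, s: Structure,
                       cutoff: float = DEFAULT_COORDINATION_CUTOFF,
                       pair_cutoffs: dict[tuple[str, str], float] | None = None,
                       metal_element: str = "",
                       ) -> list[CoordinatingAtom]:
    """Non-carbon, non-hydrogen heavy atoms within the coordination cutoff.

    Atoms of metal-residue-code groups (the metal itself and its cluster
    partners) are excluded; water oxygens count.  ``pair_cutoffs`` may
    override the cutoff per (metal element, donor element) pair.
    """
    pair_cutoffs = pair_cutoffs or {}
    found = []
    metal_xyz = np.asarray(metal_xyz, dtype=float)
    for res in s.residues():
        if res.is_metal_code:
            continue
        for atom in res.heavy_atoms():
            if atom.element in ("C", "H") or atom.element in METAL_ELEMENTS:
                continue
            limit = pair_cutoffs.get((metal_element, atom.element), cutoff)
            d = float(np.linalg.norm(atom.xyz - metal_xyz))
            if d <= limit:
                found.append(CoordinatingAtom(
                    element=atom.element, xyz=atom.xyz, distance=d,
                    residue_name=res.name))
    found.sort(key=lambda a: a.distance)
    return found


def bond_valence(atoms: list[CoordinatingAtom], metal_element: str,
                 oxidation_state: int | None = None) -> tuple[float, float]:
    """Bond valence sum and its oxidation-state-normalized value.

    ``bv = Σ exp((R0 − d)/0.37)``; unknown metal–donor pairs fall back to a
    generic R0 with a warning.  ``normalized_bv = bv / nominal oxidation
    state`` (1 for ideal coordination).
    """
    bv = 0.0
    for atom in atoms:
        pair_table = R0_TABLE.get(metal_element, {})
        r0 = pair_table.get(atom.element)
        if r0 is None:
            logger.warning("no R0 for pair %s-%s; using generic %.2f",
                           metal_element, atom.element, GENERIC_R0)
            r0 = GENERIC_R0
        bv += math.exp((r0 - atom.distance) / BOND_VALENCE_B)
    ox = oxidation_state or 2
    return bv, bv / ox


# ---------------------------------------------------------------------------
# Per-site features
# ---------------------------------------------------------------------------

_REGULARITY_CODE = {"regular": 0.0, "distorted": 1.0, "irregular": 2.0,
                    "undetermined": 2.0}


@dataclass
class CoordFeatures:
    features: dict[str, float]
    matches: list[GeometryMatch] = field(default_factory=list)

    def geometry_onehot(self, lib: GeometryLibrary | None = None
                        ) -> dict[str, float]:
        """Indicator per library geometry name; computed for reporting but
        excluded from the training schema (assignments are too diverse)."""
        lib = lib or default_library()
        onehot = {f"geoname_{e.name}": 0.0 for e in lib.entries}
        for m in self.matches:
            key = f"geoname_{m.name}"
            if key in onehot:
                onehot[key] = 1.0
        return onehot


def site_charge(site: MetalSite, s: Structure) -> int:
    """Formal site charge from FORMUL records (nominal oxidation state when
    the file carries no charge for a code)."""
    total = 0
    for res in s.residues():
        if not res.is_metal_code:
            continue
        for atom in res.metal_atoms():
            d = np.linalg.norm(site.metal_coords - atom.xyz, axis=1)
            if np.any(d < 1e-3):
                total += s.formul_charges.get(
                    res.name, METAL_CODE_OXIDATION_STATE.get(res.name, 0))
                break
    return total


def coord_features(site: MetalSite, s: Structure,
                   cutoff: float = DEFAULT_COORDINATION_CUTOFF,
                   lib: GeometryLibrary | None = None) -> CoordFeatures:
    """All coordination-geometry features for one site (``geo_`` prefix)."""
    lib = lib or default_library()
    matches: list[GeometryMatch] = []
    counts = {"N": 0, "O": 0, "S": 0, "other": 0}
    bv_total = 0.0
    ox_total = 0
    ang_sum = 0.0
    ang_max = 0.0
    cn_total = 0
    n_coord_total = 0
    code_by_metal: list[str] = []
    for res in s.residues():
        if not res.is_metal_code:
            continue
        for atom in res.metal_atoms():
            d = np.linalg.norm(site.metal_coords - atom.xyz, axis=1)
            if not np.any(d < 1e-3):
                continue
            code_by_metal.append(res.name)
            donors = coordinating_atoms(atom.xyz, s, cutoff,
                                        metal_element=atom.element)
            n_coord_total += len(donors)
            for donor in donors:
                counts[donor.element if donor.element in counts
                       else "other"] += 1
            ox = METAL_CODE_OXIDATION_STATE.get(res.name, 2)
            ox_total += ox
            bv, _ = bond_valence(donors, atom.element, ox)
            bv_total += bv
            vectors = np.array([(a.xyz - atom.xyz) / a.distance
                                for a in donors]) if donors else np.empty((0, 3))
            match = classify_geometry(vectors, lib)
            matches.append(match)
            cn_total += match.coordination_number
            ang_sum += match.angular_deviation_sum
            ang_max = max(ang_max, match.max_angle_deviation)
    n_metals = max(len(code_by_metal), 1)
    regularity = max((_REGULARITY_CODE[m.regularity] for m in matches),
                     default=2.0)
    feats = {
        "geo_cn_total": float(cn_total),
        "geo_cn_mean": cn_total / n_metals,
        "geo_vacancy": float(any(m.vacancy for m in matches)),
        "geo_regularity": regularity,
        "geo_n_coord_total": float(n_coord_total),
        "geo_n_coord_mean": n_coord_total / n_metals,
        "geo_site_charge": float(site_charge(site, s)),
        "geo_angdev_sum": ang_sum,
        "geo_angdev_max": ang_max,
        "geo_bond_valence": bv_total,
        "geo_norm_bond_valence": bv_total / max(ox_total, 1),
    }
    for element in ("N", "O", "S", "other"):
        key = element.lower()
        feats[f"geo_n_{key}_total"] = float(counts[element])
        feats[f"geo_n_{key}_mean"] = counts[element] / n_metals
    return CoordFeatures(features=feats, matches=matches)
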