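"""Deterministic synthetic inputs: toy metalloprotein structures, energy
tables and labeled feature tables.

Every generator is a pure function of its spec (scenario + seed + size
parameters), so two runs produce byte-identical files.  The structures are
geometrically exact by construction — e.g. the zinc scenario places two
cysteine sulfurs and two histidine ND1 nitrogens at 2.1 Å in perfect
tetrahedral directions — so they double as oracles for the geometry, site
and pocket code.  Cavity walls are built from single-atom glycine
pseudo-residues laid out on the dilated boundary surface of the intended
void, which makes the void shape analytically known.

These are not physical decoys: no rotamer realism, no hydrogen atoms, no
crystallographic symmetry.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import DEFAULT_TERM_SCHEMA
from .structure import Atom, Chain, Residue, Structure, write_structure

SCENARIOS = ("zinc_tetrahedral_pocket", "surface_magnesium", "dinuclear_site",
             "hemisphere_cavity", "separable_features", "null_features")

#: ideal tetrahedral unit vectors
TETRAHEDRAL = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / math.sqrt(3)

# effective occupancy erosion of the pocket grid: carbon vdW 1.7 + probe 1.4
_EROSION = 1.7 + 1.4


@dataclass
class FixtureSpec:
    scenario: str
    seed: int = 0
    size: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


# ---------------------------------------------------------------------------
# Geometric helpers
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n near-evenly spaced points on a sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1 + math.sqrt(5)) * i
    cos_t = 1 - 2 * i / n
    sin_t = np.sqrt(np.clip(1 - cos_t ** 2, 0, 1))
    return radius * np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _ring_points(radius: float, z: float, spacing: float) -> np.ndarray:
    n = max(int(round(2 * math.pi * radius / spacing)), 3)
    ang = 2 * math.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.full(n, z)])


def cavity_wall_points(r_void: float = 5.0, chimney_r: float | None = 0.8,
                       chimney_len: float = 4.0, spacing: float = 0.5,
                       ) -> np.ndarray:
    """Wall atoms whose union of (vdW + probe) balls leaves a hemispherical
    void of radius ``r_void`` (z < 0).

    Atoms sit on the boundary of the void dilated by the erosion distance
    (3.1 Å for carbon with a 1.4 Å probe): a spherical shell, a ceiling
    disk above the mouth, and the blending torus around the mouth circle.
    With ``chimney_r`` set, a solvent channel of that radius pierces the
    ceiling (the channel flares near the mouth, since no wall atom may come
    within the erosion distance of the mouth disk); ``chimney_r=None``
    seals the ceiling, making the void exactly the hemisphere.
    """
    e = _EROSION
    shell_r = r_void + e
    pieces = []
    # lower hemispherical shell
    n_shell = int(4 * math.pi * shell_r ** 2 / spacing ** 2)
    sphere = _fibonacci_sphere(n_shell, shell_r)
    pieces.append(sphere[sphere[:, 2] < 0.0])
    if chimney_r is not None:
        # chimney cylinder; wall atoms must stay at least the erosion
        # distance from the mouth disk, so it starts at z = e
        cyl_r = chimney_r + e
        for z in np.arange(e, e + chimney_len + spacing / 2, spacing):
            pieces.append(_ring_points(cyl_r, z, spacing))
        ceiling_inner = cyl_r
    else:
        ceiling_inner = 0.0
    # ceiling disk/annulus at z = erosion, out to the mouth radius
    for r in np.arange(ceiling_inner, r_void + spacing / 2, spacing):
        pieces.append(_ring_points(max(r, spacing / 4), e, spacing))
    # blending torus around the mouth circle (r_void, z = 0)
    n_arc = max(int(round((math.pi / 2) * e / spacing)), 2)
    for j in range(n_arc + 1):
        ang = (math.pi / 2) * j / n_arc
        r = r_void + e * math.sin(ang)
        z = e * math.cos(ang)
        pieces.append(_ring_points(r, z, spacing))
    return np.vstack(pieces)


def _wall_residues(chain: Chain, points: np.ndarray, start_num: int = 1000
                   ) -> None:
    """Attach wall points as single-atom glycine pseudo-residues."""
    for i, xyz in enumerate(points):
        chain.residues.append(Residue(
            chain_id=chain.id, seq_number=start_num + i, name="GLY",
            atoms=[Atom(name="CA", element="C", xyz=xyz)]))


def _metal_residue(chain_id: str, seq: int, code: str, element: str,
                   xyz: np.ndarray) -> Residue:
    return Residue(chain_id=chain_id, seq_number=seq, name=code,
                   atoms=[Atom(name=element, element=element, xyz=xyz,
                               is_hetero=True)], is_hetero=True)


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _cys(chain_id: str, seq: int, v: np.ndarray) -> Residue:
    t = _perp(v)
    atoms = [
        Atom("SG", "S", 2.1 * v),
        Atom("CB", "C", 3.6 * v),
        Atom("CA", "C", 5.0 * v),
        Atom("N", "N", 5.0 * v + 1.45 * t),
        Atom("C", "C", 5.0 * v - 1.50 * t),
        Atom("O", "O", 5.8 * v - 1.70 * t),
    ]
    return Residue(chain_id=chain_id, seq_number=seq, name="CYS", atoms=atoms)


def _his(chain_id: str, seq: int, v: np.ndarray) -> Residue:
    t = _perp(v)
    atoms = [
        Atom("ND1", "N", 2.1 * v),
        Atom("CE1", "C", 2.1 * v + 1.35 * t),
        Atom("NE2", "N", 3.1 * v + 1.45 * t),
        Atom("CD2", "C", 3.5 * v + 0.6 * t),
        Atom("CG", "C", 3.4 * v),
        Atom("CB", "C", 4.3 * v),
        Atom("CA", "C", 5.2 * v),
        Atom("N", "N", 5.2 * v + 1.45 * t),
        Atom("C", "C", 5.2 * v - 1.50 * t),
        Atom("O", "O", 6.0 * v - 1.70 * t),
    ]
    return Residue(chain_id=chain_id, seq_number=seq, name="HIS", atoms=atoms)


# ---------------------------------------------------------------------------
# Structure scenarios
# ---------------------------------------------------------------------------

def _zinc_tetrahedral_pocket(spec: FixtureSpec) -> Structure:
    """Zn(2+) at the origin, 2 CYS S + 2 HIS N donors at 2.1 Å in perfect
    tetrahedral directions, inside a domed cavity of radius 6 Å."""
    chain = Chain(id="A")
    chain.residues.append(_cys("A", 1, TETRAHEDRAL[0]))
    chain.residues.append(_cys("A", 2, TETRAHEDRAL[1]))
    chain.residues.append(_his("A", 3, TETRAHEDRAL[2]))
    chain.residues.append(_his("A", 4, TETRAHEDRAL[3]))
    wall = cavity_wall_points(r_void=float(spec.size.get("cavity_radius", 6.0)),
                              chimney_r=1.0, spacing=0.6)
    _wall_residues(chain, wall, start_num=100)
    chain.residues.append(_metal_residue("A", 5001, "ZN", "ZN",
                                         np.zeros(3)))
    s = Structure(
        id="zn01", chains=[chain], resolution=1.8,
        classification="TRANSFERASE",
        molecule_names={"A": "ZINC TRANSFERASE"},
        ec_numbers={"A": "2.1.1.1"},
        formul_charges={"ZN": 2},
        deposition_date=_dt.date(2015, 6, 17),
        uniprot_by_chain={"A": "P00000"},
    )
    return s


def _surface_magnesium(spec: FixtureSpec) -> Structure:
    """Mg(2+) resting on a flat slab: a fully exposed, pocketless site."""
    chain = Chain(id="A")
    xs = np.arange(-9.0, 9.1, 1.2)
    points = [np.array([x, y, z])
              for z in (-3.0, -4.2) for x in xs for y in xs]
    _wall_residues(chain, np.array(points), start_num=100)
    chain.residues.append(_metal_residue("A", 5001, "MG", "MG",
                                         np.array([0.0, 0.0, 0.0])))
    return Structure(
        id="mg01", chains=[chain], resolution=2.0,
        classification="METAL TRANSPORT",
        molecule_names={"A": "MAGNESIUM CARRIER"},
        formul_charges={"MG": 2},
        deposition_date=_dt.date(2016, 3, 1),
    )


def _dinuclear_site(spec: FixtureSpec) -> Structure:
    """Two zinc ions 4.9 Å apart on one chain: a single dinuclear site."""
    gap = float(spec.size.get("metal_gap", 4.9))
    chain = Chain(id="A")
    ring = _ring_points(8.0, 0.0, 2.2)
    ring2 = _ring_points(8.0, gap, 2.2)
    _wall_residues(chain, np.vstack([ring, ring2]), start_num=100)
    chain.residues.append(_metal_residue("A", 5001, "ZN", "ZN",
                                         np.array([0.0, 0.0, 0.0])))
    chain.residues.append(_metal_residue("A", 5002, "ZN", "ZN",
                                         np.array([0.0, 0.0, gap])))
    return Structure(
        id="zn02", chains=[chain], resolution=1.9,
        classification="HYDROLASE", molecule_names={"A": "DIZINC HYDROLASE"},
        ec_numbers={"A": "3.1.1.1"}, formul_charges={"ZN": 2},
        deposition_date=_dt.date(2017, 9, 10),
    )


def _hemisphere_cavity(spec: FixtureSpec) -> Structure:
    """A radius-r hemispherical cavity in a solid wall, zinc just below the
    hemisphere center.  The analytic void volume is (2/3)·π·r³.

    By default the ceiling is sealed so the void is exactly the hemisphere;
    ``size={"chimney": True}`` pierces it with a solvent channel
    (``chimney_len`` controls the channel length, hence the pocket depth).
    The metal sits half a grid cell below the mouth plane so no grid layer
    falls exactly on the flat cavity boundary.
    """
    r = float(spec.size.get("radius", 5.0))
    chimney = bool(spec.size.get("chimney", False))
    chimney_len = float(spec.size.get("chimney_len", 4.0))
    wall = cavity_wall_points(
        r_void=r, chimney_r=0.8 if chimney else None,
        chimney_len=chimney_len, spacing=0.5)
    chain = Chain(id="A")
    _wall_residues(chain, wall, start_num=100)
    chain.residues.append(_metal_residue("A", 9001, "ZN", "ZN",
                                         np.array([0.0, 0.0, -0.25])))
    return Structure(
        id="hemi", chains=[chain], resolution=1.5,
        classification="SYNTHETIC CAVITY",
        molecule_names={"A": "SYNTHETIC CAVITY WALL"},
        formul_charges={"ZN": 2},
        deposition_date=_dt.date(2019, 1, 1),
    )


def make_structure(spec: FixtureSpec,
                   path: str | Path | None = None) -> Structure:
    """Build the scenario's structure; optionally also write it as PDB."""
    builders = {
        "zinc_tetrahedral_pocket": _zinc_tetrahedral_pocket,
        "surface_magnesium": _surface_magnesium,
        "dinuclear_site": _dinuclear_site,
        "hemisphere_cavity": _hemisphere_cavity,
    }
    if spec.scenario not in builders:
        raise ValueError(f"scenario {spec.scenario!r} is not a structure "
                         "scenario")
    s = builders[spec.scenario](spec)
    if path is not None:
        write_structure(s, path)
    return s


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def make_energy_table(s: Structure, seed: int = 0,
                      terms: tuple[str, ...] = DEFAULT_TERM_SCHEMA,
                      path: str | Path | None = None) -> str:
    """Per-residue energy table text for a structure: standard-normal term
    values from the seed, one row per amino-acid residue."""
    rng = np.random.default_rng(seed)
    lines = ["label " + " ".join(terms)]
    for res in s.residues():
        if not res.is_amino_acid:
            continue
        values = rng.normal(0.0, 1.0, size=len(terms))
        row = " ".join(f"{v:.4f}" for v in values)
        lines.append(f"{res.chain_id}_{res.seq_number} {row}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def make_feature_table(n_pos: int = 240, n_neg: int = 760,
                       n_features: int = 20, n_informative: int = 1,
                       effect_size: float = 5.0, seed: int = 0,
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Labeled Gaussian feature table.

    Features are standard normal; the first ``n_informative`` columns are
    shifted by ``effect_size`` for the positive (enzymatic) class.  The
    default class balance is 24 % positive, matching a realistically
    imbalanced site table; ``effect_size=0`` gives an uninformative null
    table.
    """
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    x = rng.normal(0.0, 1.0, size=(n, n_features))
    x[:n_pos, :n_informative] += effect_size
    perm = rng.permutation(n)
    x, labels = x[perm], labels[perm]
    cols = [f"f{i:02d}" for i in range(n_features)]
    return pd.DataFrame(x, columns=cols), labels


def make_table_from_spec(spec: FixtureSpec) -> tuple[pd.DataFrame, np.ndarray]:
    size = dict(spec.size)
    if spec.scenario == "separable_features":
        size.setdefault("effect_size", 5.0)
    elif spec.scenario == "null_features":
        size["effect_size"] = 0.0
    else:
        raise ValueError(f"scenario {spec.scenario!r} is not a table scenario")
    return make_feature_table(seed=spec.seed, **size)
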