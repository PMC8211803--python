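"""Protein structure data model and PDB/mmCIF input/output.

The pipeline operates on crystal structures of metalloproteins.  This module
exposes a small uniform data model (:class:`Structure` / :class:`Chain` /
:class:`Residue` / :class:`Atom`) on top of gemmi's parsers, carrying exactly
the header metadata downstream stages need: resolution, structure
classification, per-chain molecule names and EC numbers, formal charges from
FORMUL records, and the deposition date.

Conventions (crystal-structure scope):

* multi-model files: model 1 only, with a logged warning;
* alternate locations: the highest-occupancy conformer is kept, ties broken
  by altloc letter order;
* header fields that are absent in the file stay ``None`` — never guessed.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Chemical vocabulary
# ---------------------------------------------------------------------------

#: Ligand residue codes treated as metal sites (Fe/Cu/Zn/Mn/Mg/Mo/Ni/Co forms).
METAL_RESIDUE_CODES = frozenset(
    {"FE", "FE2", "FES", "FEO", "CU", "CU1", "CUA", "MG",
     "ZN", "MN", "MO", "MOO", "MOS", "NI", "3CO", "CO"}
)

#: Elements counted as "metal atoms of interest" inside those residues
#: (FES clusters also contain inorganic S, which is not a metal atom).
METAL_ELEMENTS = frozenset({"FE", "CU", "ZN", "MN", "MG", "MO", "NI", "CO"})

#: Nominal oxidation state per metal residue code, used to normalize bond
#: valence sums.  Values follow the usual formal charges of the PDB chemical
#: component dictionary for these codes.
METAL_CODE_OXIDATION_STATE = {
    "FE": 3, "FE2": 2, "FES": 3, "FEO": 3,
    "CU": 2, "CU1": 1, "CUA": 2,
    "MG": 2, "ZN": 2, "MN": 2,
    "MO": 6, "MOO": 4, "MOS": 4,
    "NI": 2, "3CO": 3, "CO": 2,
}

STANDARD_AMINO_ACIDS = frozenset(
    {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
     "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}
)

NUCLEOTIDE_CODES = frozenset(
    {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "DI", "I"}
)

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})


class StructureFormatError(ValueError):
    """Raised when a file cannot be parsed as PDB/mmCIF."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no atoms."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str              # upper-case element symbol, e.g. "FE", "C"
    xyz: np.ndarray           # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False

    @property
    def is_metal_code(self) -> bool:
        return self.name in METAL_RESIDUE_CODES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    @property
    def is_nucleotide(self) -> bool:
        return self.name in NUCLEOTIDE_CODES

    @property
    def is_water(self) -> bool:
        return self.name in WATER_CODES

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_number}{self.insertion_code}"

    def alpha_carbon(self) -> Atom | None:
        """CA atom for amino-acid residues, else None."""
        for a in self.atoms:
            if a.name == "CA" and a.element == "C":
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOM_NAMES]

    def backbone_atoms(self) -> list[Atom]:
        return [a for a in self.heavy_atoms() if a.name in BACKBONE_ATOM_NAMES]

    def metal_atoms(self) -> list[Atom]:
        """Metal atoms of interest inside this residue (empty for non-metal codes)."""
        if not self.is_metal_code:
            return []
        return [a for a in self.atoms if a.element in METAL_ELEMENTS]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.vstack([a.xyz for a in atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino_acid or r.is_nucleotide]

    def amino_acid_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino_acid]

    @property
    def n_polymer_residues(self) -> int:
        return len(self.polymer_residues())


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    classification: str | None = None
    molecule_names: dict[str, str] = field(default_factory=dict)   # chain id -> name
    ec_numbers: dict[str, str] = field(default_factory=dict)       # chain id -> EC
    formul_charges: dict[str, int] = field(default_factory=dict)   # residue code -> charge
    deposition_date: _dt.date | None = None
    #: set by the curator when a chain lacks a sequence-database accession
    uniprot_by_chain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution, if present, must be > 0")

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def get_chain(self, chain_id: str) -> Chain | None:
        for chain in self.chains:
            if chain.id == chain_id:
                return chain
        return None

    def metal_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_metal_code]

    def protein_centroid(self) -> np.ndarray:
        """Centroid of amino-acid heavy atoms."""
        coords = [a.xyz for r in self.residues() if r.is_amino_acid
                  for a in r.heavy_atoms()]
        if not coords:
            return np.zeros(3)
        return np.mean(np.vstack(coords), axis=0)

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties broken by altloc letter order."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def _convert_model(st: gemmi.Structure) -> list[Chain]:
    if len(st) == 0:
        raise EmptyStructureError("file contains no model")
    if len(st) > 1:
        logger.warning("file %s has %d models; using model 1 only", st.name, len(st))
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                seq_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name.strip(),
                is_hetero=(gres.het_flag == "H"),
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for gatom in gres:
                by_name.setdefault(gatom.name, []).append(gatom)
            for name, group in by_name.items():
                gatom = _pick_altloc(group)
                res.atoms.append(Atom(
                    name=name,
                    element=gatom.element.name.upper(),
                    xyz=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=gatom.occ,
                    b_factor=gatom.b_iso,
                    is_hetero=res.is_hetero,
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    if not chains:
        raise EmptyStructureError("structure has no atoms")
    return chains


_FORMUL_CHARGE_RE = re.compile(r"(\d+)\s*([+-])")


def _parse_pdb_headers(path: Path, s: Structure) -> None:
    """Scan PDB header records gemmi does not surface uniformly."""
    compnd_text: list[str] = []
    for raw in path.read_text().splitlines():
        record = raw[:6].rstrip()
        if record == "HEADER":
            classification = raw[10:50].strip()
            if classification:
                s.classification = classification
            date_str = raw[50:59].strip()
            if date_str:
                try:
                    s.deposition_date = _dt.datetime.strptime(
                        date_str, "%d-%b-%y").date()
                except ValueError:
                    pass
        elif record == "COMPND":
            compnd_text.append(raw[10:80].rstrip())
        elif record == "FORMUL":
            code = raw[12:16].strip()
            formula = raw[19:70]
            m = _FORMUL_CHARGE_RE.search(formula)
            if code and m:
                charge = int(m.group(1)) * (1 if m.group(2) == "+" else -1)
                s.formul_charges[code] = charge
        elif record in ("ATOM", "HETATM"):
            break
    _parse_compnd("\n".join(compnd_text), s)


def _parse_compnd(text: str, s: Structure) -> None:
    """Extract MOLECULE / EC specifications, assigned to their CHAIN tokens."""
    molecule = None
    ec = None
    # COMPND is a sequence of TOKEN: value; specifications, MOL_ID-delimited
    for spec in re.split(r"MOL_ID:", text):
        molecule = None
        ec = None
        chains: list[str] = []
        for m in re.finditer(r"(MOLECULE|CHAIN|EC):\s*([^;]*)", spec):
            key, value = m.group(1), " ".join(m.group(2).split())
            if key == "MOLECULE":
                molecule = value
            elif key == "EC":
                ec = value
            elif key == "CHAIN":
                chains = [c.strip() for c in value.split(",") if c.strip()]
        for cid in chains:
            if molecule:
                s.molecule_names[cid] = molecule
            if ec:
                s.ec_numbers[cid] = ec


def _parse_mmcif_headers(path: Path, s: Structure) -> None:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    kw = block.find_value("_struct_keywords.pdbx_keywords")
    if kw:
        s.classification = gemmi.cif.as_string(kw)
    date = block.find_value("_pdbx_database_status.recvd_initial_deposition_date")
    if date:
        try:
            s.deposition_date = _dt.date.fromisoformat(gemmi.cif.as_string(date))
        except ValueError:
            pass
    # entity descriptions / EC, joined to chains through label_asym ↔ entity
    names: dict[str, str] = {}
    ecs: dict[str, str] = {}
    for row in block.find("_entity.", ["id", "?pdbx_description", "?pdbx_ec"]):
        eid = row.str(0)
        if row.has(1) and row.str(1) not in ("?", "."):
            names[eid] = row.str(1)
        if row.has(2) and row.str(2) not in ("?", "."):
            ecs[eid] = row.str(2)
    for row in block.find("_struct_asym.", ["id", "entity_id"]):
        cid, eid = row.str(0), row.str(1)
        if eid in names:
            s.molecule_names.setdefault(cid, names[eid])
        if eid in ecs:
            s.ec_numbers.setdefault(cid, ecs[eid])
    # formal charges per component, when provided
    for row in block.find("_chem_comp.", ["id", "?pdbx_formal_charge"]):
        if row.has(1) and row.str(1) not in ("?", "."):
            try:
                charge = int(row.str(1))
            except ValueError:
                continue
            if charge != 0:
                s.formul_charges[row.str(0)] = charge


def read_structure(path: str | Path,
                   dialect: Literal["pdb", "mmcif", "auto"] = "auto") -> Structure:
    """Read a PDB or mmCIF file into the uniform data model.

    Model 1 only; highest-occupancy altloc conformers; header fields left
    ``None`` when the file does not state them.

    Raises
    ------
    StructureFormatError
        when the file does not parse under the named standard.
    EmptyStructureError
        when the file parses but contains no atoms.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {dialect}: {exc}") from exc

    s = Structure(id=(st.name or path.stem).lower())
    s.chains = _convert_model(st)
    if st.resolution and st.resolution > 0:
        s.resolution = float(st.resolution)
    if dialect == "pdb":
        _parse_pdb_headers(path, s)
    else:
        _parse_mmcif_headers(path, s)
    # a parse that yields no recognizable coordinate content is a format error
    if dialect == "pdb" and s.n_atoms == 0:
        raise StructureFormatError(f"{path} contains no coordinate records")
    return s


# ---------------------------------------------------------------------------
# Writing (standard PDB)
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # element symbols of width 2 start in column 13; others in column 14
    if len(element) == 2 or len(name) == 4:
        return f"{name:<4.4s}"
    return f" {name:<3.3s}"


def write_structure(s: Structure, path: str | Path) -> None:
    """Write the structure as a standard PDB file.

    Emits HEADER / COMPND / REMARK 2 / FORMUL records for the metadata the
    model carries, then ATOM/HETATM records at PDB precision (3 decimals).
    """
    path = Path(path)
    lines: list[str] = []
    date = (s.deposition_date or _dt.date(2000, 1, 1)).strftime("%d-%b-%y").upper()
    classification = (s.classification or "UNCLASSIFIED")[:40]
    lines.append(f"HEADER    {classification:<40s}{date:<9s}   {s.id[:4].upper():<4s}")
    mol_id = 0
    compnd: list[str] = []
    for chain in s.chains:
        name = s.molecule_names.get(chain.id)
        if name is None:
            continue
        mol_id += 1
        compnd.append(f"MOL_ID: {mol_id};")
        compnd.append(f"MOLECULE: {name};")
        compnd.append(f"CHAIN: {chain.id};")
        ec = s.ec_numbers.get(chain.id)
        if ec:
            compnd.append(f"EC: {ec};")
    for i, text in enumerate(compnd, start=1):
        cont = "  " if i == 1 else f"{i:>3d}"
        lines.append(f"COMPND {cont} {text:<69s}"[:80])
    if s.resolution is not None:
        lines.append("REMARK   2")
        lines.append(f"REMARK   2 RESOLUTION.    {s.resolution:5.2f} ANGSTROMS.")
    for i, (code, charge) in enumerate(sorted(s.formul_charges.items()), start=2):
        sign = "+" if charge >= 0 else "-"
        lines.append(f"FORMUL  {i:>2d}  {code:<4.4s}   {code:>2.4s} {abs(charge)}{sign}")
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            record = "HETATM" if res.is_hetero else "ATOM  "
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.xyz
                lines.append(
                    f"{record}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f" {res.name:>3.3s} {chain.id[:1]}{res.seq_number:>4d}"
                    f"{res.insertion_code[:1] or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2.2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Structure-level quality gates applied before featurization."""
    max_resolution: float = 3.5          # strictly-greater values are dropped
    max_sites: int = 40                  # structures with more sites are dropped
    min_chain_length: int = 20           # shorter protein chains are dropped
    drop_missing_resolution: bool = False


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)
    dropped_chains: list[str] = field(default_factory=list)


def quality_filter(s: Structure, cfg: FilterConfig | None = None,
                   n_sites: int | None = None) -> tuple[FilterDecision, Structure]:
    """Apply the structure quality gates.

    Returns the decision (with machine-readable reason codes) and the
    possibly chain-reduced structure.  Reason codes: ``resolution``,
    ``missing_resolution``, ``site_count``, ``nucleotide_only``,
    ``no_protein_chain``.

    ``n_sites`` may be supplied by the caller; otherwise metal sites are
    counted with the site finder.
    """
    cfg = cfg or FilterConfig()
    decision = FilterDecision(keep=True)

    if s.resolution is None:
        if cfg.drop_missing_resolution:
            decision.keep = False
            decision.reasons.append("missing_resolution")
        else:
            logger.warning("structure %s has no resolution record; kept", s.id)
    elif s.resolution > cfg.max_resolution:
        decision.keep = False
        decision.reasons.append("resolution")

    if n_sites is None:
        from .sites import find_sites   # deferred: sites depends on this module
        n_sites = len(find_sites(s))
    if n_sites > cfg.max_sites:
        decision.keep = False
        decision.reasons.append("site_count")

    polymer_chains = [c for c in s.chains if c.n_polymer_residues > 0]
    if polymer_chains and all(
            not c.amino_acid_residues() for c in polymer_chains):
        decision.keep = False
        decision.reasons.append("nucleotide_only")

    kept_chains: list[Chain] = []
    for chain in s.chains:
        n_aa = len(chain.amino_acid_residues())
        if 0 < n_aa < cfg.min_chain_length:
            decision.dropped_chains.append(chain.id)
        else:
            kept_chains.append(chain)
    filtered = Structure(
        id=s.id, chains=kept_chains, resolution=s.resolution,
        classification=s.classification,
        molecule_names=dict(s.molecule_names), ec_numbers=dict(s.ec_numbers),
        formul_charges=dict(s.formul_charges),
        deposition_date=s.deposition_date,
        uniprot_by_chain=dict(s.uniprot_by_chain),
    )
    if decision.keep and not any(
            c.amino_acid_residues() for c in filtered.chains):
        decision.keep = False
        decision.reasons.append("no_protein_chain")
    return decision, filtered


# ---------------------------------------------------------------------------
# Enzyme-name evidence
# ---------------------------------------------------------------------------

def token_has_ase_suffix(token: str) -> bool:
    """Case-insensitive "…ase" suffix test on one token (length >= 5)."""
    token = token.strip(".,;:()[]'\"").lower()
    return len(token) >= 5 and token.endswith("ase")


def has_ase_evidence(*texts: str | None) -> bool:
    """Whether any whitespace-delimited token of the texts is an enzyme name
    by the "ase"-suffix heuristic ("transferase" matches; "base" does not)."""
    for text in texts:
        if not text:
            continue
        if any(token_has_ase_suffix(tok) for tok in text.split()):
            return True
    return False
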