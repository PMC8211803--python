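"""Computational labeling of sites and redundancy removal.

Sites are labeled enzymatic / non-enzymatic / discarded by a pure decision
procedure over externally supplied homology evidence — sequence-homology
hits against a curated catalytic-site database (PHMMER-style E-values),
structural alignments (TM-align-style TM-scores with residue
correspondences), and enzyme-name evidence (EC number, "ase"-suffixed
classification or molecule name).  The external search and alignment tools
are consumed as evidence tables through documented adapters, never executed
here, so the logic is exactly testable.

The decision order:

1. homolog at E ≤ 1e-6 AND enzyme-name evidence AND TM-score ≥ 0.40 AND the
   site within 5 Å of an aligned catalytic residue → **enzymatic**;
2. another site on the same chain is enzymatic, this one is not →
   **non-enzymatic**;
3. no homolog hit AND no EC AND no "ase" anywhere → **non-enzymatic**;
4. anything partial → **discarded** (with reason codes).

Redundant sites are removed by local-environment similarity: the Jaccard
index of residue-identity multisets within 3.75 Å (within homology
clusters) or 6.0 Å (across sets); pairs above 0.80 keep one site by the
stated priority order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sites import MetalSite
from .structure import has_ase_evidence

logger = logging.getLogger(__name__)

PHMMER_EVALUE_CUTOFF = 1e-6
TM_SCORE_CUTOFF = 0.40
CATALYTIC_DISTANCE_CUTOFF = 5.0
INTRA_SET_RADIUS = 3.75
CROSS_SET_RADIUS = 6.0
LOCAL_SIMILARITY_CUTOFF = 0.80     # strictly greater is redundant


# ---------------------------------------------------------------------------
# Evidence model
# ---------------------------------------------------------------------------

@dataclass
class TMAlignment:
    entry_id: str
    tm_score: float
    #: catalytic-residue positions of the database entry mapped into the
    #: query structure's coordinates; empty when the alignment is missing
    aligned_catalytic_xyz: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tm_score <= 1.0:
            raise ValueError("TM-score must lie in [0, 1]")


@dataclass
class HomologyEvidence:
    chain_id: str
    hits: list[tuple[str, float]] = field(default_factory=list)   # (entry, E)
    alignments: list[TMAlignment] = field(default_factory=list)
    ec_number: bool = False
    ase_in_classification: bool = False
    ase_in_molecule_name: bool = False

    def __post_init__(self) -> None:
        if any(e < 0 for _, e in self.hits):
            raise ValueError("E-values must be >= 0")

    @property
    def name_evidence(self) -> bool:
        return (self.ec_number or self.ase_in_classification
                or self.ase_in_molecule_name)

    @classmethod
    def from_structure_headers(cls, chain_id: str, classification: str | None,
                               molecule_name: str | None,
                               ec_number: str | None,
                               hits: Sequence[tuple[str, float]] = (),
                               alignments: Sequence[TMAlignment] = (),
                               ) -> "HomologyEvidence":
        return cls(chain_id=chain_id, hits=list(hits),
                   alignments=list(alignments),
                   ec_number=bool(ec_number),
                   ase_in_classification=has_ase_evidence(classification),
                   ase_in_molecule_name=has_ase_evidence(molecule_name))


@dataclass
class SiteLabel:
    site_id: str
    label: str                       # enzymatic | non_enzymatic | discarded
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label == "discarded" and not self.reasons:
            raise ValueError("discarded labels need at least one reason")


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def label_site(site_id: str, site_center: np.ndarray, ev: HomologyEvidence,
               chain_has_enzymatic: bool = False) -> SiteLabel:
    """Terminal label for one site given assembled evidence.

    ``chain_has_enzymatic`` is supplied by the caller after a first labeling
    pass (unlabeled sites on chains with an enzymatic site become
    non-enzymatic).  Every call returns exactly one terminal label; the
    reason trail reconstructs the decision path.
    """
    strong_hits = [(eid, e) for eid, e in ev.hits if e <= PHMMER_EVALUE_CUTOFF]
    if strong_hits and ev.name_evidence:
        good_tm = [a for a in ev.alignments
                   if a.tm_score >= TM_SCORE_CUTOFF
                   and a.entry_id in {eid for eid, _ in strong_hits}]
        missing = [eid for eid, _ in strong_hits
                   if not any(a.entry_id == eid for a in ev.alignments)]
        for aln in good_tm:
            for xyz in aln.aligned_catalytic_xyz:
                d = float(np.linalg.norm(np.asarray(xyz) - site_center))
                if d <= CATALYTIC_DISTANCE_CUTOFF:
                    return SiteLabel(site_id, "enzymatic",
                                     [f"catalytic_residue_within_5A:{aln.entry_id}"])
        if chain_has_enzymatic:
            return SiteLabel(site_id, "non_enzymatic",
                             ["unlabeled_on_enzymatic_chain"])
        if missing:
            return SiteLabel(site_id, "discarded",
                             ["missing_alignment_for_hit"])
        if not good_tm:
            return SiteLabel(site_id, "discarded", ["tm_score_below_cutoff"])
        return SiteLabel(site_id, "discarded", ["no_catalytic_residue_nearby"])
    if chain_has_enzymatic:
        return SiteLabel(site_id, "non_enzymatic",
                         ["unlabeled_on_enzymatic_chain"])
    if not strong_hits and not ev.name_evidence:
        return SiteLabel(site_id, "non_enzymatic", ["no_enzymatic_evidence"])
    reasons = []
    if strong_hits and not ev.name_evidence:
        reasons.append("homolog_without_name_evidence")
    if ev.name_evidence and not strong_hits:
        reasons.append("name_evidence_without_homolog")
    return SiteLabel(site_id, "discarded", reasons)


def label_chain_sites(sites: Sequence[tuple[str, np.ndarray]],
                      ev: HomologyEvidence) -> list[SiteLabel]:
    """Two-pass labeling of all sites on one chain: the first pass finds
    enzymatic sites, the second relabels remaining sites on enzymatic
    chains as non-enzymatic."""
    first = [label_site(sid, center, ev) for sid, center in sites]
    if not any(lab.label == "enzymatic" for lab in first):
        return first
    return [lab if lab.label == "enzymatic"
            else label_site(lab.site_id, center, ev, chain_has_enzymatic=True)
            for lab, (sid, center) in zip(first, sites)]


# ---------------------------------------------------------------------------
# Local site similarity (environment Jaccard)
# ---------------------------------------------------------------------------

def site_environment(site: MetalSite, radius: float) -> list[str]:
    """Residue-identity multiset within ``radius`` of the site center
    (min heavy-atom distance; the site's own metal residues are excluded
    by construction of the residue index)."""
    return sorted(info.residue.name for info in site.residue_index
                  if info.min_heavy_distance <= radius)


def multiset_jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| over residue-identity multisets
    (duplicates counted); two empty environments are identical (J = 1)."""
    from collections import Counter
    ca, cb = Counter(a), Counter(b)
    union = sum((ca | cb).values())
    if union == 0:
        return 1.0
    inter = sum((ca & cb).values())
    return inter / union


def local_site_similarity(site_a: MetalSite, site_b: MetalSite,
                          radius: float = INTRA_SET_RADIUS) -> float:
    return multiset_jaccard(site_environment(site_a, radius),
                            site_environment(site_b, radius))


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

@dataclass
class SitePriority:
    """Keep-priority attributes for redundancy resolution, in the stated
    order: catalytic label, ligand-free, isolated (no other site 5–15 Å),
    mutation-free, then resolution; ties broken lexicographically."""
    site_id: str
    structure_id: str = ""
    is_catalytic: bool = False
    has_other_ligands: bool = True
    has_nearby_sites: bool = True      # another site within 5–15 Å
    has_mutations: bool = True
    resolution: float = 99.0

    def sort_key(self) -> tuple:
        return (not self.is_catalytic, self.has_other_ligands,
                self.has_nearby_sites, self.has_mutations, self.resolution,
                self.structure_id, self.site_id)


def deduplicate(environments: Mapping[str, Sequence[str]],
                clusters: Sequence[Sequence[str]],
                priorities: Mapping[str, SitePriority],
                cutoff: float = LOCAL_SIMILARITY_CUTOFF,
                ) -> tuple[set[str], list[tuple[str, str, float]]]:
    """Remove redundant sites within homology clusters.

    ``environments`` maps site id to its residue-identity multiset at the
    relevant radius; ``clusters`` lists groups of alignable sites.  Within a
    cluster, sites are visited in keep-priority order; a site is removed
    when its environment Jaccard with an already-kept cluster member
    *exceeds* the cutoff (0.80 exactly keeps both).  Returns the kept ids
    and a removal log of (removed, kept_duplicate, similarity).

    The last member of a cluster is never removed, and no kept pair within
    a cluster exceeds the cutoff.
    """
    kept: set[str] = set(environments)
    log: list[tuple[str, str, float]] = []
    for cluster in clusters:
        members = [sid for sid in cluster if sid in environments]
        members.sort(key=lambda sid: priorities[sid].sort_key()
                     if sid in priorities else (True, True, True, True,
                                                99.0, "", sid))
        cluster_kept: list[str] = []
        for sid in members:
            duplicate_of = None
            best = 0.0
            for other in cluster_kept:
                j = multiset_jaccard(environments[sid], environments[other])
                if j > cutoff and j >= best:
                    duplicate_of, best = other, j
            if duplicate_of is None:
                cluster_kept.append(sid)
            else:
                kept.discard(sid)
                log.append((sid, duplicate_of, best))
    return kept, log


def cross_set_deduplicate(env_a: Mapping[str, Sequence[str]],
                          env_b: Mapping[str, Sequence[str]],
                          pairs: Sequence[tuple[str, str]],
                          cutoff: float = LOCAL_SIMILARITY_CUTOFF,
                          ) -> tuple[set[str], list[tuple[str, str, float]]]:
    """Cross-set removal (test-set leakage control): for each candidate
    pair (a from set A kept, b from set B), remove b when the 6 Å
    environment Jaccard exceeds the cutoff."""
    removed: set[str] = set()
    log = []
    for a, b in pairs:
        if a not in env_a or b not in env_b or b in removed:
            continue
        j = multiset_jaccard(env_a[a], env_b[b])
        if j > cutoff:
            removed.add(b)
            log.append((b, a, j))
    return set(env_b) - removed, log


# ---------------------------------------------------------------------------
# Special filters
# ---------------------------------------------------------------------------

NUCLEIC_PHOSPHATE_CUTOFF = 10.0
RELAXATION_MOVEMENT_CUTOFF = 3.0


def special_filters(sites: Sequence[MetalSite],
                    labels: Mapping[str, str],
                    phosphate_xyz: Sequence[np.ndarray] = (),
                    metal_displacement: Mapping[str, float] | None = None,
                    ) -> tuple[list[MetalSite], list[tuple[str, str]]]:
    """Post-labeling removals.

    * NTPase rule: non-enzymatic Mg sites within 10 Å of a nucleic-acid
      phosphate ligand are removed (enzymatic Mg sites are kept).
    * Loose-metal rule: sites whose metal moved more than 3 Å between two
      supplied coordinate sets (pre/post structure relaxation,
      superposition already applied) are removed.
    """
    metal_displacement = metal_displacement or {}
    kept = []
    removed: list[tuple[str, str]] = []
    for site in sites:
        if labels.get(site.site_id) == "non_enzymatic" \
                and "MG" in site.metal_elements and len(phosphate_xyz):
            d = min(float(np.linalg.norm(np.asarray(p) - site.center))
                    for p in phosphate_xyz)
            if d <= NUCLEIC_PHOSPHATE_CUTOFF:
                removed.append((site.site_id, "mg_near_nucleic_phosphate"))
                continue
        move = metal_displacement.get(site.site_id)
        if move is not None and move > RELAXATION_MOVEMENT_CUTOFF:
            removed.append((site.site_id, "metal_moved_during_relaxation"))
            continue
        kept.append(site)
    return kept, removed
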