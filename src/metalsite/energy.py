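"""Per-residue energy-term tables and their shell/sphere aggregation.

Per-residue score tables (Rosetta per-residue scorefile dialect: a header
line of term names, one row per residue, pose-total rows ignored) are inputs
— the energy function itself is never evaluated here.  Each of the 21 terms
of the default schema is aggregated per site as the sum or the mean over the
residues of each distance region, for both region modes, giving 84 features
per (statistic, mode) method.  Across all four methods the distinct feature
identifiers number 294, because the first shell and the first sphere are the
same region.

Empty regions contribute 0 for both sum and mean, keeping feature vectors
dense for downstream scaling.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .sites import MetalSite, RegionSpec, residues_in_region

logger = logging.getLogger(__name__)

DEFAULT_N_TERMS = 21

#: the per-residue score terms of the beta-generation Rosetta energy function
DEFAULT_TERM_SCHEMA = (
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_atr_xover4", "fa_intra_rep_xover4",
    "fa_intra_sol_xover4", "lk_ball", "lk_ball_iso", "lk_ball_bridge",
    "lk_ball_bridge_uncpl", "fa_elec", "fa_intra_elec", "pro_close",
    "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc", "dslf_fa13",
    "rama_prepro", "omega", "fa_dun",
)


class EnergyTableError(ValueError):
    """Malformed per-residue energy table."""


@dataclass
class EnergyTable:
    """Rows keyed by (chain, residue number); one numeric column per term."""
    values: pd.DataFrame            # index: MultiIndex (chain, resnum)

    @property
    def terms(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_terms(self) -> int:
        return len(self.values.columns)

    def lookup(self, chain: str, resnum: int) -> pd.Series | None:
        key = (chain, resnum)
        if key in self.values.index:
            return self.values.loc[key]
        return None


_LABEL_RE = re.compile(r"^(?:[A-Z0-9]{3}[:_])?([A-Za-z0-9])[:_]?(-?\d+)$")


def _parse_residue_label(label: str) -> tuple[str, int]:
    """Parse residue labels like ``A_12``, ``HIS:A:12`` or ``A:12``."""
    label = label.strip()
    m = _LABEL_RE.match(label)
    if m:
        return m.group(1), int(m.group(2))
    parts = re.split(r"[:_]", label)
    if len(parts) >= 2:
        try:
            return parts[-2], int(parts[-1])
        except ValueError:
            pass
    raise EnergyTableError(f"cannot parse residue label {label!r}")


def read_energy_table(path: str | Path | io.TextIOBase) -> EnergyTable:
    """Read a whitespace/tab-delimited per-residue energy table.

    The first column holds the residue label; remaining columns are numeric
    terms.  Leading ``SCORE:`` tokens and pose-total rows (labels containing
    ``pose``) are ignored.  Tables with other than 21 terms are accepted with
    a warning (feature counts downstream scale as 4 x n_terms).

    Raises :class:`EnergyTableError` on duplicate residue labels or
    non-numeric cells.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and
             not ln.lstrip().startswith("#")]
    if not lines:
        raise EnergyTableError("empty energy table")
    rows = [ln.split() for ln in lines]
    # tolerate a Rosetta-style leading "SCORE:" token
    rows = [(r[1:] if r and r[0].rstrip(":").upper() == "SCORE" else r)
            for r in rows]
    header = rows[0]
    label_col, terms = header[0], header[1:]
    if not terms:
        raise EnergyTableError("no term columns found")
    data: dict[tuple[str, int], list[float]] = {}
    for r in rows[1:]:
        if not r or "pose" in r[0].lower():
            continue
        if len(r) != len(terms) + 1:
            raise EnergyTableError(
                f"row {r[0]!r} has {len(r) - 1} values, expected {len(terms)}")
        key = _parse_residue_label(r[0])
        if key in data:
            raise EnergyTableError(f"duplicate residue label {r[0]!r}")
        try:
            data[key] = [float(v) for v in r[1:]]
        except ValueError as exc:
            raise EnergyTableError(f"non-numeric cell in row {r[0]!r}") from exc
    if len(terms) != DEFAULT_N_TERMS:
        logger.warning("energy table %r has %d terms (default schema has %d)",
                       label_col, len(terms), DEFAULT_N_TERMS)
    index = pd.MultiIndex.from_tuples(data.keys(), names=["chain", "resnum"])
    df = pd.DataFrame(list(data.values()), index=index, columns=terms)
    return EnergyTable(values=df)


def region_feature_name(term: str, stat: str, mode: str, k: int) -> str:
    """Canonical feature identifier ``<term>_<stat>_<mode><k>``.

    The first shell equals the first sphere, so both (stat, shell, 1) and
    (stat, sphere, 1) map to the shared ``..._sphere1`` name.
    """
    if k == 1:
        mode = "sphere"
    return f"{term}_{stat}_{mode}{k}"


@dataclass
class RosettaFeatureGroup:
    stat: Literal["mean", "sum"]
    mode: Literal["shell", "sphere"]
    features: dict[str, float]

    @property
    def method(self) -> str:
        return f"{self.stat}_{self.mode}"


def aggregate(site: MetalSite, table: EnergyTable,
              stat: Literal["mean", "sum"],
              mode: Literal["shell", "sphere"],
              cutoffs: tuple[float, ...] | None = None) -> RosettaFeatureGroup:
    """Aggregate per-residue terms over the site's distance regions.

    Region membership uses the closest-heavy-atom distance rule.  Residues
    present in the structure but absent from the table are treated as absent
    from every region (with a warning).  Empty regions give 0 for both
    statistics.
    """
    region = RegionSpec(mode=mode,
                        cutoffs=cutoffs or RegionSpec().cutoffs)
    features: dict[str, float] = {}
    warned = False
    for k in range(1, region.n_regions + 1):
        members = residues_in_region(site, region, k, "closest-heavy-atom")
        values = []
        for res in members:
            row = table.lookup(res.chain_id, res.seq_number)
            if row is None:
                if not warned:
                    logger.warning("site %s: residue %s missing from energy "
                                   "table; treated as absent", site.site_id,
                                   res.label)
                    warned = True
                continue
            values.append(row.to_numpy(dtype=float))
        for j, term in enumerate(table.terms):
            name = region_feature_name(term, stat, mode, k)
            if not values:
                features[name] = 0.0
            else:
                col = np.array([v[j] for v in values])
                features[name] = float(col.sum() if stat == "sum"
                                       else col.mean())
    return RosettaFeatureGroup(stat=stat, mode=mode, features=features)


def aggregate_all_methods(site: MetalSite, table: EnergyTable,
                          ) -> dict[str, RosettaFeatureGroup]:
    """All four (stat, mode) aggregation methods for one site."""
    out = {}
    for stat in ("mean", "sum"):
        for mode in ("shell", "sphere"):
            grp = aggregate(site, table, stat, mode)  # type: ignore[arg-type]
            out[grp.method] = grp
    return out
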