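"""Canonical feature schema across the five feature categories.

Feature names carry category prefixes so feature-set configurations can
select by prefix: ``ros_`` (energy terms), ``pok_`` (pocket void), ``lin_``
(pocket lining), ``ele_`` (electrostatics), ``geo_`` (coordination
geometry).

Energy-term features are named ``ros_<term>_<stat>_<mode><k>`` for the four
aggregation methods (mean/sum × shell/sphere over four cutoffs).  Each
method contributes 21 × 4 = 84 features; because the first shell and the
first sphere are the same region, the union over all four methods has
294 distinct identifiers (for the default 21-term schema).  The four
methods are mutually exclusive within any one feature set.

A few electrostatics slots whose exact definition is not pinned down from
first principles are computed but flagged ``provisional`` and excluded from
the default training schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .energy import DEFAULT_TERM_SCHEMA, region_feature_name

ROSETTA_METHODS = ("mean_shell", "mean_sphere", "sum_shell", "sum_sphere")
CATEGORY_PREFIXES = {"rosetta": "ros_", "pocket_void": "pok_",
                     "pocket_lining": "lin_", "electrostatics": "ele_",
                     "geometry": "geo_"}


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str
    provisional: bool = False


def rosetta_feature_names(method: str,
                          terms: Sequence[str] = DEFAULT_TERM_SCHEMA,
                          n_regions: int = 4) -> list[str]:
    """The 4 × n_terms identifiers of one aggregation method."""
    stat, mode = method.split("_")
    return [f"ros_{region_feature_name(term, stat, mode, k)}"
            for k in range(1, n_regions + 1) for term in terms]


def rosetta_unique_names(terms: Sequence[str] = DEFAULT_TERM_SCHEMA,
                         n_regions: int = 4) -> list[str]:
    """Distinct identifiers across all four methods (294 for 21 terms)."""
    seen: dict[str, None] = {}
    for method in ROSETTA_METHODS:
        for name in rosetta_feature_names(method, terms, n_regions):
            seen.setdefault(name)
    return list(seen)


def pocket_void_names() -> list[str]:
    names = ["pok_volume", "pok_depth", "pok_cityblock_to_opening",
             "pok_centroid_offset"]
    for band in ("bottom", "middle", "top"):
        names += [f"pok_{band}_farthest", f"pok_{band}_hull_area",
                  f"pok_{band}_ellipse_offset", f"pok_{band}_ellipse_r_major",
                  f"pok_{band}_ellipse_r_minor"]
    return names


def pocket_lining_names() -> list[str]:
    names = []
    for scale in ("eisenberg", "kd"):
        names += [f"lin_{scale}_{stat}"
                  for stat in ("mean", "min", "max", "skew", "sd")]
    names += ["lin_n_backbone", "lin_n_sidechain", "lin_occluding_volume",
              "lin_volume_no_sidechains", "lin_lj_volume_occupied",
              "lin_wall_sasa"]
    return names


def electrostatics_names(include_provisional: bool = False
                         ) -> list[str]:
    names = []
    for shell in ("inside", "outside"):
        for moment in ("mu2", "mu3", "mu4"):
            names += [f"ele_{shell}_{moment}_mean", f"ele_{shell}_{moment}_max"]
        names += [f"ele_{shell}_dpka_min", f"ele_{shell}_dpka_max",
                  f"ele_{shell}_residual_mean", f"ele_{shell}_residual_max"]
        for rank in ("destab", "stab"):
            names += [f"ele_{shell}_{rank}_mean", f"ele_{shell}_{rank}_max"]
    names += ["ele_env_mu2", "ele_env_mu3", "ele_env_mu4",
              "ele_env_destab", "ele_env_stab"]
    if include_provisional:
        names += provisional_electrostatics_names()
    return names


def provisional_electrostatics_names() -> list[str]:
    return ["ele_env_dpka", "ele_env_residual",
            "ele_inside_n_ionizable", "ele_outside_n_ionizable"]


def geometry_names() -> list[str]:
    names = ["geo_cn_total", "geo_cn_mean", "geo_vacancy", "geo_regularity",
             "geo_n_coord_total", "geo_n_coord_mean", "geo_site_charge",
             "geo_angdev_sum", "geo_angdev_max", "geo_bond_valence",
             "geo_norm_bond_valence"]
    for element in ("n", "o", "s", "other"):
        names += [f"geo_n_{element}_total", f"geo_n_{element}_mean"]
    return names


@dataclass
class FeatureRegistry:
    """The full named feature schema for one Rosetta aggregation method."""
    rosetta_method: str = "mean_sphere"
    terms: tuple[str, ...] = DEFAULT_TERM_SCHEMA
    include_provisional: bool = False
    defs: list[FeatureDef] = field(init=False)

    def __post_init__(self) -> None:
        if self.rosetta_method not in ROSETTA_METHODS:
            raise ValueError(f"unknown aggregation method "
                             f"{self.rosetta_method!r}")
        defs = [FeatureDef(n, "rosetta")
                for n in rosetta_feature_names(self.rosetta_method,
                                               self.terms)]
        defs += [FeatureDef(n, "pocket_void") for n in pocket_void_names()]
        defs += [FeatureDef(n, "pocket_lining")
                 for n in pocket_lining_names()]
        defs += [FeatureDef(n, "electrostatics")
                 for n in electrostatics_names()]
        if self.include_provisional:
            defs += [FeatureDef(n, "electrostatics", provisional=True)
                     for n in provisional_electrostatics_names()]
        defs += [FeatureDef(n, "geometry") for n in geometry_names()]
        self.defs = defs

    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def by_category(self, category: str) -> list[str]:
        return [d.name for d in self.defs if d.category == category]

    def select(self, prefixes: Iterable[str]) -> list[str]:
        prefixes = tuple(prefixes)
        return [d.name for d in self.defs if d.name.startswith(prefixes)]


def validate_feature_set(names: Sequence[str]) -> None:
    """Reject feature sets mixing Rosetta aggregation methods.

    The four aggregation-method groups are never included together in one
    model; names from more than one ``<stat>_<mode>`` family (beyond the
    shared first-region ``sphere1`` identifiers) raise ``ValueError``.
    """
    stats = set()
    families = set()
    for name in names:
        if not name.startswith("ros_"):
            continue
        parts = name.rsplit("_", 2)
        if len(parts) != 3:
            continue
        stat, region = parts[1], parts[2]
        stats.add(stat)
        mode = region.rstrip("0123456789")
        k = region[len(mode):]
        if mode == "sphere" and k == "1":
            continue    # shared first region belongs to both region modes
        families.add((stat, mode))
    if len(stats) > 1 or len(families) > 1:
        raise ValueError(
            "feature set mixes Rosetta aggregation methods: "
            f"{sorted(families) or sorted(stats)}")
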