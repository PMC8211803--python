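"""End-to-end per-site featurization: one row per metal site, columns per
the registry schema (``ros_``/``pok_``/``lin_``/``ele_``/``geo_`` prefixes).
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from . import energy as energy_mod
from . import geometry as geometry_mod
from . import pocket as pocket_mod
from . import titration as titration_mod
from .registry import FeatureRegistry
from .sites import MetalSite, find_sites
from .structure import Structure

logger = logging.getLogger(__name__)


def featurize_site(s: Structure, site: MetalSite,
                   energy_table: energy_mod.EnergyTable | None = None,
                   rosetta_method: str = "mean_sphere",
                   pocket_cfg: pocket_mod.PocketConfig | None = None,
                   titration_cfg: titration_mod.TitrationConfig | None = None,
                   curves: Sequence[titration_mod.TitrationCurve] | None = None,
                   registry: FeatureRegistry | None = None) -> dict[str, float]:
    """All five feature categories for one site, keyed by registry name.

    Without an energy table the energy-term features are zero (with a
    warning); titration curves are solved on demand unless supplied (e.g.
    read from a precomputed table).
    """
    registry = registry or FeatureRegistry(rosetta_method=rosetta_method)
    features: dict[str, float] = {name: 0.0 for name in registry.names()}

    if energy_table is not None:
        stat, mode = rosetta_method.split("_")
        group = energy_mod.aggregate(site, energy_table, stat, mode)
        for name, value in group.features.items():
            key = f"ros_{name}"
            if key in features:
                features[key] = value
    else:
        logger.warning("site %s: no energy table; energy-term features "
                       "left at 0", site.site_id)

    grid = pocket_mod.build_pocket(site, s, pocket_cfg)
    for name, value in pocket_mod.void_features(grid).as_dict().items():
        if name in features:
            features[name] = value
    lining = pocket_mod.lining_features(grid, s, site, pocket_cfg)
    for name, value in lining.as_dict().items():
        if name in features:
            features[name] = value

    if curves is None:
        curves = titration_mod.solve_titration(s, titration_cfg)
    scalars = titration_mod.electro_scalars(curves, titration_cfg)
    electro = titration_mod.electro_features(site, curves, scalars,
                                             titration_cfg)
    for name, value in electro.features.items():
        if name in features:
            features[name] = value

    coord = geometry_mod.coord_features(site, s)
    for name, value in coord.features.items():
        if name in features:
            features[name] = value
    return features


def featurize_structure(s: Structure,
                        sites: Sequence[MetalSite] | None = None,
                        energy_table: energy_mod.EnergyTable | None = None,
                        rosetta_method: str = "mean_sphere",
                        pocket_cfg: pocket_mod.PocketConfig | None = None,
                        titration_cfg: titration_mod.TitrationConfig | None = None,
                        ) -> pd.DataFrame:
    """Feature table over all (or the given) sites of one structure."""
    if sites is None:
        sites = find_sites(s)
    registry = FeatureRegistry(rosetta_method=rosetta_method)
    curves = titration_mod.solve_titration(s, titration_cfg)
    rows = []
    for site in sites:
        row = featurize_site(s, site, energy_table, rosetta_method,
                             pocket_cfg, titration_cfg, curves, registry)
        rows.append(pd.Series(row, name=site.site_id))
    if not rows:
        return pd.DataFrame(columns=registry.names())
    return pd.DataFrame(rows)
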