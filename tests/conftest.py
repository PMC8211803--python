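"""Shared fixtures: synthetic structures and their derived objects.

Expensive constructions (cavity grids, solved titration curves) are session
scoped; everything is generated programmatically from the fixtures module.
"""

import numpy as np
import pytest

from metalsite.fixtures import FixtureSpec, make_structure
from metalsite.pocket import build_pocket
from metalsite.sites import MetalSite, find_sites


@pytest.fixture(scope="session")
def zinc_structure():
    return make_structure(FixtureSpec("zinc_tetrahedral_pocket"))


@pytest.fixture(scope="session")
def zinc_site(zinc_structure):
    sites = find_sites(zinc_structure)
    assert len(sites) == 1
    return sites[0]


@pytest.fixture(scope="session")
def zinc_pocket(zinc_structure, zinc_site):
    return build_pocket(zinc_site, zinc_structure)


@pytest.fixture(scope="session")
def hemisphere_structure():
    return make_structure(FixtureSpec("hemisphere_cavity"))


@pytest.fixture(scope="session")
def hemisphere_pocket(hemisphere_structure):
    site = find_sites(hemisphere_structure)[0]
    return build_pocket(site, hemisphere_structure)


def make_site(center, metal_coords=None, metal_elements=None,
              residue_index=()):
    """Minimal MetalSite for unit tests that do not need a structure."""
    center = np.asarray(center, dtype=float)
    coords = (np.asarray(metal_coords, dtype=float)
              if metal_coords is not None else center[None, :])
    elements = metal_elements or ["ZN"] * len(coords)
    return MetalSite(site_id="test_site", structure_id="test",
                     chain_id="A", metal_elements=list(elements),
                     metal_coords=coords, metal_residue_codes=["ZN"],
                     center=center, residue_index=list(residue_index))
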