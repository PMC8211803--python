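"""Coordination geometry matching, bond valence and site features."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from metalsite import geometry as G
from metalsite.fixtures import FixtureSpec, make_structure
from metalsite.sites import find_sites
from metalsite.structure import Atom, Chain, Residue, Structure


LIB = G.default_library()


class TestLibrary:
    def test_exactly_36_entries(self):
        assert len(LIB) == 36
        assert len({e.name for e in LIB.entries}) == 36

    def test_unit_vertices_and_cn_range(self):
        for entry in LIB.entries:
            norms = np.linalg.norm(entry.vertices, axis=1)
            assert np.allclose(norms, 1.0, atol=1e-9)
            assert 2 <= entry.coordination_number <= 9
            assert entry.coordination_number == len(entry.vertices)

    def test_vacancy_lineage_points_to_real_parent(self):
        names = {e.name for e in LIB.entries}
        vacant = [e for e in LIB.entries if e.is_vacant]
        assert vacant
        for entry in vacant:
            assert entry.vacancy_parent in names
            parent = LIB.get(entry.vacancy_parent)
            assert parent.coordination_number == \
                entry.coordination_number + 1

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "library.json"
        LIB.to_json(path)
        loaded = G.GeometryLibrary.from_json(path)
        assert len(loaded) == 36
        for a, b in zip(LIB.entries, loaded.entries):
            assert a.name == b.name
            assert np.allclose(a.vertices, b.vertices, atol=1e-5)


def brute_force_best_entry(vectors):
    """Independent oracle: exhaustive RMSD over every library entry of the
    matching coordination number (permutations + Kabsch)."""
    obs = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    best_name, best_rmsd = None, np.inf
    for entry in LIB.by_cn(len(obs)):
        for perm in itertools.permutations(range(len(obs))):
            rot, rssd = Rotation.align_vectors(obs, entry.vertices[list(perm)])
            rmsd = rssd / math.sqrt(len(obs))
            if rmsd < best_rmsd:
                best_name, best_rmsd = entry.name, rmsd
    return best_name, best_rmsd


class TestClassify:
    @pytest.mark.parametrize("name", ["tetrahedron", "octahedron",
                                      "square_planar", "trigonal_bipyramid"])
    def test_library_self_match(self, name):
        entry = LIB.get(name)
        match = G.classify_geometry(entry.vertices)
        assert match.name == name
        assert match.rmsd < 1e-6
        assert match.regularity == "regular"
        assert match.angular_deviation_sum == pytest.approx(0.0, abs=1e-4)
        assert match.max_angle_deviation == pytest.approx(0.0, abs=1e-4)

    def test_octahedron_minus_vertex_is_vacant_cn5(self):
        vectors = G.default_library().get("octahedron").vertices[:5]
        match = G.classify_geometry(vectors)
        oracle_name, oracle_rmsd = brute_force_best_entry(vectors)
        assert match.name == oracle_name
        assert match.rmsd == pytest.approx(oracle_rmsd, abs=1e-9)
        assert match.coordination_number == 5
        assert match.vacancy
        assert LIB.get(match.name).vacancy_parent == "octahedron"

    def test_perturbed_tetrahedron_keeps_name(self):
        verts = LIB.get("tetrahedron").vertices.copy()
        rot15 = Rotation.from_rotvec(np.radians(15) * np.array([0, 1, 0]))
        verts[0] = rot15.apply(verts[0])
        match = G.classify_geometry(verts)
        assert match.name == "tetrahedron"
        assert match.rmsd > 0
        assert match.regularity in ("regular", "distorted")
        assert match.max_angle_deviation > 5.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        verts = LIB.get("square_pyramid").vertices
        base = G.classify_geometry(verts)
        for _ in range(3):
            rot = Rotation.random(random_state=rng)
            match = G.classify_geometry(rot.apply(verts))
            assert match.name == base.name
            assert abs(match.rmsd - base.rmsd) < 1e-6

    def test_high_cn_iterative_path_self_match(self):
        for name in ("cube", "tricapped_trigonal_prism"):
            entry = LIB.get(name)
            match = G.classify_geometry(entry.vertices)
            assert match.name == name
            assert match.rmsd < 1e-6

    def test_single_vector_undetermined(self):
        match = G.classify_geometry(np.array([[0.0, 0.0, 1.0]]))
        assert match.name == "undetermined"
        assert match.regularity == "undetermined"


class TestBondValence:
    def _donor(self, element, d):
        return G.CoordinatingAtom(element=element,
                                  xyz=np.array([d, 0.0, 0.0]),
                                  distance=d, residue_name="HIS")

    def test_donor_at_r0_contributes_one(self):
        r0 = G.R0_TABLE["ZN"]["N"]
        bv, _ = G.bond_valence([self._donor("N", r0)], "ZN", 2)
        assert bv == pytest.approx(1.0)

    def test_donor_at_r0_plus_b(self):
        r0 = G.R0_TABLE["ZN"]["O"]
        bv, _ = G.bond_valence([self._donor("O", r0 + 0.37)], "ZN", 2)
        assert bv == pytest.approx(math.exp(-1), abs=1e-9)

    def test_normalization_by_oxidation_state(self):
        # two donors each contributing exactly 1 -> bv 2, Zn(2+) -> nbv 1
        r0 = G.R0_TABLE["ZN"]["N"]
        donors = [self._donor("N", r0), self._donor("N", r0)]
        bv, nbv = G.bond_valence(donors, "ZN", 2)
        assert bv == pytest.approx(2.0)
        assert nbv == pytest.approx(1.0)

    def test_unknown_pair_falls_back_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            bv, _ = G.bond_valence([self._donor("SE", 1.8)], "ZN", 2)
        assert bv == pytest.approx(1.0)    # generic R0 = 1.8 at d = 1.8
        assert any("R0" in r.message for r in caplog.records)


class TestCoordinatingAtoms:
    def test_zinc_fixture_donor_census(self, zinc_structure, zinc_site):
        atoms = G.coordinating_atoms(zinc_site.center, zinc_structure)
        by_element = {}
        for a in atoms:
            by_element[a.element] = by_element.get(a.element, 0) + 1
        assert by_element == {"N": 2, "S": 2}
        assert all(a.distance == pytest.approx(2.1, abs=1e-6) for a in atoms)

    def test_candidate_beyond_cutoff_excluded(self):
        ch = Chain(id="A", residues=[Residue("A", 1, "HIS", atoms=[
            Atom("ND1", "N", [3.0, 0, 0])])])
        s = Structure(id="x", chains=[ch])
        assert G.coordinating_atoms(np.zeros(3), s) == []

    def test_water_oxygen_counts(self):
        ch = Chain(id="A", residues=[Residue("A", 1, "HOH", atoms=[
            Atom("O", "O", [2.3, 0, 0])], is_hetero=True)])
        s = Structure(id="x", chains=[ch])
        atoms = G.coordinating_atoms(np.zeros(3), s)
        assert len(atoms) == 1 and atoms[0].element == "O"

    def test_carbon_and_metal_cluster_atoms_excluded(self):
        ch = Chain(id="A", residues=[
            Residue("A", 1, "ALA", atoms=[Atom("CB", "C", [2.0, 0, 0])]),
            Residue("A", 2, "FES", is_hetero=True, atoms=[
                Atom("FE1", "FE", [0, 0, 0], is_hetero=True),
                Atom("S1", "S", [2.2, 0, 0], is_hetero=True)]),
        ])
        s = Structure(id="x", chains=[ch])
        assert G.coordinating_atoms(np.zeros(3), s) == []


class TestSiteFeatures:
    def test_zinc_site_features(self, zinc_structure, zinc_site):
        cf = G.coord_features(zinc_site, zinc_structure)
        f = cf.features
        assert f["geo_cn_total"] == 4.0
        assert f["geo_n_n_total"] == 2.0 and f["geo_n_s_total"] == 2.0
        assert f["geo_n_coord_total"] == 4.0
        assert f["geo_vacancy"] == 0.0
        assert f["geo_regularity"] == 0.0      # regular
        assert f["geo_site_charge"] == 2.0      # FORMUL ZN 2+
        assert f["geo_angdev_sum"] == pytest.approx(0.0, abs=1e-3)
        assert cf.matches[0].name == "tetrahedron"

    def test_count_consistency_n_o_s_other(self, zinc_structure, zinc_site):
        f = G.coord_features(zinc_site, zinc_structure).features
        total = sum(f[f"geo_n_{e}_total"] for e in ("n", "o", "s", "other"))
        assert total == f["geo_n_coord_total"]

    def test_per_metal_means_times_n_metals(self):
        s = make_structure(FixtureSpec("dinuclear_site"))
        site = find_sites(s)[0]
        assert site.n_metals == 2
        f = G.coord_features(site, s).features
        for key in ("geo_cn", "geo_n_coord", "geo_n_n", "geo_n_o",
                    "geo_n_s", "geo_n_other"):
            assert f[f"{key}_mean"] * 2 == pytest.approx(f[f"{key}_total"])

    def test_geometry_onehot_excluded_from_registry(self, zinc_structure,
                                                    zinc_site):
        from metalsite.registry import FeatureRegistry
        cf = G.coord_features(zinc_site, zinc_structure)
        onehot = cf.geometry_onehot()
        assert len(onehot) == 36
        assert onehot["geoname_tetrahedron"] == 1.0
        assert not set(onehot) & set(FeatureRegistry().names())
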