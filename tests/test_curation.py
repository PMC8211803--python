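"""Labeling decision procedure, environment Jaccard and deduplication."""

import itertools

import numpy as np
import pytest

from metalsite import curation as C


def _evidence(evalue=None, tm=None, cat_xyz=(), ec=False, ase_class=False,
              ase_mol=False):
    hits = [("M0001", evalue)] if evalue is not None else []
    alignments = []
    if tm is not None:
        alignments = [C.TMAlignment(
            "M0001", tm, [np.asarray(x, float) for x in cat_xyz])]
    return C.HomologyEvidence(chain_id="A", hits=hits, alignments=alignments,
                              ec_number=ec, ase_in_classification=ase_class,
                              ase_in_molecule_name=ase_mol)


CENTER = np.zeros(3)


class TestLabelSite:
    def test_all_gates_pass_is_enzymatic(self):
        ev = _evidence(evalue=1e-7, tm=0.45, cat_xyz=[[3.0, 0, 0]], ec=True)
        lab = C.label_site("s1", CENTER, ev)
        assert lab.label == "enzymatic"

    def test_tm_below_cutoff_is_discarded(self):
        ev = _evidence(evalue=1e-7, tm=0.35, cat_xyz=[[3.0, 0, 0]], ec=True)
        lab = C.label_site("s1", CENTER, ev)
        assert lab.label == "discarded"
        assert "tm_score_below_cutoff" in lab.reasons

    def test_no_evidence_at_all_is_non_enzymatic(self):
        lab = C.label_site("s1", CENTER, _evidence())
        assert lab.label == "non_enzymatic"
        assert "no_enzymatic_evidence" in lab.reasons

    def test_homolog_without_name_evidence_discarded(self):
        ev = _evidence(evalue=1e-8, tm=0.9, cat_xyz=[[1.0, 0, 0]])
        lab = C.label_site("s1", CENTER, ev)
        assert lab.label == "discarded"
        assert "homolog_without_name_evidence" in lab.reasons

    def test_name_evidence_without_homolog_discarded(self):
        lab = C.label_site("s1", CENTER, _evidence(ec=True))
        assert lab.label == "discarded"
        assert "name_evidence_without_homolog" in lab.reasons

    def test_weak_evalue_does_not_count_as_hit(self):
        # E above the cutoff is no homology evidence at all
        ev = _evidence(evalue=1e-3)
        lab = C.label_site("s1", CENTER, ev)
        assert lab.label == "non_enzymatic"

    def test_missing_alignment_for_strong_hit_discarded(self):
        ev = C.HomologyEvidence(chain_id="A", hits=[("M0001", 1e-9)],
                                ec_number=True)
        lab = C.label_site("s1", CENTER, ev)
        assert lab.label == "discarded"
        assert "missing_alignment_for_hit" in lab.reasons

    def test_catalytic_residue_too_far_discarded(self):
        ev = _evidence(evalue=1e-7, tm=0.8, cat_xyz=[[7.0, 0, 0]], ec=True)
        lab = C.label_site("s1", CENTER, ev)
        assert lab.label == "discarded"
        assert "no_catalytic_residue_nearby" in lab.reasons

    def test_unlabeled_site_on_enzymatic_chain_is_non_enzymatic(self):
        ev = _evidence(evalue=1e-7, tm=0.8, cat_xyz=[[1.0, 0, 0]], ec=True)
        sites = [("s1", np.zeros(3)), ("s2", np.array([30.0, 0, 0]))]
        labels = {lab.site_id: lab.label
                  for lab in C.label_chain_sites(sites, ev)}
        assert labels == {"s1": "enzymatic", "s2": "non_enzymatic"}

    def test_every_evidence_combination_reaches_a_terminal_label(self):
        # the decision procedure is total over the evidence space
        for evalue, tm, near, ec in itertools.product(
                (None, 1e-7, 1e-3), (None, 0.9, 0.2), (True, False),
                (True, False)):
            cat = [[1.0, 0, 0]] if near else [[20.0, 0, 0]]
            ev = _evidence(evalue=evalue, tm=tm, cat_xyz=cat, ec=ec)
            lab = C.label_site("s", CENTER, ev)
            assert lab.label in ("enzymatic", "non_enzymatic", "discarded")
            if lab.label == "discarded":
                assert lab.reasons


class TestEnvironmentJaccard:
    def test_identical_environments(self):
        assert C.multiset_jaccard(["HIS", "ASP"], ["HIS", "ASP"]) == 1.0

    def test_multiset_counting(self):
        j = C.multiset_jaccard(["HIS", "HIS", "ASP"], ["HIS", "ASP", "GLU"])
        assert j == pytest.approx(0.5)     # |∩| = 2, |∪| = 4

    def test_disjoint(self):
        assert C.multiset_jaccard(["HIS"], ["GLU"]) == 0.0

    def test_both_empty_defined_as_identical(self):
        assert C.multiset_jaccard([], []) == 1.0


class TestDeduplicate:
    def _priorities(self, **overrides):
        base = {
            "a": C.SitePriority("a", is_catalytic=True),
            "b": C.SitePriority("b"),
            "c": C.SitePriority("c"),
        }
        base.update(overrides)
        return base

    def test_catalytic_site_kept(self):
        env = {"a": ["HIS", "ASP"], "b": ["HIS", "ASP"]}
        kept, log = C.deduplicate(env, [["a", "b"]], self._priorities())
        assert kept == {"a"}
        assert log == [("b", "a", 1.0)]

    def test_similarity_exactly_at_cutoff_keeps_both(self):
        # 8 shared HIS, one differing residue each: J = 8/10 = 0.80 exactly
        env = {"a": ["HIS"] * 8 + ["ASP"], "b": ["HIS"] * 8 + ["GLU"]}
        assert C.multiset_jaccard(env["a"], env["b"]) == pytest.approx(0.8)
        kept, _ = C.deduplicate(env, [["a", "b"]], self._priorities())
        assert kept == {"a", "b"}

    def test_three_mutually_similar_keep_exactly_one(self):
        env = {k: ["HIS", "HIS", "ASP"] for k in ("a", "b", "c")}
        kept, log = C.deduplicate(env, [["a", "b", "c"]], self._priorities())
        assert len(kept) == 1 and len(log) == 2

    def test_last_cluster_member_never_removed(self):
        env = {"a": ["HIS"]}
        kept, _ = C.deduplicate(env, [["a"]], self._priorities())
        assert kept == {"a"}

    def test_no_kept_pair_exceeds_cutoff(self):
        rng = np.random.default_rng(8)
        names = ["HIS", "ASP", "GLU", "CYS", "TYR"]
        env = {f"s{i}": list(rng.choice(names, size=6)) for i in range(12)}
        priorities = {k: C.SitePriority(k) for k in env}
        kept, _ = C.deduplicate(env, [list(env)], priorities)
        assert kept
        for a, b in itertools.combinations(sorted(kept), 2):
            assert C.multiset_jaccard(env[a], env[b]) <= 0.80 + 1e-12

    def test_priority_order_resolution_tie_break(self):
        env = {"a": ["HIS"], "b": ["HIS"]}
        pr = {"a": C.SitePriority("a", resolution=2.5),
              "b": C.SitePriority("b", resolution=1.2)}
        kept, _ = C.deduplicate(env, [["a", "b"]], pr)
        assert kept == {"b"}

    def test_cross_set_removal(self):
        env_a = {"x": ["HIS", "HIS", "ASP"]}
        env_b = {"y": ["HIS", "HIS", "ASP"], "z": ["GLU"]}
        kept, log = C.cross_set_deduplicate(env_a, env_b,
                                            [("x", "y"), ("x", "z")])
        assert kept == {"z"}
        assert log[0][:2] == ("y", "x")


class TestSpecialFilters:
    def test_mg_near_phosphate_rules(self, zinc_site):
        from conftest import make_site
        mg = make_site([0, 0, 0], metal_elements=["MG"])
        labels = {mg.site_id: "non_enzymatic"}
        kept, removed = C.special_filters(
            [mg], labels, phosphate_xyz=[np.array([8.0, 0, 0])])
        assert not kept and removed[0][1] == "mg_near_nucleic_phosphate"
        labels = {mg.site_id: "enzymatic"}
        kept, removed = C.special_filters(
            [mg], labels, phosphate_xyz=[np.array([8.0, 0, 0])])
        assert kept and not removed

    def test_metal_movement_rule(self):
        from conftest import make_site
        site = make_site([0, 0, 0])
        kept, removed = C.special_filters(
            [site], {site.site_id: "non_enzymatic"},
            metal_displacement={site.site_id: 3.2})
        assert not kept and removed[0][1] == "metal_moved_during_relaxation"
        kept, _ = C.special_filters(
            [site], {site.site_id: "non_enzymatic"},
            metal_displacement={site.site_id: 2.9})
        assert kept
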