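"""Titration solver limits, curve scalars and per-site electrostatics."""

import numpy as np
import pytest

from metalsite import titration as T
from metalsite.fixtures import FixtureSpec, _cys, make_structure
from metalsite.structure import Atom, Chain, Residue, Structure

from conftest import make_site


def _isolated(residue_name="ASP"):
    builders = {
        "ASP": lambda: Residue("A", 1, "ASP", atoms=[
            Atom("CG", "C", [0, 0, 0]), Atom("OD1", "O", [0.6, 1.0, 0]),
            Atom("OD2", "O", [0.6, -1.0, 0]), Atom("CB", "C", [-1.3, 0, 0]),
            Atom("CA", "C", [-2.4, 0.8, 0])]),
        "CYS": lambda: _cys("A", 1, np.array([0.0, 0.0, 1.0])),
    }
    ch = Chain(id="A", residues=[builders[residue_name]()])
    return Structure(id="iso", chains=[ch])


def logistic_density_moments(pka, ph_min=0.0, ph_max=14.0, step=5e-4):
    """Independent oracle: moments of the ideal titration derivative, by
    dense numerical integration of the logistic density on the pH window."""
    x = np.arange(ph_min, ph_max + step / 2, step)
    d = np.log(10) * 10 ** (x - pka) / (1 + 10 ** (x - pka)) ** 2
    d /= np.trapezoid(d, x)
    mean = np.trapezoid(x * d, x)
    return tuple(float(np.trapezoid((x - mean) ** k * d, x))
                 for k in (2, 3, 4))


class TestSolver:
    def test_isolated_residue_is_ideal_sigmoid(self):
        curve = T.solve_titration(_isolated("ASP"))[0]
        ideal = 1.0 / (1.0 + 10.0 ** (curve.ph - curve.pka_intrinsic))
        assert np.max(np.abs(curve.theta - ideal)) < 1e-9
        assert T.sigmoid_fit_residual(curve) < 1e-6
        assert curve.pka_apparent == pytest.approx(4.0, abs=1e-6)

    def test_isolated_residue_moment_limits(self):
        # CYS (pKa 8.3) sits near the window center, so the truncated
        # logistic density stays effectively symmetric
        curve = T.solve_titration(_isolated("CYS"))[0]
        mu2, mu3, _ = T.curve_moments(curve)
        mu2_oracle, mu3_oracle, _ = logistic_density_moments(8.3)
        assert abs(mu3) < 1e-3                    # symmetric derivative
        assert abs(mu3_oracle) < 1e-3
        assert mu2 == pytest.approx(mu2_oracle, abs=1e-3)

    def test_theta_monotone_and_bounded(self, zinc_structure):
        # strongly coupled mean-field curves can rise by a few 1e-4 per pH
        # step where a neighbor's charge state flips; anything larger than
        # 1e-3 would be a solver defect
        for curve in T.solve_titration(zinc_structure):
            assert np.all(curve.theta >= -1e-9)
            assert np.all(curve.theta <= 1 + 1e-9)
            assert np.all(np.diff(curve.theta) <= 1e-3)
            assert curve.theta[0] > curve.theta[-1]

    def test_zero_interactions_reproduce_ideal_sigmoids(self, zinc_structure):
        cfg = T.TitrationConfig(interaction_scale=0.0)
        for curve in T.solve_titration(zinc_structure, cfg):
            assert T.sigmoid_fit_residual(curve) < 1e-6

    def test_structure_without_ionizables_gives_no_curves(self):
        ch = Chain(id="A", residues=[Residue("A", 1, "ALA", atoms=[
            Atom("CA", "C", [0, 0, 0]), Atom("CB", "C", [1.2, 0, 0])])])
        assert T.solve_titration(Structure(id="x", chains=[ch])) == []

    def test_termini_included_when_requested(self):
        cfg = T.TitrationConfig(include_termini=True)
        # the CYS builder carries backbone N and C atoms for the termini
        curves = T.solve_titration(_isolated("CYS"), cfg)
        kinds = {c.residue_name for c in curves}
        assert {"CYS", "NTERM", "CTERM"} <= kinds


class TestScalars:
    def test_ideal_sigmoid_zero_shift_and_residual(self):
        curves = T.solve_titration(_isolated("CYS"))
        scalars = T.electro_scalars(curves)
        sc = scalars[curves[0].residue_id]
        assert sc.sigmoid_residual < 1e-6
        assert sc.delta_pka == pytest.approx(0.0, abs=1e-6)

    def test_two_sigmoid_average_inflates_mu2(self):
        ph = np.arange(0, 14.0001, 0.05)
        single = T.TitrationCurve(("A", 1, ""), "ASP", ph,
                                  1 / (1 + 10 ** (ph - 7.0)), 7.0, 0.0)
        double = T.TitrationCurve(("A", 2, ""), "ASP", ph,
                                  0.5 * (1 / (1 + 10 ** (ph - 4.0))
                                         + 1 / (1 + 10 ** (ph - 10.0))),
                                  7.0, 0.0)
        mu2_single = T.curve_moments(single)[0]
        mu2_double = T.curve_moments(double)[0]
        assert mu2_double > 5 * mu2_single

    def test_quintile_rank_bins(self):
        ph = np.arange(0, 14.0001, 0.05)
        curves = [T.TitrationCurve(("A", i, ""), "ASP", ph,
                                   1 / (1 + 10 ** (ph - 7.0)), 7.0,
                                   solvation=float(-i))
                  for i in range(10)]
        scalars = T.electro_scalars(curves)
        # solvation -0 is highest -> most destabilized -> bin 1
        destab = [scalars[("A", i, "")].destab_rank_bin for i in range(10)]
        assert destab == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        stab = [scalars[("A", i, "")].stab_rank_bin for i in range(10)]
        assert stab == [5, 5, 4, 4, 3, 3, 2, 2, 1, 1]

    def test_flat_curve_flagged_absent(self):
        ph = np.arange(0, 14.0001, 0.05)
        flat = T.TitrationCurve(("A", 1, ""), "ARG", ph,
                                np.full_like(ph, 0.999), 12.0, 0.0)
        scalars = T.electro_scalars([flat])
        assert scalars[("A", 1, "")].flagged_absent


class TestSiteFeatures:
    def _curve_at(self, ca_xyz, mu_target=None, residue=1, pka=7.0):
        ph = np.arange(0, 14.0001, 0.05)
        return T.TitrationCurve(("A", residue, ""), "HIS", ph,
                                1 / (1 + 10 ** (ph - pka)), pka, 0.0,
                                charge_center=np.asarray(ca_xyz, float),
                                ca_xyz=np.asarray(ca_xyz, float))

    def test_single_residue_environmental_weight_cancels(self):
        site = make_site([0, 0, 0])
        curve = self._curve_at([3.0, 0, 0])
        scalars = {curve.residue_id: T.ElectroScalars(
            2.0, 0.0, 0.0, 0.0, 0.0, 1, 1)}
        feats = T.electro_features(site, [curve], scalars)
        assert feats.features["ele_env_mu2"] == pytest.approx(2.0)

    def test_environmental_average_arithmetic(self):
        site = make_site([0, 0, 0])
        c1 = self._curve_at([1.0, 0, 0], residue=1)
        c2 = self._curve_at([2.0, 0, 0], residue=2)
        scalars = {c1.residue_id: T.ElectroScalars(0.0, 0, 0, 0, 0, 1, 1),
                   c2.residue_id: T.ElectroScalars(5.0, 0, 0, 0, 0, 1, 1)}
        feats = T.electro_features(site, [c1, c2], scalars)
        # (1*0 + 0.25*5) / 1.25
        assert feats.features["ele_env_mu2"] == pytest.approx(1.0)

    def test_environmental_average_scale_equivariant(self):
        values = [1.7, 4.2, 0.3]
        dists = [2.0, 4.0, 8.0]
        base = T.environmental_average(values, dists)
        scaled = T.environmental_average([3.5 * v for v in values], dists)
        assert scaled == pytest.approx(3.5 * base)

    def test_residue_exactly_at_3p5_is_inside(self):
        site = make_site([0, 0, 0])
        curve = self._curve_at([3.5, 0, 0])
        feats = T.electro_features(site, [curve])
        assert feats.features["ele_inside_n_ionizable"] == 1.0
        assert feats.features["ele_outside_n_ionizable"] == 0.0
        assert "outside" in feats.empty_shells

    def test_empty_shells_give_zero_aggregates(self):
        site = make_site([0, 0, 0])
        feats = T.electro_features(site, [])
        assert set(feats.empty_shells) == {"inside", "outside"}
        assert all(v == 0.0 for v in feats.features.values())


class TestTableBackend:
    def test_round_trip_scalars_equal(self, tmp_path, zinc_structure):
        curves = T.solve_titration(zinc_structure)
        path = tmp_path / "titration.tsv"
        T.write_titration_table(curves, path)
        read = T.read_titration_table(path, zinc_structure)
        assert len(read) == len(curves)
        direct = T.electro_scalars(curves)
        via_table = T.electro_scalars(read)
        for c_mem, c_tab in zip(curves, read):
            a = direct[c_mem.residue_id]
            b = via_table[c_tab.residue_id]
            assert a.flagged_absent == b.flagged_absent
            if not a.flagged_absent:
                assert a.mu2 == pytest.approx(b.mu2, abs=1e-6)
                assert a.delta_pka == pytest.approx(b.delta_pka, abs=2e-2)
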