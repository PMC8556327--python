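"""Surface areas against closed forms; assembly-route thermodynamics."""

import math

import numpy as np
import pytest

from phycoring.energetics import (AssemblyEnergyModel, DEFAULT_DG_DISS,
                                  contact_percent, formation_energy,
                                  interface_report, pathway_graph,
                                  shrake_rupley_sasa,
                                  solvation_energy_estimate)
from phycoring.structure import Atom


def _carbon(xyz, n=1, chain="A"):
    return Atom("C", "CA", np.asarray(xyz, float), "ALA", n, chain)


def _sphere_area(r_vdw=1.70, probe=1.4):
    return 4.0 * math.pi * (r_vdw + probe) ** 2


def _cap_area(d, R=1.70 + 1.4):
    """Buried (occluded) cap area on each of two equal spheres at distance d."""
    h = R - d / 2.0
    return 2.0 * math.pi * R * h


class TestShrakeRupley:
    def test_single_carbon_closed_form(self):
        res = shrake_rupley_sasa([_carbon([0, 0, 0])])
        assert res.total == pytest.approx(_sphere_area(), rel=5e-3)

    def test_distant_atoms_are_independent(self):
        res = shrake_rupley_sasa([_carbon([0, 0, 0]), _carbon([100, 0, 0], 2)])
        assert res.total == pytest.approx(2 * _sphere_area(), rel=1e-6)
        assert res.total == pytest.approx(res.per_atom_area.sum(), rel=1e-9)

    @pytest.mark.parametrize("d", [1.5, 2.5, 4.0])
    def test_overlapping_pair_matches_cap_oracle(self, d):
        atoms = [_carbon([0, 0, 0]), _carbon([d, 0, 0], 2)]
        got = shrake_rupley_sasa(atoms, n_points=960).total
        analytic = 2 * (_sphere_area() - _cap_area(d))
        assert got == pytest.approx(analytic, rel=0.01)
        assert got < 2 * _sphere_area()

    def test_brute_force_high_density_agreement(self):
        atoms = [_carbon([0, 0, 0]), _carbon([2.0, 0, 0], 2)]
        coarse = shrake_rupley_sasa(atoms, n_points=960).total
        dense = shrake_rupley_sasa(atoms, n_points=10_000).total
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_convergence_under_point_doubling(self, hexamer_ring):
        asm, _ = hexamer_ring
        part = asm.protomer_atoms(asm.protomers[0])
        a = shrake_rupley_sasa(part, n_points=960).total
        b = shrake_rupley_sasa(part, n_points=1920).total
        assert abs(b - a) / a < 0.003

    def test_unknown_element_raises(self):
        odd = Atom("Xq", "XQ", np.zeros(3), "UNK", 1, "A")
        with pytest.raises(ValueError, match="Xq"):
            shrake_rupley_sasa([odd])

    def test_empty_and_bad_probe(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa([])
        with pytest.raises(ValueError):
            shrake_rupley_sasa([_carbon([0, 0, 0])], probe=0.0)


class TestInterfaceReport:
    def test_separated_parts_bury_nothing(self):
        rep = interface_report([_carbon([0, 0, 0])], [_carbon([100, 0, 0], 2, "B")])
        assert rep.buried == pytest.approx(0.0, abs=0.1)
        assert rep.contact_percent_a == pytest.approx(0.0, abs=0.01)

    def test_two_sphere_dimer_matches_cap(self):
        d = 2.5
        rep = interface_report([_carbon([0, 0, 0])], [_carbon([d, 0, 0], 2, "B")])
        assert rep.buried == pytest.approx(_cap_area(d), rel=0.01)
        # per-part burial agrees up to sphere-point sampling noise
        assert rep.buried_a == pytest.approx(rep.buried_b, rel=0.02)

    def test_buried_symmetric_under_part_swap(self, hexamer_ring):
        asm, _ = hexamer_ring
        a = asm.protomer_atoms(asm.protomers[0])
        b = asm.protomer_atoms(asm.protomers[1])
        ab = interface_report(a, b, n_points=480)
        ba = interface_report(b, a, n_points=480)
        assert ab.buried == pytest.approx(ba.buried, abs=0.1)
        assert ab.buried >= -0.1

    def test_overlapping_parts_rejected(self):
        a = [_carbon([0, 0, 0])]
        with pytest.raises(ValueError, match="overlap"):
            interface_report(a, a)


class TestContactPercent:
    def test_limits(self):
        assert contact_percent(0.0, 123.0) == 0.0
        assert contact_percent(50.0, 50.0) == 50.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            contact_percent(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            contact_percent(-1.0, 10.0)


class TestSolvationEstimate:
    def test_zero_burial_gives_zero(self):
        got = solvation_energy_estimate([_carbon([0, 0, 0])],
                                        [_carbon([100, 0, 0], 2, "B")])
        assert got == pytest.approx(0.0, abs=1e-3)

    def test_hand_computed_sum(self):
        # two overlapping carbons: dG = asp_C * total buried area
        d = 2.5
        a, b = [_carbon([0, 0, 0])], [_carbon([d, 0, 0], 2, "B")]
        asp = {"C": 0.016}
        sa = shrake_rupley_sasa(a).total
        sb = shrake_rupley_sasa(b).total
        sc = shrake_rupley_sasa(a + b).total
        expected = 0.016 * (sa + sb - sc)
        got = solvation_energy_estimate(a, b, asp=asp)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_linearity_in_asp(self):
        d = 2.5
        a, b = [_carbon([0, 0, 0])], [_carbon([d, 0, 0], 2, "B")]
        one = solvation_energy_estimate(a, b, asp={"C": 0.016})
        two = solvation_energy_estimate(a, b, asp={"C": 0.032})
        assert two == pytest.approx(2 * one, rel=1e-9)


class TestFormationEnergy:
    def test_tetramers_to_octamer_is_positive(self):
        assert formation_energy([4, 4], 8) == pytest.approx(11.1, abs=1e-9)

    def test_monomers_to_hexamer(self):
        assert formation_energy([1] * 6, 6) == pytest.approx(-54.6, abs=1e-9)

    def test_identity_product(self):
        assert formation_energy([6], 6) == 0.0

    def test_unbalanced_stoichiometry(self):
        with pytest.raises(ValueError, match="unbalanced"):
            formation_energy([2, 2], 6)

    def test_additivity(self):
        model = AssemblyEnergyModel()
        ab = formation_energy([1, 1], 2, model)
        ab_c = formation_energy([2, 1], 3, model)
        abc = formation_energy([1, 1, 1], 3, model)
        assert ab + ab_c == pytest.approx(abc, abs=1e-12)

    def test_hexamer_more_stable_than_octamer(self):
        model = AssemblyEnergyModel()
        ranking = model.ranking()
        assert ranking.index(6) < ranking.index(8)
        assert model.diss(6) > model.diss(8)


class TestPathwayGraph:
    def test_default_routes_flag_tetramer_step(self):
        rows = pathway_graph()
        flagged = [r for r in rows if r["unfavorable"] and "final_n" not in r]
        assert len(flagged) == 1
        assert flagged[0]["step"] == "4+4->8"
        assert flagged[0]["dg_f"] == pytest.approx(11.1, abs=1e-9)

    def test_route_totals_telescope(self):
        model = AssemblyEnergyModel()
        for row in pathway_graph(model):
            if "final_n" in row:
                assert row["dg_f"] == pytest.approx(
                    -model.diss(row["final_n"]), abs=1e-12)

    def test_zero_table_gives_zero_steps(self):
        model = AssemblyEnergyModel(dg_diss={n: 0.0 for n in DEFAULT_DG_DISS})
        assert all(r["dg_f"] == 0.0 for r in pathway_graph(model))

    def test_unknown_oligomer_rejected(self):
        with pytest.raises(KeyError, match="n=5"):
            pathway_graph(routes={"bad": [(1, [1] * 5, 5)]})

    def test_empty_routes_give_empty_table(self):
        assert pathway_graph(routes={}) == []

    def test_override_table_recomputes(self):
        model = AssemblyEnergyModel(dg_diss={1: 0.0, 2: 10.0, 4: 15.0})
        assert formation_energy([2, 2], 4, model) == pytest.approx(5.0)
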