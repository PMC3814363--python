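"""SASA, buried area, contact typing and polar-contact density."""

import numpy as np
import pytest

from p4ring.interface import (buried_area, find_contacts, interface_report,
                              ring_interfaces, sasa)
from p4ring.model import Atom, Chain, Residue, StructureModel
from p4ring.synthetic import RingSpec, contact_pair_model, make_ring, slab_interface_model

R_EXP = 1.7 + 1.4  # carbon + water probe


def carbon_model(positions, chain_ids=None):
    """Carbon pseudo-atoms; one chain per id given, else all in chain A."""
    if chain_ids:
        chains = [Chain(cid, [Residue(1, "ALA",
                                      atoms=[Atom("CA", "C", np.asarray(pos, float))])])
                  for cid, pos in zip(chain_ids, positions)]
    else:
        chains = [Chain("A", [Residue(k + 1, "ALA",
                                      atoms=[Atom("CA", "C", np.asarray(pos, float))])
                              for k, pos in enumerate(positions)])]
    return StructureModel("toy", chains)


class TestSASA:
    def test_isolated_carbon_matches_sphere_area(self, carbon_at_origin):
        result = sasa(carbon_at_origin, probe=1.4, n_points=960)
        exact = 4 * np.pi * R_EXP ** 2
        assert result.total == pytest.approx(exact, rel=0.01)
        assert result.radii_set == "bondi64"

    def test_fully_enclosed_atom_zero(self):
        # central atom caged by 26 neighbours on a 2.2 Å lattice
        shell = [np.array([i, j, k]) * 2.2
                 for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        model = carbon_model(shell)
        result = sasa(model, probe=1.4, n_points=960)
        centre = [i for i, a in enumerate(result.atoms) if a[1] == 14][0]
        assert result.per_atom[centre] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [3.0, 4.0, 5.0])
    def test_two_sphere_analytic_case(self, d):
        model = carbon_model([[0, 0, 0], [d, 0, 0]], chain_ids="AB")
        total = sasa(model, probe=1.4, n_points=960).total
        cap = 2 * np.pi * R_EXP * (R_EXP - d / 2)
        analytic = 2 * (4 * np.pi * R_EXP ** 2 - cap)
        assert total == pytest.approx(analytic, rel=0.02)

    def test_monotone_under_added_occluders(self, carbon_at_origin):
        prev = sasa(carbon_at_origin, 1.4, 960).per_atom[0]
        positions = [[0, 0, 0]]
        for extra in ([4, 0, 0], [0, 4, 0], [0, 0, 4]):
            positions.append(extra)
            area0 = sasa(carbon_model(positions), 1.4, 960).per_atom[0]
            assert area0 <= prev + 1e-9
            prev = area0

    def test_unknown_element_named_in_error(self):
        model = StructureModel("x", [Chain("A", [Residue(1, "UNK",
                               atoms=[Atom("Q1", "Xx", np.zeros(3))])])])
        with pytest.raises(KeyError, match="Xx"):
            sasa(model)

    def test_doubling_points_converged_within_1pct(self, tube_ring):
        t1 = sasa(tube_ring, 1.4, 960).total
        t2 = sasa(tube_ring, 1.4, 1920).total
        assert abs(t1 - t2) / t2 < 0.01


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self):
        model = carbon_model([[0, 0, 0], [100, 0, 0]], chain_ids="AB")
        assert abs(buried_area(model, "A", "B")) < 1.0

    def test_symmetric_in_chain_order(self):
        slabs = slab_interface_model()
        assert buried_area(slabs, "A", "B") == buried_area(slabs, "B", "A")

    def test_touching_slabs_match_refined_sampling_within_3pct(self):
        slabs = slab_interface_model()
        coarse = buried_area(slabs, "A", "B", n_points=960)
        fine = buried_area(slabs, "A", "B", n_points=1920)
        assert coarse == pytest.approx(fine, rel=0.03)
        assert coarse > 50  # genuinely buried interface

    def test_halved_convention_is_half_of_full(self):
        slabs = slab_interface_model()
        assert buried_area(slabs, "A", "B", halved=False) == pytest.approx(
            2 * buried_area(slabs, "A", "B", halved=True))


class TestContacts:
    def test_ser_asp_hbond_but_not_salt_bridge(self):
        m = contact_pair_model(("SER", "OG"), ("ASP", "OD1"), 2.9)
        assert len(find_contacts(m, "A", "B", "hbond")) == 1
        assert len(find_contacts(m, "A", "B", "salt_bridge")) == 0

    def test_boundary_distance_inclusive(self):
        m = contact_pair_model(("SER", "OG"), ("ASP", "OD1"), 3.5)
        hits = find_contacts(m, "A", "B", "hbond")
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(3.5, abs=1e-6)

    def test_beyond_boundary_excluded(self):
        m = contact_pair_model(("SER", "OG"), ("ASP", "OD1"), 3.51)
        assert len(find_contacts(m, "A", "B", "hbond")) == 0

    def test_lys_glu_counts_in_both_inventories(self):
        m = contact_pair_model(("LYS", "NZ"), ("GLU", "OE1"), 3.2)
        assert len(find_contacts(m, "A", "B", "hbond")) == 1
        assert len(find_contacts(m, "A", "B", "salt_bridge")) == 1

    def test_hydrophobic_apolar_carbons(self):
        m = contact_pair_model(("LEU", "CD1"), ("LEU", "CD1"), 4.5)
        assert len(find_contacts(m, "A", "B", "hydrophobic")) == 1
        # carbonyl carbons are not apolar: no contact through backbone C
        m2 = contact_pair_model(("LEU", "C"), ("LEU", "C"), 4.0)
        assert len(find_contacts(m2, "A", "B", "hydrophobic")) == 0

    def test_unknown_kind_rejected(self):
        m = contact_pair_model(("SER", "OG"), ("ASP", "OD1"), 2.9)
        with pytest.raises(ValueError, match="kind"):
            find_contacts(m, "A", "B", "pi_stack")


class TestInterfaceReport:
    def test_double_qualifying_pair_counted_once_in_polar(self):
        m = contact_pair_model(("LYS", "NZ"), ("GLU", "OE1"), 3.2)
        rep = interface_report(m, "A", "B")
        assert rep.n_hbonds == 1
        assert rep.n_salt_bridges == 1
        assert rep.n_polar_unique == 1
        assert rep.polar_density == pytest.approx(1.0 / rep.bsa)

    def test_zero_polar_contacts_zero_density(self):
        slabs = slab_interface_model()
        rep = interface_report(slabs, "A", "B")
        assert rep.n_hbonds == 0 and rep.n_salt_bridges == 0
        assert rep.polar_density == 0.0
        assert rep.bsa > 0

    def test_polar_density_arithmetic(self):
        # 30 polar contacts over 1875 Å² buried → 0.016 per Å²
        assert 30 / 1875 == pytest.approx(0.016)

    def test_ring_reports_adjacent_pairs(self, tube_ring):
        reports = ring_interfaces(tube_ring)
        assert len(reports) == 6
        assert {(r.chain_a, r.chain_b) for r in reports} == {
            ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F"), ("F", "A")}
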