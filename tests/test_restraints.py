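"""Restraint types, contact-list parsing, and flat-bottom scoring."""

import numpy as np
import pytest

from crossbeta.fibril_model import FibrilModel, build_chain, replicate
from crossbeta.restraints import (
    AtomRef,
    DihedralRestraint,
    DistanceRestraint,
    HBondRestraint,
    RestraintError,
    RestraintSet,
    UNAMBIGUOUS_CONTACTS,
    make_inregister_restraints,
    parse_contact_list,
    violation_report,
)
from crossbeta.synth_data import gen_restraints_from_structure


class TestParseContacts:
    def test_printed_list_gives_ten(self):
        rs = parse_contact_list(UNAMBIGUOUS_CONTACTS)
        assert len(rs.distance) == 10
        assert all(r.rclass == "unambiguous" for r in rs.distance)
        assert all(r.a.subunit_offset == 0 and r.b.subunit_offset == 0
                   for r in rs.distance)

    def test_bounds_by_experiment_class(self):
        rs = parse_contact_list(UNAMBIGUOUS_CONTACTS)
        for r in rs.distance:
            names = (r.a.atom_name, r.b.atom_name)
            if any(n.startswith("N") for n in names):
                assert (r.target, r.lower_margin) == (4.5, 2.5)
            else:
                assert (r.target, r.lower_margin) == (5.5, 1.5)

    def test_empty_string(self):
        assert len(parse_contact_list("")) == 0

    def test_pair_without_shared_ambiguity_group(self):
        rs = parse_contact_list("Q449Cδ−L456Cβ, Q449Cδ-L456Cγ")
        assert len(rs.distance) == 2
        assert all(r.ambiguity_group is None for r in rs.distance)

    def test_malformed_token_named(self):
        with pytest.raises(RestraintError, match="449 Cd"):
            parse_contact_list("449 Cd-L456Cβ")

    def test_atom_invalid_for_residue(self):
        with pytest.raises(RestraintError, match="not valid"):
            parse_contact_list("G451Cβ−N454Cα")  # glycine has no Cβ

    def test_sequence_check(self):
        with pytest.raises(RestraintError, match="sequence has"):
            parse_contact_list("A441Cβ−G451Cα", sequence="VFNNCSEVQIG",
                               start_number=441)


class TestInRegister:
    def test_default_counts(self):
        rs = make_inregister_restraints()
        assert rs.counts() == {"distance": 3, "hbond": 5, "dihedral": 0}
        for r in rs.distance:
            assert r.target == 4.75 and r.a.residue_number == r.b.residue_number
            assert {r.a.subunit_offset, r.b.subunit_offset} == {0, 1}

    def test_empty_registry(self):
        rs = make_inregister_restraints(registry_atoms=(), hbond_pairs=())
        assert len(rs) == 0

    def test_missing_registry_atom(self):
        with pytest.raises(RestraintError, match="missing"):
            make_inregister_restraints(registry_atoms=((2, "CB"),),
                                       hbond_pairs=(),
                                       sequence="AGA", start_number=1)

    def test_invalid_rise(self):
        with pytest.raises(RestraintError):
            make_inregister_restraints(rise=-1.0)


class TestSerialization:
    def test_tsv_idempotent(self):
        rs = parse_contact_list(UNAMBIGUOUS_CONTACTS)
        rs.extend(make_inregister_restraints())
        rs.add(DihedralRestraint(449, "phi", -120.0, 25.0))
        text = rs.to_tsv()
        rs2 = RestraintSet.from_tsv(text)
        assert rs2.to_tsv() == text

    def test_duplicate_distance_rejected(self):
        rs = RestraintSet()
        r = DistanceRestraint(AtomRef(1, "CA"), AtomRef(3, "CA"), 5.0, 1.0,
                              1.0)
        rs.add(r)
        with pytest.raises(RestraintError, match="duplicate"):
            rs.add(DistanceRestraint(AtomRef(3, "CA"), AtomRef(1, "CA"),
                                     5.0, 1.0, 1.0))

    def test_assign_export(self):
        rs = parse_contact_list("Q449Cδ−L456Cβ")
        text = rs.to_assign_statements()
        assert text.startswith("assign (resid 449 and name CD)")
        assert "5.50 1.50 1.50" in text

    def test_field_validation(self):
        with pytest.raises(RestraintError):
            DistanceRestraint(AtomRef(1, "CA"), AtomRef(2, "CA"), -1.0,
                              1.0, 1.0)
        with pytest.raises(RestraintError):
            DihedralRestraint(1, "phi", 0.0, -5.0)
        with pytest.raises(RestraintError):
            AtomRef(1, "CA", subunit_offset=2)


@pytest.fixture(scope="module")
def model():
    return replicate(build_chain("AVANQL"), 3, 4.75, 0.0)


class TestViolationReport:

    def _distance(self, model, a, b):
        return float(np.linalg.norm(model.get_atom(*a) - model.get_atom(*b)))

    def test_inside_flat_bottom_zero(self, model):
        d = self._distance(model, (2, "CA"), (5, "CA"))
        rs = RestraintSet()
        rs.add(DistanceRestraint(AtomRef(2, "CA"), AtomRef(5, "CA"), d,
                                 1.0, 1.0))
        tab, tot = violation_report(model, rs)
        assert tot["energy"] == 0.0 and tot["n_violated"] == 0

    def test_quadratic_excess_closed_form(self, model):
        d = self._distance(model, (2, "CA"), (5, "CA"))
        # target chosen so the distance sits exactly 0.5 A above the bound
        rs = RestraintSet()
        rs.add(DistanceRestraint(AtomRef(2, "CA"), AtomRef(5, "CA"),
                                 d - 1.5, 1.0, 1.0))
        tab, tot = violation_report(model, rs, force_k=1.0)
        assert tot["energy"] == pytest.approx(0.25, abs=1e-9)
        assert tab.violation.iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_ambiguity_r6_dominance(self, model):
        d1 = self._distance(model, (2, "CA"), (4, "CA"))
        d2 = self._distance(model, (1, "CA"), (6, "CA"))
        assert d2 > d1
        rs = RestraintSet()
        rs.add(DistanceRestraint(AtomRef(2, "CA"), AtomRef(4, "CA"), 5.0,
                                 1.0, 1.0, ambiguity_group="g1"))
        rs.add(DistanceRestraint(AtomRef(1, "CA"), AtomRef(6, "CA"), 5.0,
                                 1.0, 1.0, ambiguity_group="g1"))
        tab, _ = violation_report(model, rs)
        d_eff = float(tab.loc[tab.restraint == "group:g1", "value"].iloc[0])
        expected = (d1 ** -6 + d2 ** -6) ** (-1.0 / 6.0)
        assert d_eff == pytest.approx(expected, abs=1e-9)
        assert d_eff <= d1  # shorter member dominates

    def test_dihedral_on_circle(self, model):
        rs = RestraintSet()
        rs.add(DihedralRestraint(3, "phi", 170.0, 5.0))  # actual phi = 180
        tab, tot = violation_report(model, rs)
        assert tab.violation.iloc[0] == pytest.approx(5.0, abs=1e-6)
        rs2 = RestraintSet()
        rs2.add(DihedralRestraint(3, "phi", -175.0, 10.0))  # 5 deg away
        _, tot2 = violation_report(model, rs2)
        assert tot2["n_violated"] == 0

    def test_unresolvable_atom_names_restraint(self, model):
        rs = RestraintSet()
        rs.add(DistanceRestraint(AtomRef(2, "SG"), AtomRef(5, "CA"), 5.0,
                                 1.0, 1.0))
        with pytest.raises(RestraintError, match="2SG"):
            violation_report(model, rs)

    def test_intermolecular_needs_stack(self):
        p = build_chain("AVA")
        rs = make_inregister_restraints(registry_atoms=((2, "CB"),),
                                        hbond_pairs=())
        with pytest.raises(RestraintError, match=">= 2 subunits"):
            violation_report(FibrilModel(p, 1, 4.75), rs)

    def test_generated_restraints_self_consistent(self, mini_arch):
        """Restraints back-computed from coordinates score zero on the
        coordinates that generated them."""
        protomer, rs = mini_arch
        model = FibrilModel(protomer, 1, 4.75)
        tab, tot = violation_report(model, rs)
        assert tot["n_violated"] == 0
        assert tot["max_violation"] == 0.0

    def test_ideal_strand_zero_violations_vs_inregister(self, ideal_strand):
        model = replicate(ideal_strand, 5, 4.75, 0.0)
        tab, tot = violation_report(model, make_inregister_restraints())
        assert tot["n_violated"] == 0

    def test_hbond_component_expansion(self):
        h = HBondRestraint(449, 448)
        comps = h.components()
        assert [c.target for c in comps] == [2.3, 3.3]
        assert all(c.adjacent_either_side for c in comps)


class TestStructureDerivedRestraints:
    def test_cutoff_validation(self, mini_arch):
        protomer, _ = mini_arch
        with pytest.raises(ValueError):
            gen_restraints_from_structure(protomer, -1.0)

    def test_tiny_cutoff_empty(self, mini_arch):
        protomer, _ = mini_arch
        rs = gen_restraints_from_structure(protomer, 0.1)
        assert len(rs) == 0

    def test_two_atom_bounds(self, mini_arch):
        protomer, rs = mini_arch
        x = protomer.coords
        for r in rs.distance:
            d = np.linalg.norm(
                x[protomer.atom_index(r.a.residue_number, r.a.atom_name)]
                - x[protomer.atom_index(r.b.residue_number, r.b.atom_name)])
            assert r.target == pytest.approx(float(d), abs=1e-9)
            assert r.lower_margin == 1.5 and r.upper_margin == 1.5

    def test_cross_subunit_tagging(self, ideal_strand):
        model = replicate(ideal_strand, 3, 4.75, 0.0)
        rs = gen_restraints_from_structure(model, 4.9)
        inter = [r for r in rs.distance if not r.intramolecular]
        assert inter, "in-register stack must create intermolecular contacts"
        assert all(r.rclass == "intermolecular" for r in inter)
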