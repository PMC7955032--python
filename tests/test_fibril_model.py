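"""Chain construction, fibril symmetry, and geometry measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossbeta.fibril_model import (
    FibrilModel,
    Protomer,
    bond_angle,
    build_chain,
    detect_hbond_ladder,
    dihedral,
    estimate_pitch,
    expected_mpl,
    kabsch_rmsd,
    kabsch_transform,
    measure_rise_twist,
    read_fibril_pdb,
    replicate,
    sequence_mass,
    twist_from_pitch,
    validate_deposited_model,
)
from crossbeta.synth_data import gen_afm_profile

ALL20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Chain building
# ---------------------------------------------------------------------------

class TestBuildChain:
    def test_extended_chain_ca_spacing(self):
        p = build_chain("AAAAAA")
        x = p.coords
        ca = [x[p.atom_index(i, "CA")] for i in p.residue_numbers]
        for a, b in zip(ca, ca[1:]):
            assert np.linalg.norm(b - a) == pytest.approx(3.80, abs=0.05)

    @pytest.mark.parametrize("resnum", range(1, 21))
    def test_canonical_backbone_bonds_all_residues(self, resnum):
        p = build_chain(ALL20)
        x = p.coords
        n_ca = np.linalg.norm(x[p.atom_index(resnum, "CA")]
                              - x[p.atom_index(resnum, "N")])
        assert n_ca == pytest.approx(1.458, abs=0.01)
        ca_c = np.linalg.norm(x[p.atom_index(resnum, "C")]
                              - x[p.atom_index(resnum, "CA")])
        assert ca_c == pytest.approx(1.525, abs=0.01)
        c_o = np.linalg.norm(x[p.atom_index(resnum, "O")]
                             - x[p.atom_index(resnum, "C")])
        assert c_o == pytest.approx(1.231, abs=0.01)
        if resnum < 20:
            c_n = np.linalg.norm(x[p.atom_index(resnum + 1, "N")]
                                 - x[p.atom_index(resnum, "C")])
            assert c_n == pytest.approx(1.329, abs=0.01)

    def test_torsions_round_trip(self):
        p = build_chain("AVANQL")
        p.set_torsion(3, "phi", -57.0)
        p.set_torsion(3, "psi", -47.0)
        p.set_torsion(5, "chi2", 63.0)
        x = p.coords
        idx = p.atom_index
        phi = dihedral(x[idx(2, "C")], x[idx(3, "N")], x[idx(3, "CA")],
                       x[idx(3, "C")])
        psi = dihedral(x[idx(3, "N")], x[idx(3, "CA")], x[idx(3, "C")],
                       x[idx(4, "N")])
        chi2 = dihedral(x[idx(5, "CA")], x[idx(5, "CB")], x[idx(5, "CG")],
                        x[idx(5, "CD")])
        assert phi == pytest.approx(-57.0, abs=1e-8)
        assert psi == pytest.approx(-47.0, abs=1e-8)
        assert chi2 == pytest.approx(63.0, abs=1e-8)

    def test_omega_trans_and_stereochemistry(self):
        p = build_chain("AVA")
        x = p.coords
        idx = p.atom_index
        omega = dihedral(x[idx(1, "CA")], x[idx(1, "C")], x[idx(2, "N")],
                         x[idx(2, "CA")])
        assert abs(abs(omega) - 180.0) < 1e-8
        # one consistent handedness for every CB
        for r in (1, 2, 3):
            improper = dihedral(x[idx(r, "C")], x[idx(r, "N")],
                                x[idx(r, "CA")], x[idx(r, "CB")])
            assert improper == pytest.approx(-122.6, abs=0.1)

    def test_three_residue_chain_vs_planar_oracle(self):
        """All-trans glycine backbone must match a closed-form planar
        zig-zag computed independently with explicit 2D trigonometry."""
        p = build_chain("GGG")
        x = p.coords
        names = [(1, "N"), (1, "CA"), (1, "C"), (2, "N"), (2, "CA"),
                 (2, "C"), (3, "N"), (3, "CA"), (3, "C")]
        built = np.array([x[p.atom_index(r, n)] for r, n in names])

        bonds = [1.458, 1.525, 1.329, 1.458, 1.525, 1.329, 1.458, 1.525]
        angles = [111.2, 116.2, 121.7, 111.2, 116.2, 121.7, 111.2]
        pos = [np.zeros(2)]
        heading = 0.0
        sign = -1.0
        for k, b in enumerate(bonds):
            pos.append(pos[-1] + b * np.array([math.cos(heading),
                                               math.sin(heading)]))
            if k < len(angles):
                turn = math.pi - math.radians(angles[k])
                sign = -sign
                heading += sign * turn
        oracle = np.column_stack([np.array(pos), np.zeros(len(pos))])
        assert kabsch_rmsd(built, oracle) < 1e-6

    def test_unknown_residue_code(self):
        with pytest.raises(ValueError, match="unknown residue"):
            build_chain("AXA")

    def test_polar_hydrogens_present(self):
        p = build_chain("SQNY")
        names = {n for (_r, _t, n) in p.atoms}
        assert {"HG", "HE21", "HE22", "HD21", "HD22", "HH", "H"} <= names


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _horn_quaternion_rmsd(a, b):
    """Independent superposition oracle: Horn's closed-form quaternion
    method (eigenvector of the 4x4 key matrix)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    M = a.T @ b
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    N = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(N)[-1]
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / a.shape[0]
    return math.sqrt(max(msd, 0.0))


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(x, x) < 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=2).as_matrix()
        y = x @ R.T + np.array([3.0, -1.0, 7.0])
        assert kabsch_rmsd(x, y) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        pert = square + rng.normal(scale=1.0, size=square.shape)
        assert kabsch_rmsd(square, pert) == pytest.approx(
            _horn_quaternion_rmsd(square, pert), abs=1e-6)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert kabsch_rmsd(a, b) >= 0
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a),
                                                  abs=1e-10)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            kabsch_transform(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Replication and screw measurement
# ---------------------------------------------------------------------------

class TestReplicateMeasure:
    def test_untwisted_round_trip(self):
        p = build_chain("AVANQL")
        m = replicate(p, 5, 4.75, 0.0)
        rise, twist = measure_rise_twist(m)
        assert rise == pytest.approx(4.75, abs=1e-6)
        assert twist == pytest.approx(0.0, abs=1e-6)
        # every atom's copy-to-copy displacement is exactly the rise
        d = m.subunit_coords(1) - m.subunit_coords(0)
        assert np.allclose(d, [0, 0, 4.75], atol=1e-12)

    def test_twisted_round_trip(self):
        p = build_chain("AVANQL")
        m = replicate(p, 3, 4.8, -6.1)
        rise, twist = measure_rise_twist(m)
        assert rise == pytest.approx(4.8, abs=1e-6)
        assert twist == pytest.approx(-6.1, abs=1e-6)

    def test_single_subunit_is_protomer(self):
        p = build_chain("AVA")
        m = replicate(p, 1, 4.75)
        assert np.allclose(m.all_coords(), p.coords)

    def test_identical_unshifted_subunits(self):
        p = build_chain("AVA")
        subs = [p.coords, p.coords.copy()]
        rise, twist = measure_rise_twist(subs)
        assert rise == pytest.approx(0.0, abs=1e-9)
        assert twist == pytest.approx(0.0, abs=1e-9)

    def test_bad_parameters(self):
        p = build_chain("AVA")
        with pytest.raises(ValueError):
            replicate(p, 5, -1.0)
        with pytest.raises(ValueError):
            replicate(p, 0, 4.75)
        with pytest.raises(ValueError):
            measure_rise_twist([p.coords])

    def test_pdb_round_trip_chains_and_models(self, tmp_path):
        p = build_chain("AVANQL")
        m = replicate(p, 3, 4.75, -3.0)
        for style in ("chains", "models"):
            path = tmp_path / f"fib_{style}.pdb"
            m.to_pdb(path, style=style)
            subs, atoms = read_fibril_pdb(path)
            assert len(subs) == 3
            rise, twist = measure_rise_twist(subs)
            assert rise == pytest.approx(4.75, abs=1e-3)
            assert twist == pytest.approx(-3.0, abs=1e-3)


# ---------------------------------------------------------------------------
# Hydrogen-bond ladders
# ---------------------------------------------------------------------------

class TestHBondLadder:
    def test_backbone_ladder_on_ideal_strand(self, ideal_strand):
        m = replicate(ideal_strand, 3, 4.75, 0.0)
        found = detect_hbond_ladder(m)
        backbone = {c.donor_residue for c in found if not c.sidechain}
        # interior residues hydrogen-bond to an adjacent subunit
        assert len(backbone & set(range(443, 459))) >= 12

    def test_q_ladder_fixture(self, q_ladder):
        found = detect_hbond_ladder(q_ladder, donor_acceptor_pairs=[(2, 2),
                                                                    (4, 4)])
        assert {c.donor_residue for c in found} == {2, 4}
        for c in found:
            assert c.h_o == pytest.approx(1.97, abs=0.01)

    def test_zero_cutoffs_empty(self, q_ladder):
        assert detect_hbond_ladder(q_ladder, h_o_max=0.0, n_o_max=0.0) == []

    def test_needs_two_subunits(self):
        p = build_chain("AQA")
        with pytest.raises(ValueError, match="2 subunits"):
            detect_hbond_ladder(FibrilModel(p, 1, 4.75))

    def test_deposited_model_validation_on_synthetic_standin(self, tmp_path,
                                                             q_ladder):
        """The deposited-structure validator measures the Q side-chain
        ladder and the rise on any multi-subunit PDB; exercised here on the
        synthetic Q-ladder stand-in."""
        path = tmp_path / "standin.pdb"
        q_ladder.to_pdb(path, style="models")
        out = validate_deposited_model(path, q_residue=2)
        assert out["rise"] == pytest.approx(4.75, abs=1e-3)
        assert out["h_o"] == pytest.approx(1.97, abs=0.02)


# ---------------------------------------------------------------------------
# Scalar relations
# ---------------------------------------------------------------------------

class TestScalars:
    def test_twist_from_pitch_printed_value(self):
        assert round(twist_from_pitch(28.5, 0.48), 1) == 6.1

    def test_twist_from_pitch_cases(self):
        assert twist_from_pitch(0.96, 0.48) == pytest.approx(180.0)
        assert twist_from_pitch(1e9, 0.48) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            twist_from_pitch(-1.0, 0.48)

    def test_expected_mpl_printed_value(self):
        assert round(expected_mpl(9.57, 0.48), 1) == 19.9

    def test_expected_mpl_cases(self):
        assert expected_mpl(131.0, 1.0, 1) == pytest.approx(131.0)
        assert expected_mpl(9.57, 0.48, 2) == pytest.approx(39.875)

    @settings(deadline=None, max_examples=50)
    @given(mass=st.floats(1.0, 500.0), rise=st.floats(0.1, 10.0),
           mol=st.integers(1, 6))
    def test_expected_mpl_conservation(self, mass, rise, mol):
        assert expected_mpl(mass, rise, mol) * rise == pytest.approx(
            mol * mass, rel=1e-12)

    def test_sequence_mass_glycine(self):
        assert sequence_mass("G") == pytest.approx(0.07507, abs=5e-6)

    def test_sequence_mass_empty_warns(self):
        with pytest.warns(UserWarning):
            m = sequence_mass("")
        assert m == pytest.approx(0.0180153, abs=1e-6)

    def test_sequence_mass_unknown(self):
        with pytest.raises(ValueError):
            sequence_mass("AZB")


# ---------------------------------------------------------------------------
# Pitch estimation
# ---------------------------------------------------------------------------

class TestPitch:
    def test_noise_free_round_trip(self):
        (x, y), _ = gen_afm_profile(28.5, 0.3, length=12 * 28.5,
                                    sampling=1.0, noise_sd=0.0)
        r = estimate_pitch(x, y)
        assert r.periodic
        assert r.pitch_nm == pytest.approx(28.5, abs=1.0)

    def test_flat_trace_no_periodicity(self):
        x = np.arange(0.0, 300.0, 1.0)
        r = estimate_pitch(x, np.full_like(x, 1.8))
        assert not r.periodic and r.pitch_nm is None

    def test_zero_amplitude_no_periodicity(self):
        (x, y), _ = gen_afm_profile(28.5, 0.0, length=300.0, sampling=1.0,
                                    noise_sd=0.0)
        r = estimate_pitch(x, y)
        assert not r.periodic

    def test_noisy_recovery_within_5pct(self):
        (x, y), _ = gen_afm_profile(28.5, 0.3, length=12 * 28.5,
                                    sampling=1.0, noise_sd=0.3 / 5.0,
                                    seed=3)
        r = estimate_pitch(x, y)
        assert r.periodic
        assert abs(r.pitch_nm - 28.5) / 28.5 < 0.05

    def test_spectral_cross_check(self):
        (x, y), _ = gen_afm_profile(30.0, 0.3, length=420.0, sampling=1.0,
                                    noise_sd=0.0)
        r = estimate_pitch(x, y)
        assert r.spectral_pitch_nm == pytest.approx(r.pitch_nm, rel=0.15)

    def test_too_short(self):
        with pytest.raises(ValueError):
            estimate_pitch(np.array([0.0]), np.array([1.0]))
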