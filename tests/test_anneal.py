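"""Monte-Carlo annealing under strict fibril symmetry."""

import numpy as np
import pytest

from crossbeta.anneal import (
    AnnealSchedule,
    EnsembleResult,
    FoldResult,
    fold,
    medoid,
    select_best,
    two_round_protocol,
)
from crossbeta.fibril_model import FibrilModel, Protomer, kabsch_rmsd
from crossbeta.restraints import (
    DihedralRestraint,
    RestraintError,
    RestraintSet,
)

# Small ladder for unit tests; the full published ladder runs in the
# acceptance suite.
FAST = dict(t_start=800.0, t_end=25.0, decrement=25.0,
            steps_per_temperature=6, polish_cycles=1, quench_sweeps=40,
            temperature_scale=0.125)


def dihedral_only_restraints():
    rs = RestraintSet()
    for r in (2, 3):
        rs.add(DihedralRestraint(r, "phi", -120.0, 15.0))
        rs.add(DihedralRestraint(r, "psi", 130.0, 15.0))
    return rs


class TestSchedule:
    def test_published_ladder_shape(self):
        s = AnnealSchedule(extra_cold_levels=0, polish_cycles=0)
        temps = s.temperatures()
        assert temps[0] == 4000.0
        assert temps[-1] == 25.0
        assert len(temps) == 319
        assert np.allclose(np.diff(temps), -12.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t_start=10.0, t_end=25.0)
        with pytest.raises(ValueError):
            AnnealSchedule(decrement=0.0)
        with pytest.raises(ValueError):
            AnnealSchedule(round="bogus")


class TestFold:
    def test_refuses_unconstrained(self):
        with pytest.raises(RestraintError, match="refus"):
            fold("AVAL", RestraintSet(), AnnealSchedule(**FAST))

    def test_dihedral_targets_reached(self):
        ens = fold("AVAL", dihedral_only_restraints(),
                   AnnealSchedule(**FAST), n_structures=2, n_subunits=1)
        best = ens.best
        assert best.terms["dihedral"] == 0.0
        assert best.violations["n_violated"] == 0
        for r in (2, 3):
            assert abs(best.protomer.get_torsion(r, "phi") + 120.0) <= 15.0
            assert abs(best.protomer.get_torsion(r, "psi") - 130.0) <= 15.0

    def test_deterministic_replay(self):
        kw = dict(schedule=AnnealSchedule(**FAST), n_structures=2,
                  n_subunits=1, base_seed=11)
        e1 = fold("AVAL", dihedral_only_restraints(), **kw)
        e2 = fold("AVAL", dihedral_only_restraints(), **kw)
        assert np.array_equal(e1.energies(), e2.energies())
        assert np.allclose(e1.best.state, e2.best.state)

    def test_quench_is_monotone(self):
        ens = fold("AVAL", dihedral_only_restraints(),
                   AnnealSchedule(**FAST), n_structures=2, n_subunits=1)
        for m in ens:
            assert m.energy <= m.energy_before_quench + 1e-9

    def test_strict_symmetry_exact(self, mini_arch):
        protomer, rs = mini_arch
        ens = fold("AVGNQL", rs, AnnealSchedule(**FAST), n_structures=1,
                   n_subunits=3)
        model = ens.best.model(3, 4.75)
        # image copies are exact translations of the protomer
        for s in (1, 2):
            dev = model.subunit_coords(s) - model.subunit_coords(0) \
                - np.array([0.0, 0.0, 4.75 * s])
            assert np.abs(dev).max() < 1e-9

    def test_mini_arch_recovery_single_seed(self, mini_arch):
        protomer, rs = mini_arch
        ens = fold("AVGNQL", rs, AnnealSchedule(**FAST), n_structures=4,
                   n_subunits=1, base_seed=0)
        best = ens.best
        assert best.violations["n_violated"] == 0
        bb = [i for i, (_r, _t, n) in enumerate(protomer.atoms)
              if n in ("N", "CA", "C", "O")]
        rmsd = kabsch_rmsd(best.protomer.coords[bb], protomer.coords[bb])
        assert rmsd < 1.5


def _fake_member(seed, energy, torsion=180.0):
    p = Protomer("AVA")
    p.set_torsion(2, "phi", torsion)
    return FoldResult(seed=seed, energy=energy, terms={}, protomer=p,
                      state=np.zeros(1), violations={})


def _fake_ensemble(members):
    return EnsembleResult(list(members), AnnealSchedule(**FAST), 1, 4.75)


class TestSelection:
    def test_select_all_is_identity(self):
        ens = _fake_ensemble([_fake_member(0, 2.0), _fake_member(1, 1.0)])
        sel = select_best(ens, 2)
        assert [m.seed for m in sel] == [1, 0]

    def test_select_one_is_minimum(self):
        ens = _fake_ensemble([_fake_member(0, 2.0), _fake_member(1, 1.0),
                              _fake_member(2, 3.0)])
        assert select_best(ens, 1).best.seed == 1

    def test_tie_broken_by_seed(self):
        ens = _fake_ensemble([_fake_member(5, 1.0), _fake_member(2, 1.0)])
        assert [m.seed for m in select_best(ens, 2)] == [2, 5]

    def test_k_validation(self):
        ens = _fake_ensemble([_fake_member(0, 1.0)])
        with pytest.raises(ValueError):
            select_best(ens, 0)
        with pytest.raises(ValueError):
            select_best(ens, 2)

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            _fake_ensemble([_fake_member(0, float("nan"))])


class TestMedoid:
    def test_single_member(self):
        ens = _fake_ensemble([_fake_member(0, 1.0)])
        assert medoid(ens) is ens.members[0]

    def test_two_members_tie_goes_to_lower_energy(self):
        ens = _fake_ensemble([_fake_member(0, 1.0, -120.0),
                              _fake_member(1, 2.0, -100.0)])
        assert medoid(ens).energy == 1.0

    def test_outlier_excluded_matches_brute_force(self):
        members = [_fake_member(0, 1.0, -120.0),
                   _fake_member(1, 2.0, -118.0),
                   _fake_member(2, 3.0, 60.0)]  # outlier
        ens = _fake_ensemble(members)
        med = medoid(ens)
        # brute force: summed pairwise backbone RMSD
        bb = [i for i, (_r, _t, n) in enumerate(members[0].protomer.atoms)
              if n in ("N", "CA", "C", "O")]
        coords = [m.protomer.coords[bb] for m in members]
        totals = [sum(kabsch_rmsd(coords[i], coords[j])
                      for j in range(3) if j != i) for i in range(3)]
        assert med is members[int(np.argmin(totals))]
        assert med.seed in (0, 1)


class TestTwoRound:
    def test_keep_validation(self, mini_arch):
        _p, rs = mini_arch
        with pytest.raises(ValueError, match="exceed"):
            two_round_protocol("AVGNQL", rs, counts=(2, 2), keep=(3, 1),
                               schedule=AnnealSchedule(**FAST))

    def test_warm_start_improves_energy(self, mini_arch):
        _p, rs = mini_arch
        out = two_round_protocol("AVGNQL", rs, None, counts=(4, 4),
                                 keep=(2, 2),
                                 schedule=AnnealSchedule(**FAST),
                                 n_subunits=1, base_seed=3)
        assert out["final"].best.energy <= out["round1"].best.energy + 1e-9
        assert len(out["final"]) == 2
        assert out["medoid"] in out["final"].members

    def test_replay_identical(self, mini_arch):
        _p, rs = mini_arch
        kw = dict(counts=(2, 2), keep=(1, 1),
                  schedule=AnnealSchedule(**FAST), n_subunits=1,
                  base_seed=5)
        o1 = two_round_protocol("AVGNQL", rs, None, **kw)
        o2 = two_round_protocol("AVGNQL", rs, None, **kw)
        assert np.array_equal(o1["round2"].energies(),
                              o2["round2"].energies())


class TestEnsembleOutput:
    def test_multi_model_pdb_and_energy_table(self, mini_arch, tmp_path):
        _p, rs = mini_arch
        ens = fold("AVGNQL", rs, AnnealSchedule(**FAST), n_structures=2,
                   n_subunits=1)
        path = tmp_path / "ens.pdb"
        ens.to_pdb(path)
        text = path.read_text()
        assert text.count("MODEL") >= 2
        table = (tmp_path / "ens.pdb.energies.tsv").read_text()
        assert table.splitlines()[0].startswith("model\tseed\tenergy")
        assert len(table.splitlines()) == 3
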