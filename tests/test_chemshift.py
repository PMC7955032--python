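"""Secondary shifts, strand calling, and prediction consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossbeta.chemshift import (
    DihedralPrediction,
    RandomCoilTable,
    ShiftDataError,
    ShiftTable,
    call_strands,
    merge_dihedral_predictions,
    read_talos_predictions,
    secondary_shift,
)


def make_table(rc, sequence, start=1, offsets=None):
    """Observed shifts at random coil plus per-residue (dCa, dCb) offsets."""
    offsets = offsets or {}
    rows = []
    for i, code in enumerate(sequence):
        resnum = start + i
        d_ca, d_cb = offsets.get(resnum, (0.0, 0.0))
        rows.append((resnum, code, "CA", rc.ca[code] + d_ca))
        if code != "G":
            rows.append((resnum, code, "CB", rc.cb[code] + d_cb))
    return ShiftTable(rows, sequence=sequence, start_number=start)


class TestSecondaryShift:
    def test_random_coil_gives_zero(self, rc_table):
        t = make_table(rc_table, "AVGNQLY")
        d = secondary_shift(t, rc_table)
        assert len(d) == 7
        assert (d.abs() < 1e-12).all()

    def test_beta_offsets_give_minus_four(self, rc_table):
        t = make_table(rc_table, "AVANQ", offsets={3: (-2.0, 2.0)})
        d = secondary_shift(t, rc_table)
        assert d[3] == pytest.approx(-4.0)

    def test_glycine_uses_ca_only_negative_in_beta(self, rc_table):
        t = make_table(rc_table, "AGA", offsets={2: (-2.0, 0.0)})
        d = secondary_shift(t, rc_table)
        assert d[2] == pytest.approx(-2.0)  # negative still flags beta

    def test_missing_ca_residue_omitted(self, rc_table):
        rows = [(1, "A", "CA", rc_table.ca["A"]),
                (1, "A", "CB", rc_table.cb["A"]),
                (2, "V", "CB", rc_table.cb["V"])]
        d = secondary_shift(ShiftTable(rows), rc_table)
        assert list(d.index) == [1]

    def test_referencing_offset_invariance(self, rc_table):
        """Adding a constant to all Ca shifts of both the observed table
        and the reference leaves the secondary shift unchanged."""
        t1 = make_table(rc_table, "AVNQ", offsets={2: (-2.0, 2.0)})
        shifted_rc = RandomCoilTable(
            {k: v + 1.7 for k, v in rc_table.ca.items()}, rc_table.cb)
        rows = [(r.residue_number, r.residue_type, r.atom,
                 r.shift + (1.7 if r.atom == "CA" else 0.0))
                for r in t1.df.itertuples()]
        t2 = ShiftTable(rows)
        d1 = secondary_shift(t1, rc_table)
        d2 = secondary_shift(t2, shifted_rc)
        assert np.allclose(d1.values, d2.values)

    def test_unknown_residue_type_rejected(self, rc_table):
        t = ShiftTable([(1, "X", "CA", 55.0)])
        with pytest.raises(ShiftDataError):
            secondary_shift(t, rc_table)


class TestShiftTableValidation:
    def test_duplicate_shift_rejected(self):
        with pytest.raises(ShiftDataError, match="duplicate"):
            ShiftTable([(1, "A", "CA", 52.0), (1, "A", "CA", 53.0)])

    def test_carbon_window(self):
        with pytest.raises(ShiftDataError, match="window"):
            ShiftTable([(1, "A", "CA", 250.0)])

    def test_nitrogen_window(self):
        with pytest.raises(ShiftDataError, match="window"):
            ShiftTable([(1, "A", "N", 50.0)])

    def test_residue_outside_construct(self):
        with pytest.raises(ShiftDataError, match="outside"):
            ShiftTable([(99, "A", "CA", 52.0)], sequence="AVA",
                       start_number=1)

    def test_tsv_round_trip(self, rc_table, tmp_path):
        t = make_table(rc_table, "AVGNQ", offsets={2: (-2.0, 2.0)})
        path = tmp_path / "shifts.tsv"
        t.to_tsv(path)
        t2 = ShiftTable.from_tsv(path)
        pd.testing.assert_frame_equal(t.df, t2.df)

    def test_nmrstar_round_trip(self, rc_table):
        t = make_table(rc_table, "AVGNQ", offsets={2: (-2.0, 2.0)})
        t2 = ShiftTable.from_nmrstar(t.to_nmrstar())
        assert len(t2) == len(t)
        d1 = secondary_shift(t, rc_table)
        d2 = secondary_shift(t2, rc_table)
        assert np.allclose(d1.values, d2.values, atol=1e-3)


class TestCallStrands:
    def test_all_positive_empty(self):
        s = pd.Series({i: 1.0 for i in range(1, 10)})
        assert call_strands(s) == []

    def test_below_min_len_dropped(self):
        assert call_strands(pd.Series({1: -1.0, 2: -1.0, 3: 1.0})) == []

    def test_gap_breaks_runs(self):
        s = pd.Series({1: -1.0, 2: -1.0, 3: -1.0, 5: -1.0, 6: -1.0,
                       7: -1.0})
        assert call_strands(s) == [(1, 3), (5, 7)]

    def test_empty_series(self):
        assert call_strands(pd.Series(dtype=float)) == []

    def test_threshold_is_strict(self):
        s = pd.Series({1: -1.0, 2: 0.0, 3: -1.0})
        assert call_strands(s, min_len=2) == []

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            call_strands(pd.Series({1: -1.0}), min_len=1)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=0,
                    max_size=40))
    def test_segments_sorted_disjoint_negative(self, values):
        s = pd.Series({i + 10: v for i, v in enumerate(values)})
        segs = call_strands(s)
        prev_end = -1
        for (a, b) in segs:
            assert b - a + 1 >= 3
            assert a > prev_end
            prev_end = b
            assert all(s[r] < 0.0 for r in range(a, b + 1))


class TestMergePredictions:
    def test_identity(self):
        a = [DihedralPrediction(5, "phi", -120.0, 10.0, "a")]
        b = [DihedralPrediction(5, "phi", -120.0, 10.0, "b")]
        (m,) = merge_dihedral_predictions(a, b)
        assert m.center == -120.0 and m.half_width == 10.0

    def test_disagreement_dropped(self):
        a = [DihedralPrediction(5, "phi", -120.0, 10.0, "a")]
        b = [DihedralPrediction(5, "phi", -150.0, 10.0, "b")]
        assert merge_dihedral_predictions(a, b) == []

    def test_uncertainty_expansion(self):
        a = [DihedralPrediction(5, "phi", -120.0, 10.0, "a")]
        b = [DihedralPrediction(5, "phi", -130.0, 8.0, "b")]
        (m,) = merge_dihedral_predictions(a, b)
        assert m.center == -120.0
        assert m.half_width == pytest.approx(15.0)
        assert abs(-130.0 - m.center) <= m.half_width

    def test_circular_difference(self):
        a = [DihedralPrediction(5, "psi", 175.0, 10.0, "a")]
        b = [DihedralPrediction(5, "psi", -175.0, 10.0, "b")]
        (m,) = merge_dihedral_predictions(a, b)  # 10 deg apart on circle
        assert m.half_width == pytest.approx(15.0)

    def test_one_sided_dropped(self):
        a = [DihedralPrediction(5, "phi", -120.0, 10.0, "a"),
             DihedralPrediction(6, "phi", -120.0, 10.0, "a")]
        b = [DihedralPrediction(5, "phi", -120.0, 10.0, "b")]
        out = merge_dihedral_predictions(a, b)
        assert [m.residue for m in out] == [5]

    def test_duplicate_in_one_set_rejected(self):
        a = [DihedralPrediction(5, "phi", -120.0, 10.0, "a"),
             DihedralPrediction(5, "phi", -121.0, 10.0, "a")]
        with pytest.raises(ShiftDataError, match="duplicate"):
            merge_dihedral_predictions(a, [])

    @settings(deadline=None, max_examples=60)
    @given(va=st.floats(-179.9, 180.0), d=st.floats(-20.0, 20.0),
           ua=st.floats(0.5, 40.0), ub=st.floats(0.5, 40.0))
    def test_bounds_always_cover_both_inputs(self, va, d, ua, ub):
        vb = (va + d + 180.0) % 360.0 - 180.0
        if vb == -180.0:
            vb = 180.0
        a = [DihedralPrediction(1, "phi", va, ua, "a")]
        b = [DihedralPrediction(1, "phi", vb, ub, "b")]
        (m,) = merge_dihedral_predictions(a, b)
        for v in (va, vb):
            diff = abs((v - m.center + 180.0) % 360.0 - 180.0)
            assert diff <= m.half_width + 1e-9


class TestTalosReader:
    TABLE = """DATA FIRST_RESID 441
VARS RESID RESNAME PHI PSI DPHI DPSI DIST S2 COUNT CS_COUNT CLASS
FORMAT %4d %s %8.3f %8.3f %8.3f %8.3f %8.3f %5.3f %2d %2d %s
441 V -122.000 131.000 14.0 12.0 0.0 0.9 25 10 Strong
442 F 9999.000 9999.000 0.0 0.0 0.0 0.9 25 10 None
443 N -115.000 128.000 11.0 15.0 0.0 0.9 25 10 Good
"""

    def test_reads_angles_and_skips_none(self):
        preds = read_talos_predictions(self.TABLE, source_tag="talosn")
        keys = {(p.residue_number, p.angle_name) for p in preds}
        assert keys == {(441, "phi"), (441, "psi"), (443, "phi"),
                        (443, "psi")}
        phi441 = next(p for p in preds
                      if (p.residue_number, p.angle_name) == (441, "phi"))
        assert phi441.value == -122.0 and phi441.uncertainty == 14.0
        assert phi441.source == "talosn"

    def test_class_filter(self):
        preds = read_talos_predictions(self.TABLE,
                                       keep_classes={"Strong"})
        assert {p.residue_number for p in preds} == {441}
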