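"""Secondary chemical shifts, beta-strand calling, and dihedral-prediction
consensus.

The secondary chemical shift used here is the per-residue difference

    Delta = (dCa_obs - dCa_rc) - (dCb_obs - dCb_rc)

between the observed Ca/Cb shifts and their random-coil reference values;
negative Delta indicates beta-strand conformation.  Maximal runs of
consecutive negative residues of at least ``min_len`` are called as
strands.  Torsion-angle predictions from two independent predictors are
merged by a consensus rule: only (residue, angle) pairs on which both
sources agree within a tolerance (default 20 degrees on the circle) are
kept, with the uncertainty widened so both predictions lie inside the
resulting bound.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .restraints import DihedralRestraint

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftTable",
    "RandomCoilTable",
    "DihedralPrediction",
    "secondary_shift",
    "call_strands",
    "merge_dihedral_predictions",
    "read_talos_predictions",
]

_CARBON_WINDOW = (0.0, 190.0)
_NITROGEN_WINDOW = (90.0, 140.0)


class ShiftDataError(ValueError):
    pass


# --------------------------------------------------------------------------
# Shift tables
# --------------------------------------------------------------------------

class ShiftTable:
    """Per-residue, per-atom chemical shifts.

    Backed by a DataFrame with columns ``residue_number`` (int),
    ``residue_type`` (1-letter code), ``atom`` (CA, CB, CO, N, ...) and
    ``shift`` (ppm).  At most one shift per (residue, atom); shifts must
    sit in plausible ppm windows (carbon 0-190, nitrogen 90-140).
    """

    COLUMNS = ["residue_number", "residue_type", "atom", "shift"]

    def __init__(self, rows, sequence=None, start_number=None):
        df = pd.DataFrame(rows, columns=self.COLUMNS)
        df["residue_number"] = df["residue_number"].astype(int)
        df["residue_type"] = df["residue_type"].str.upper()
        df["atom"] = df["atom"].str.upper().replace({"C'": "CO"})
        df["shift"] = df["shift"].astype(float)
        dup = df.duplicated(subset=["residue_number", "atom"])
        if dup.any():
            bad = df[dup].iloc[0]
            raise ShiftDataError(
                f"duplicate shift for residue {bad.residue_number} atom "
                f"{bad.atom}")
        carbons = df["atom"].str.startswith(("C",))
        nitro = df["atom"].str.startswith("N")
        if ((df.loc[carbons, "shift"] < _CARBON_WINDOW[0]).any()
                or (df.loc[carbons, "shift"] > _CARBON_WINDOW[1]).any()):
            raise ShiftDataError("carbon shift outside the 0-190 ppm window")
        if ((df.loc[nitro, "shift"] < _NITROGEN_WINDOW[0]).any()
                or (df.loc[nitro, "shift"] > _NITROGEN_WINDOW[1]).any()):
            raise ShiftDataError("nitrogen shift outside the 90-140 ppm window")
        if sequence is not None and start_number is not None:
            lo, hi = start_number, start_number + len(sequence) - 1
            out = ~df["residue_number"].between(lo, hi)
            if out.any():
                raise ShiftDataError(
                    f"residue numbers outside construct range {lo}-{hi}: "
                    f"{sorted(df.loc[out, 'residue_number'].unique())}")
        self.df = df.sort_values(["residue_number", "atom"]).reset_index(drop=True)
        self.sequence = sequence
        self.start_number = start_number

    def __len__(self):
        return len(self.df)

    def get(self, residue_number, atom):
        atom = atom.upper()
        sel = self.df[(self.df.residue_number == residue_number)
                      & (self.df.atom == atom)]
        return float(sel["shift"].iloc[0]) if len(sel) else None

    def residue_types(self):
        return dict(zip(self.df.residue_number, self.df.residue_type))

    def residues(self):
        return sorted(self.df.residue_number.unique())

    # -- TSV ---------------------------------------------------------------
    def to_tsv(self, path=None):
        buf = io.StringIO()
        buf.write("# crossbeta shift table (ppm)\n")
        self.df.to_csv(buf, sep="\t", index=False)
        text = buf.getvalue()
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, source, **kw):
        if hasattr(source, "read") or "\n" in str(source):
            df = pd.read_csv(io.StringIO(source) if isinstance(source, str)
                             else source, sep="\t", comment="#")
        else:
            df = pd.read_csv(source, sep="\t", comment="#")
        return cls(df[cls.COLUMNS], **kw)

    # -- NMR-STAR ----------------------------------------------------------
    def to_nmrstar(self, path=None, entry_id="crossbeta"):
        """Write a minimal NMR-STAR file holding one Atom_chem_shift loop."""
        lines = [
            f"data_{entry_id}",
            "",
            "save_assigned_chemical_shifts",
            "   _Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts",
            "   loop_",
            "      _Atom_chem_shift.ID",
            "      _Atom_chem_shift.Seq_ID",
            "      _Atom_chem_shift.Comp_ID",
            "      _Atom_chem_shift.Atom_ID",
            "      _Atom_chem_shift.Val",
        ]
        from .fibril_model import THREE_LETTER
        for i, row in enumerate(self.df.itertuples(), start=1):
            comp = THREE_LETTER.get(row.residue_type, row.residue_type)
            atom = "C" if row.atom == "CO" else row.atom
            lines.append(f"      {i} {row.residue_number} {comp} {atom} "
                         f"{row.shift:.3f}")
        lines += ["   stop_", "save_", ""]
        text = "\n".join(lines)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_nmrstar(cls, source, **kw):
        """Read the Atom_chem_shift loop of an NMR-STAR file.

        Only the one loop is interpreted (tags ``Seq_ID``, ``Comp_ID``,
        ``Atom_ID``, ``Val``); this intentionally small reader covers BMRB
        chemical-shift interchange without a full STAR grammar.
        """
        text = source
        if "\n" not in str(source):
            with open(source) as fh:
                text = fh.read()
        from .fibril_model import ONE_LETTER
        lines = text.splitlines()
        tags, rows = [], []
        in_loop = in_body = False
        for line in lines:
            s = line.strip()
            if s == "loop_":
                tags, in_loop, in_body = [], True, False
                continue
            if in_loop and s.startswith("_"):
                tags.append(s.split(".")[-1])
                continue
            if in_loop and tags:
                if s in ("stop_", "save_") or s.startswith("_") is False and not s:
                    in_loop = in_body = False
                    if any(r for r in rows):
                        break
                    continue
                if "Atom_chem_shift" not in line and not any(
                        t in ("Seq_ID", "Atom_ID", "Val") for t in tags):
                    continue
                if s == "stop_":
                    in_loop = False
                    continue
                vals = s.split()
                if len(vals) == len(tags):
                    rows.append(dict(zip(tags, vals)))
                    in_body = True
        if not rows:
            raise ShiftDataError("no Atom_chem_shift loop found")
        out = []
        for r in rows:
            comp = r.get("Comp_ID", "X")
            code = ONE_LETTER.get(comp.upper(), comp[:1].upper())
            atom = r.get("Atom_ID", "").upper()
            if atom == "C":
                atom = "CO"
            out.append((int(r["Seq_ID"]), code, atom, float(r["Val"])))
        return cls(out, **kw)


class RandomCoilTable:
    """Per-residue-type random-coil Ca/Cb reference shifts (ppm).

    The bundled default is a published peptide random-coil compilation
    (see the header of ``data/random_coil_shifts.tsv``); any table with the
    same layout can be supplied instead.  All 20 residue types must be
    present; glycine carries no Cb entry.
    """

    def __init__(self, ca: dict, cb: dict):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(ca)
        if missing:
            raise ShiftDataError(f"random-coil table missing {sorted(missing)}")
        if "G" in cb:
            raise ShiftDataError("glycine must not carry a Cb reference")
        self.ca = dict(ca)
        self.cb = dict(cb)

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", comment="#")
        ca, cb = {}, {}
        for row in df.itertuples():
            ca[row.residue] = float(row.ca)
            if str(row.cb) != "-":
                cb[row.residue] = float(row.cb)
        return cls(ca, cb)

    @classmethod
    def bundled(cls):
        ref = resources.files("crossbeta.data") / "random_coil_shifts.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


# --------------------------------------------------------------------------
# Secondary shifts and strand calling
# --------------------------------------------------------------------------

def secondary_shift(table: ShiftTable, rc: RandomCoilTable | None = None):
    """Per-residue secondary-shift difference Delta (ppm), negative in
    beta-strands.

    Delta = (dCa_obs - dCa_rc) - (dCb_obs - dCb_rc).  Glycine, which has
    no Cb, contributes its Ca secondary shift alone (already negative in
    beta-strands, so the sign convention is unchanged).  Residues without
    a Ca shift are omitted with a logged note.  Returns a Series indexed
    by residue number.
    """
    rc = rc or RandomCoilTable.bundled()
    types = table.residue_types()
    out = {}
    for resnum in table.residues():
        rtype = types[resnum]
        if rtype not in rc.ca:
            raise ShiftDataError(
                f"residue type {rtype!r} absent from the random-coil table")
        ca = table.get(resnum, "CA")
        if ca is None:
            logger.info("residue %d has no Ca shift; omitted", resnum)
            continue
        d_ca = ca - rc.ca[rtype]
        if rtype == "G":
            out[resnum] = d_ca
            continue
        cb = table.get(resnum, "CB")
        if cb is None:
            logger.info("residue %d (%s) has no Cb shift; omitted",
                        resnum, rtype)
            continue
        out[resnum] = d_ca - (cb - rc.cb[rtype])
    return pd.Series(out, name="delta_ca_cb").sort_index()


def call_strands(delta, min_len=3, threshold=0.0):
    """Call beta-strand segments from a secondary-shift series.

    Returns maximal runs of consecutive assigned residues with
    ``Delta < threshold`` and length >= ``min_len`` as a sorted list of
    ``(start_residue, end_residue)`` tuples.  Unassigned residue numbers
    break runs.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if delta is None or len(delta) == 0:
        return []
    s = pd.Series(delta).sort_index()
    segments = []
    run_start = prev = None

    def close_run():
        if run_start is not None and prev - run_start + 1 >= min_len:
            segments.append((run_start, prev))

    for resnum, val in s.items():
        neg = val < threshold
        contiguous = prev is not None and resnum == prev + 1
        if neg and run_start is not None and contiguous:
            prev = resnum
        elif neg:
            close_run()
            run_start = prev = resnum
        else:
            close_run()
            run_start = None
            prev = resnum
    close_run()
    return segments


# --------------------------------------------------------------------------
# Dihedral predictions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralPrediction:
    residue_number: int
    angle_name: str  # phi, psi, chi1, chi2
    value: float     # degrees in (-180, 180]
    uncertainty: float
    source: str = ""

    def __post_init__(self):
        if not -180.0 < self.value <= 180.0:
            raise ShiftDataError(
                f"angle value {self.value} outside (-180, 180]")
        if self.uncertainty <= 0:
            raise ShiftDataError("uncertainty must be positive")


def _circular_diff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


def merge_dihedral_predictions(a, b, agreement_tol=20.0):
    """Two-source dihedral consensus.

    For every (residue, angle) present in both sets with circular
    disagreement <= ``agreement_tol``, emit a :class:`DihedralRestraint`
    centred on the primary source's value with the uncertainty expanded to
    cover both predictions:
    ``half_width = max(u_a, u_b, d/2 + max(u_a, u_b), d)`` where ``d`` is
    the circular difference.  Pairs disagreeing by more than the tolerance,
    or present in only one set, are dropped (logged).
    """

    def index(preds, tag):
        out = {}
        for p in preds:
            key = (p.residue_number, p.angle_name)
            if key in out:
                raise ShiftDataError(
                    f"duplicate prediction for {key} in set {tag}")
            out[key] = p
        return out

    ia = index(a, "a")
    ib = index(b, "b")
    merged = []
    for key in sorted(ia):
        if key not in ib:
            logger.info("prediction %s only in primary set; dropped", key)
            continue
        pa, pb = ia[key], ib[key]
        d = _circular_diff(pa.value, pb.value)
        if d > agreement_tol:
            logger.info("prediction %s disagrees by %.1f deg; dropped",
                        key, d)
            continue
        half = max(pa.uncertainty, pb.uncertainty,
                   d / 2.0 + max(pa.uncertainty, pb.uncertainty), d)
        merged.append(DihedralRestraint(key[0], key[1], pa.value, half))
    for key in ib:
        if key not in ia:
            logger.info("prediction %s only in secondary set; dropped", key)
    return merged


_TALOS_ANGLE_COLS = {"PHI": "phi", "PSI": "psi", "CHI1": "chi1",
                     "CHI2": "chi2"}


def read_talos_predictions(source, source_tag="talos", keep_classes=None):
    """Read a TALOS-style whitespace-separated prediction table.

    Expected layout: a ``VARS`` line naming columns (RESID, RESNAME, PHI,
    PSI, DPHI, DPSI, ... CLASS) followed by a ``FORMAT`` line and data
    rows; bare whitespace tables with a header row are also accepted.
    Angles of 9999 (TALOS "no prediction") and rows whose CLASS is in
    ``{'None'}`` (or not in ``keep_classes`` when given) are skipped.
    Returns a list of :class:`DihedralPrediction`.
    """
    text = source
    if "\n" not in str(source):
        with open(source) as fh:
            text = fh.read()
    cols = None
    rows = []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "REMARK", "DATA", "FORMAT")):
            continue
        if s.startswith("VARS"):
            cols = s.split()[1:]
            continue
        parts = s.split()
        if cols is None:
            if re.match(r"^[A-Za-z]", parts[0]):
                cols = parts
                continue
            raise ShiftDataError("prediction table has no column header")
        rows.append(parts)
    if cols is None:
        raise ShiftDataError("empty prediction table")
    cols = [c.upper() for c in cols]
    preds = []
    for parts in rows:
        rec = dict(zip(cols, parts))
        klass = rec.get("CLASS", "Good")
        if klass == "None":
            continue
        if keep_classes is not None and klass not in keep_classes:
            continue
        resid = int(rec["RESID"])
        for col, angle in _TALOS_ANGLE_COLS.items():
            if col not in rec:
                continue
            val = float(rec[col])
            if abs(val) > 360.0:
                continue
            if val <= -180.0:
                val += 360.0
            unc = float(rec.get("D" + col, 20.0))
            if unc <= 0:
                unc = 20.0
            preds.append(DihedralPrediction(resid, angle, val, unc,
                                            source_tag))
    return preds
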