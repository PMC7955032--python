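"""Distance, dihedral and hydrogen-bond restraints for fibril calculation.

Houses the restraint types, a parser for printed SSNMR contact lists
(tokens like ``V441Cγ−G451Cα``), a generator for parallel in-register
intermolecular restraints (same-atom carbon-carbon stacking at the
cross-beta rise plus explicit backbone hydrogen bonds), and a flat-bottom
violation/energy report for coordinates.

Distance bounds follow the experiment class they derive from: carbon-carbon
contacts from long-mixing DARR spectra carry 5.5 +/- 1.5 A, nitrogen-
involving contacts from 6.4 ms TEDOR carry 4.5 +/- 2.5 A, ambiguous
refinement-round contacts carry 5.5 +/- 2.5 A, and in-register stacking
carries 4.75 +/- 0.1 A.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fibril_model import FibrilModel, VALID_ATOMS, dihedral as _dihedral

__all__ = [
    "AtomRef",
    "DistanceRestraint",
    "HBondRestraint",
    "DihedralRestraint",
    "RestraintSet",
    "parse_contact_list",
    "make_inregister_restraints",
    "violation_report",
    "UNAMBIGUOUS_CONTACTS",
    "INREGISTER_REGISTRY",
    "INREGISTER_HBOND_PAIRS",
    "DARR_BOUNDS",
    "TEDOR_BOUNDS",
    "AMBIGUOUS_BOUNDS",
]

# Printed unambiguous non-sequential contact list (ten contacts); the
# Q449Cδ entry pairs with both L456Cβ and L456Cγ as two separate restraints.
UNAMBIGUOUS_CONTACTS = (
    "V441Cγ−G451Cα, S446Cβ−V448Cβ, Q449Cδ−L456Cβ, Q449Cδ−L456Cγ, "
    "I450Cγ2−N452Cα, G451Cα−N454Nδ2, N452Cα−N454Cα, N452Cβ−N454Cα, "
    "Y453Cβ−S455Cβ, L456Cγ−Q449Nε2"
)

# Registry atoms stacked at the cross-beta rise between adjacent subunits.
INREGISTER_REGISTRY = ((444, "CB"), (448, "CB"), (455, "CO"))

# Explicit inter-subunit backbone hydrogen bonds (donor residue amide,
# acceptor residue carbonyl).  The (451, 450) pair is kept exactly as
# printed in the source protocol even though the residue-type labels there
# (I451/G450) conflict with the numbering used elsewhere (I450/G451); the
# restraint is defined by residue numbers and backbone atoms, so it is
# well-formed either way.
INREGISTER_HBOND_PAIRS = ((444, 443), (445, 444), (449, 448), (451, 450),
                          (456, 455))

DARR_BOUNDS = (5.5, 1.5, 1.5)      # target, lower margin, upper margin (A)
TEDOR_BOUNDS = (4.5, 2.5, 2.5)
AMBIGUOUS_BOUNDS = (5.5, 2.5, 2.5)
INREGISTER_BOUNDS = (4.75, 0.1, 0.1)
HBOND_H_O = (2.3, 0.1, 0.1)
HBOND_N_O = (3.3, 0.1, 0.1)

DEFAULT_FORCE_K = 50.0  # energy units per A^2 outside the flat bottom


class RestraintError(ValueError):
    pass


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRef:
    """Reference to one atom: residue number, PDB-style atom name, and the
    subunit offset along the fibril (0 = same molecule, +/-1 = adjacent)."""

    residue_number: int
    atom_name: str
    subunit_offset: int = 0

    def __post_init__(self):
        object.__setattr__(self, "atom_name",
                           "C" if self.atom_name == "CO" else self.atom_name)
        if self.subunit_offset not in (-1, 0, 1):
            raise RestraintError(
                f"subunit offset {self.subunit_offset} outside {{-1, 0, +1}}")

    def __str__(self):
        off = {0: "", 1: "'", -1: '"'}[self.subunit_offset]
        return f"{self.residue_number}{self.atom_name}{off}"


@dataclass(frozen=True)
class DistanceRestraint:
    a: AtomRef
    b: AtomRef
    target: float
    lower_margin: float
    upper_margin: float
    ambiguity_group: str | None = None
    rclass: str = "unambiguous"
    adjacent_either_side: bool = False

    def __post_init__(self):
        if self.target <= 0:
            raise RestraintError("distance target must be positive")
        if self.lower_margin <= 0 or self.upper_margin <= 0:
            raise RestraintError("margins must be positive")
        valid = {"unambiguous", "low_ambiguity", "high_ambiguity",
                 "intermolecular", "hbond_component"}
        if self.rclass not in valid:
            raise RestraintError(f"unknown restraint class {self.rclass!r}")

    @property
    def intramolecular(self):
        return self.a.subunit_offset == self.b.subunit_offset

    @property
    def bounds(self):
        return (self.target - self.lower_margin, self.target + self.upper_margin)


@dataclass(frozen=True)
class HBondRestraint:
    """Inter-subunit hydrogen bond: amide (N, H) of the donor residue to
    carbonyl (C', O) of the acceptor residue on an adjacent subunit.  The
    ladder repeats on every interface; which side (s+1 or s-1) a given
    donor points to depends on the pleat, so violations are evaluated
    against the nearer adjacent image."""

    donor_residue: int
    acceptor_residue: int
    donor_n: str = "N"
    donor_h: str = "H"
    acceptor_c: str = "C"
    acceptor_o: str = "O"
    h_o_target: float = HBOND_H_O[0]
    h_o_margin: float = HBOND_H_O[1]
    n_o_target: float = HBOND_N_O[0]
    n_o_margin: float = HBOND_N_O[1]

    def components(self):
        """Expand to the two distance restraints (H...O and N...O)."""
        return (
            DistanceRestraint(
                AtomRef(self.donor_residue, self.donor_h, 0),
                AtomRef(self.acceptor_residue, self.acceptor_o, 1),
                self.h_o_target, self.h_o_margin, self.h_o_margin,
                rclass="hbond_component", adjacent_either_side=True),
            DistanceRestraint(
                AtomRef(self.donor_residue, self.donor_n, 0),
                AtomRef(self.acceptor_residue, self.acceptor_o, 1),
                self.n_o_target, self.n_o_margin, self.n_o_margin,
                rclass="hbond_component", adjacent_either_side=True),
        )


@dataclass(frozen=True)
class DihedralRestraint:
    residue: int
    angle_name: str  # phi, psi, chi1..chi4
    center: float
    half_width: float

    def __post_init__(self):
        if self.half_width <= 0:
            raise RestraintError("half_width must be positive")


@dataclass
class RestraintSet:
    distance: list = field(default_factory=list)
    hbond: list = field(default_factory=list)
    dihedral: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __len__(self):
        return len(self.distance) + len(self.hbond) + len(self.dihedral)

    def add(self, r, note=None):
        if isinstance(r, DistanceRestraint):
            key = frozenset([(r.a.residue_number, r.a.atom_name, r.a.subunit_offset),
                             (r.b.residue_number, r.b.atom_name, r.b.subunit_offset)])
            for other in self.distance:
                okey = frozenset([
                    (other.a.residue_number, other.a.atom_name, other.a.subunit_offset),
                    (other.b.residue_number, other.b.atom_name, other.b.subunit_offset)])
                if okey == key and other.rclass == r.rclass:
                    raise RestraintError(f"duplicate distance restraint {r.a}-{r.b}")
            self.distance.append(r)
        elif isinstance(r, HBondRestraint):
            self.hbond.append(r)
        elif isinstance(r, DihedralRestraint):
            self.dihedral.append(r)
        else:
            raise TypeError(type(r))
        if note:
            self.provenance.append(note)

    def extend(self, other: "RestraintSet"):
        for r in other.distance:
            self.add(r)
        self.hbond.extend(other.hbond)
        self.dihedral.extend(other.dihedral)
        self.provenance.extend(other.provenance)
        return self

    def counts(self):
        return {"distance": len(self.distance), "hbond": len(self.hbond),
                "dihedral": len(self.dihedral)}

    # -- serialization -----------------------------------------------------
    _HEADER = ("# crossbeta restraint table\n"
               "# kind\tres_a\tatom_a\toff_a\tres_b\tatom_b\toff_b\t"
               "target\tlower\tupper\tgroup\tclass\tflags\n")

    def to_tsv(self, path=None):
        lines = [self._HEADER.rstrip("\n")]
        for r in self.distance:
            lines.append("\t".join(map(str, [
                "dist", r.a.residue_number, r.a.atom_name, r.a.subunit_offset,
                r.b.residue_number, r.b.atom_name, r.b.subunit_offset,
                f"{r.target:g}", f"{r.lower_margin:g}", f"{r.upper_margin:g}",
                r.ambiguity_group or "-", r.rclass,
                "adj" if r.adjacent_either_side else "-"])))
        for r in self.hbond:
            lines.append("\t".join(map(str, [
                "hbond", r.donor_residue, f"{r.donor_n}/{r.donor_h}", 0,
                r.acceptor_residue, f"{r.acceptor_c}/{r.acceptor_o}", 1,
                f"{r.h_o_target:g}", f"{r.h_o_margin:g}", f"{r.n_o_target:g}",
                f"{r.n_o_margin:g}", "hbond", "adj"])))
        for r in self.dihedral:
            lines.append("\t".join(map(str, [
                "dihedral", r.residue, r.angle_name, 0, "-", "-", "-",
                f"{r.center:g}", f"{r.half_width:g}", "-", "-", "dihedral",
                "-"])))
        text = "\n".join(lines) + "\n"
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, source):
        text = source
        if "\n" not in str(source):
            with open(source) as fh:
                text = fh.read()
        rs = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            kind = f[0]
            if kind == "dist":
                rs.add(DistanceRestraint(
                    AtomRef(int(f[1]), f[2], int(f[3])),
                    AtomRef(int(f[4]), f[5], int(f[6])),
                    float(f[7]), float(f[8]), float(f[9]),
                    None if f[10] == "-" else f[10], f[11],
                    adjacent_either_side=f[12] == "adj"))
            elif kind == "hbond":
                dn, dh = f[2].split("/")
                ac, ao = f[5].split("/")
                rs.add(HBondRestraint(
                    int(f[1]), int(f[4]), dn, dh, ac, ao,
                    float(f[7]), float(f[8]), float(f[9]), float(f[10])))
            elif kind == "dihedral":
                rs.add(DihedralRestraint(int(f[1]), f[2], float(f[7]),
                                         float(f[8])))
            else:
                raise RestraintError(f"unknown restraint kind {kind!r}")
        return rs

    def to_assign_statements(self):
        """Generic ``assign (atom) (atom) d dminus dplus`` text export."""
        out = []
        for r in self.distance:
            seg_a = f"(resid {r.a.residue_number} and name {r.a.atom_name})"
            seg_b = f"(resid {r.b.residue_number} and name {r.b.atom_name}"
            if r.b.subunit_offset:
                seg_b += f" and segid SUB{r.b.subunit_offset:+d}"
            seg_b += ")"
            out.append(f"assign {seg_a} {seg_b} "
                       f"{r.target:.2f} {r.lower_margin:.2f} {r.upper_margin:.2f}")
        for h in self.hbond:
            for r in h.components():
                seg_a = f"(resid {r.a.residue_number} and name {r.a.atom_name})"
                seg_b = (f"(resid {r.b.residue_number} and name {r.b.atom_name}"
                         f" and segid SUB+1)")
                out.append(f"assign {seg_a} {seg_b} "
                           f"{r.target:.2f} {r.lower_margin:.2f} "
                           f"{r.upper_margin:.2f}")
        for d in self.dihedral:
            out.append(f"assign dihedral resid {d.residue} {d.angle_name} "
                       f"{d.center:.1f} {d.half_width:.1f}")
        return "\n".join(out) + ("\n" if out else "")


# --------------------------------------------------------------------------
# Parsing printed contact lists
# --------------------------------------------------------------------------

_GREEK = {"α": "A", "β": "B", "γ": "G", "δ": "D", "ε": "E", "ζ": "Z",
          "η": "H"}

# Residue-specific resolution of Greek position labels that are degenerate
# in PDB nomenclature (branched side chains).  Branch 1 is used for a bare
# degenerate label; an explicit digit (e.g. Cγ2) is honoured.
_BRANCH_DEFAULT = {
    ("V", "CG"): "CG1", ("I", "CG"): "CG1", ("T", "CG"): "CG2",
    ("L", "CD"): "CD1", ("I", "CD"): "CD1",
    ("F", "CD"): "CD1", ("Y", "CD"): "CD1", ("F", "CE"): "CE1",
    ("Y", "CE"): "CE1", ("N", "OD"): "OD1", ("N", "ND"): "ND2",
    ("D", "OD"): "OD1", ("Q", "OE"): "OE1", ("Q", "NE"): "NE2",
    ("E", "OE"): "OE1", ("R", "NH"): "NH1",
}

_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Za-z][\w'α-ω]*)$")


def _normalize_atom(res_type: str, raw: str) -> str:
    name = "".join(_GREEK.get(ch, ch) for ch in raw).upper()
    if name == "CO":
        name = "C"
    if name not in VALID_ATOMS.get(res_type, frozenset()):
        name = _BRANCH_DEFAULT.get((res_type, name), name)
    if name not in VALID_ATOMS.get(res_type, frozenset()):
        raise RestraintError(
            f"atom {raw!r} is not valid for residue type {res_type}")
    return name


def parse_atom_token(token: str):
    """Parse ``V441Cγ`` -> (residue_type, residue_number, atom_name)."""
    token = token.strip()
    m = _TOKEN_RE.match(token)
    if not m:
        raise RestraintError(f"malformed atom token {token!r}")
    res_type, resnum, atom = m.group(1), int(m.group(2)), m.group(3)
    return res_type, resnum, _normalize_atom(res_type, atom)


def parse_contact_list(text: str, sequence=None, start_number=1) -> RestraintSet:
    """Parse a printed list of unambiguous inter-residue contacts.

    Pairs are ``ResidueNumberAtom`` tokens joined by a dash and separated
    by commas or "and".  Carbon-carbon pairs receive DARR bounds
    (5.5 +/- 1.5 A); pairs involving a nitrogen receive TEDOR bounds
    (4.5 +/- 2.5 A).  All contacts are intramolecular (subunit offset 0):
    with one molecule per cross-beta unit the observed correlations are
    within-molecule.  If ``sequence`` is given, token residue types are
    checked against it.
    """
    rs = RestraintSet()
    cleaned = re.sub(r"\band\b", ",", text)
    for dash in ("−", "–", "—"):
        cleaned = cleaned.replace(dash, "-")
    for item in cleaned.split(","):
        item = item.strip().rstrip(".")
        if not item:
            continue
        parts = [p for p in item.split("-") if p.strip()]
        if len(parts) != 2:
            raise RestraintError(f"malformed contact {item!r}")
        refs = []
        for tok in parts:
            res_type, resnum, atom = parse_atom_token(tok)
            if sequence is not None:
                i = resnum - start_number
                if not 0 <= i < len(sequence):
                    raise RestraintError(
                        f"residue {resnum} outside the sequence")
                if sequence[i].upper() != res_type:
                    raise RestraintError(
                        f"token {tok!r}: sequence has {sequence[i]} at "
                        f"{resnum}, not {res_type}")
            refs.append(AtomRef(resnum, atom, 0))
        a, b = refs
        if a.atom_name.startswith("N") or b.atom_name.startswith("N"):
            target, lo, up = TEDOR_BOUNDS
        else:
            target, lo, up = DARR_BOUNDS
        rs.add(DistanceRestraint(a, b, target, lo, up, rclass="unambiguous"),
               note=f"contact {item.strip()}")
    return rs


# --------------------------------------------------------------------------
# In-register intermolecular restraints
# --------------------------------------------------------------------------

def make_inregister_restraints(registry_atoms=INREGISTER_REGISTRY,
                               hbond_pairs=INREGISTER_HBOND_PAIRS,
                               rise=4.75, margin=0.1,
                               sequence=None, start_number=1) -> RestraintSet:
    """Parallel in-register stacking restraints for one subunit interface.

    Each registry atom is restrained between subunit s and s+1 at
    ``rise +/- margin`` (the same-atom stacking distance of a parallel
    in-register sheet); each hydrogen-bond pair adds an explicit
    inter-subunit amide-to-carbonyl H-bond with the standard H...O
    2.3 +/- 0.1 A and N...O 3.3 +/- 0.1 A bounds.  The set describes one
    interface; under strict symmetry it repeats on every interface of the
    model (``violation_report`` evaluates the representative interface).
    """
    if rise <= 0:
        raise RestraintError("rise must be positive")
    rs = RestraintSet()

    def check(resnum, atom):
        if sequence is None:
            return
        i = resnum - start_number
        if not 0 <= i < len(sequence):
            raise RestraintError(f"registry residue {resnum} outside sequence")
        code = sequence[i].upper()
        name = "C" if atom == "CO" else atom
        if name not in VALID_ATOMS[code]:
            raise RestraintError(
                f"registry atom {atom} missing for residue {resnum} ({code})")

    for resnum, atom in registry_atoms or ():
        check(resnum, atom)
        name = "C" if atom == "CO" else atom
        rs.add(DistanceRestraint(
            AtomRef(resnum, name, 0), AtomRef(resnum, name, 1),
            rise, margin, margin, rclass="intermolecular"),
            note=f"in-register {resnum}{atom} stacking")
    for donor, acceptor in hbond_pairs or ():
        check(donor, "N")
        check(acceptor, "C")
        rs.add(HBondRestraint(donor, acceptor),
               note=f"inter-subunit H-bond {donor}NH -> {acceptor}CO")
    return rs


# --------------------------------------------------------------------------
# Violation report
# --------------------------------------------------------------------------

def _flat_bottom(d, target, lo, up, k):
    if d < target - lo:
        v = (target - lo) - d
    elif d > target + up:
        v = d - (target + up)
    else:
        return 0.0, 0.0
    return v, k * v * v


def _resolve(model: FibrilModel, ref: AtomRef, base_subunit=0):
    s = base_subunit + ref.subunit_offset
    return model.get_atom(ref.residue_number, ref.atom_name, s)


def violation_report(model: FibrilModel, rs: RestraintSet,
                     force_k=DEFAULT_FORCE_K):
    """Score coordinates against a restraint set with flat-bottom wells.

    Energies are zero inside ``[target - lower, target + upper]`` and
    ``k * excess**2`` outside.  Ambiguity groups are combined into a single
    effective distance ``(sum r^-6)^(-1/6)``.  Dihedral violations are
    computed on the circle.  Under strict symmetry each restraint is
    evaluated once on the representative subunit/interface (subunit 0, and
    interface 0-1 for intermolecular terms); hydrogen-bond components
    marked adjacent-either-side use the nearer of the +/-1 images.

    Returns ``(table, totals)``: a DataFrame sorted by violation and a
    totals dict.
    """
    if model.n_subunits < 2:
        has_inter = any(r.a.subunit_offset != r.b.subunit_offset
                        for r in rs.distance) or bool(rs.hbond)
        if has_inter:
            raise RestraintError(
                "intermolecular restraints need a model with >= 2 subunits")
    rows = []

    def eval_pair(a_ref, b_ref, target, lo, up, either_side, label, rclass):
        base = 0
        if min(a_ref.subunit_offset, b_ref.subunit_offset) < 0:
            base = 1  # keep resolved subunits inside the model
        try:
            xa = _resolve(model, a_ref, base)
            xb = _resolve(model, b_ref, base)
        except (KeyError, IndexError) as exc:
            raise RestraintError(
                f"cannot resolve restraint {label}: {exc}") from exc
        d = float(np.linalg.norm(xa - xb))
        if either_side and a_ref.subunit_offset != b_ref.subunit_offset:
            mirrored = replace(b_ref, subunit_offset=-b_ref.subunit_offset)
            base2 = 1 if mirrored.subunit_offset < 0 else 0
            xa2 = _resolve(model, a_ref, base2)
            xb2 = _resolve(model, mirrored, base2)
            d = min(d, float(np.linalg.norm(xa2 - xb2)))
        return d

    # Ambiguity groups: effective r^-6 sum.
    groups: dict[str, list] = {}
    for r in rs.distance:
        if r.ambiguity_group:
            groups.setdefault(r.ambiguity_group, []).append(r)
    done_groups = set()
    for r in rs.distance:
        label = f"{r.a}-{r.b}"
        if r.ambiguity_group:
            if r.ambiguity_group in done_groups:
                continue
            done_groups.add(r.ambiguity_group)
            members = groups[r.ambiguity_group]
            inv6 = 0.0
            for m in members:
                d = eval_pair(m.a, m.b, m.target, m.lower_margin,
                              m.upper_margin, m.adjacent_either_side,
                              f"{m.a}-{m.b}", m.rclass)
                inv6 += d ** -6
            d_eff = inv6 ** (-1.0 / 6.0)
            v, e = _flat_bottom(d_eff, r.target, r.lower_margin,
                                r.upper_margin, force_k)
            rows.append(("distance", f"group:{r.ambiguity_group}", r.rclass,
                         d_eff, v, e))
            continue
        d = eval_pair(r.a, r.b, r.target, r.lower_margin, r.upper_margin,
                      r.adjacent_either_side, label, r.rclass)
        v, e = _flat_bottom(d, r.target, r.lower_margin, r.upper_margin,
                            force_k)
        rows.append(("distance", label, r.rclass, d, v, e))

    for h in rs.hbond:
        for comp, (target, margin) in zip(
                h.components(),
                ((h.h_o_target, h.h_o_margin), (h.n_o_target, h.n_o_margin))):
            label = f"{comp.a}-{comp.b}"
            d = eval_pair(comp.a, comp.b, target, margin, margin, True,
                          label, "hbond_component")
            v, e = _flat_bottom(d, target, margin, margin, force_k)
            rows.append(("hbond", label, "hbond_component", d, v, e))

    prot = model.protomer
    x = prot.coords
    for dr in rs.dihedral:
        resnum = dr.residue
        idx = prot.atom_index
        try:
            if dr.angle_name == "phi":
                pts = (idx(resnum - 1, "C"), idx(resnum, "N"),
                       idx(resnum, "CA"), idx(resnum, "C"))
            elif dr.angle_name == "psi":
                pts = (idx(resnum, "N"), idx(resnum, "CA"),
                       idx(resnum, "C"), idx(resnum + 1, "N"))
            elif dr.angle_name.startswith("chi"):
                chain = _chi_atom_chain(prot, resnum, int(dr.angle_name[3:]))
                pts = tuple(idx(resnum, n) for n in chain)
            else:
                raise RestraintError(f"unknown angle {dr.angle_name!r}")
        except KeyError as exc:
            raise RestraintError(
                f"cannot resolve dihedral {dr.angle_name} {resnum}: {exc}"
            ) from exc
        val = _dihedral(*(x[i] for i in pts))
        diff = (val - dr.center + 180.0) % 360.0 - 180.0
        v = max(0.0, abs(diff) - dr.half_width)
        e = force_k * (v * math.pi / 180.0) ** 2
        rows.append(("dihedral", f"{resnum}:{dr.angle_name}",
                     "dihedral", val, v, e))

    table = pd.DataFrame(
        rows, columns=["kind", "restraint", "class", "value", "violation",
                       "energy"])
    table = table.sort_values("violation", ascending=False,
                              kind="stable").reset_index(drop=True)
    totals = {
        "n": len(table),
        "n_violated": int((table["violation"] > 0).sum()),
        "max_violation": float(table["violation"].max()) if len(table) else 0.0,
        "energy": float(table["energy"].sum()),
    }
    return table, totals


_CHI_CHAINS = {
    1: ("N", "CA", "CB", None),
    2: ("CA", "CB", None, None),
    3: ("CB", None, None, None),
    4: (None, None, None, None),
}

# chi atom sequences per residue type: chain of heavy atoms from N along
# the side chain; chi_k is the dihedral over atoms [k-1 .. k+2].
_CHI_SEQUENCE = {
    "S": ["N", "CA", "CB", "OG"],
    "C": ["N", "CA", "CB", "SG"],
    "T": ["N", "CA", "CB", "OG1"],
    "V": ["N", "CA", "CB", "CG1"],
    "L": ["N", "CA", "CB", "CG", "CD1"],
    "I": ["N", "CA", "CB", "CG1", "CD1"],
    "F": ["N", "CA", "CB", "CG", "CD1"],
    "Y": ["N", "CA", "CB", "CG", "CD1"],
    "W": ["N", "CA", "CB", "CG", "CD1"],
    "D": ["N", "CA", "CB", "CG", "OD1"],
    "N": ["N", "CA", "CB", "CG", "OD1"],
    "H": ["N", "CA", "CB", "CG", "ND1"],
    "Q": ["N", "CA", "CB", "CG", "CD", "OE1"],
    "E": ["N", "CA", "CB", "CG", "CD", "OE1"],
    "M": ["N", "CA", "CB", "CG", "SD", "CE"],
    "K": ["N", "CA", "CB", "CG", "CD", "CE", "NZ"],
    "R": ["N", "CA", "CB", "CG", "CD", "NE", "CZ"],
}


def _chi_atom_chain(prot, resnum, k):
    code = prot.residue_type(resnum)
    seq = _CHI_SEQUENCE.get(code)
    if seq is None or len(seq) < k + 3:
        raise RestraintError(f"residue {resnum} ({code}) has no chi{k}")
    return seq[k - 1:k + 3]
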