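"""Polypeptide chain construction and fibril geometry.

This module builds protomer coordinates from internal coordinates
(sequential natural-extension-of-reference-frame placement with canonical
bond lengths and angles), replicates a protomer into a screw-symmetric
fibril with a given axial rise and twist, and measures geometry back from
coordinates: rise/twist of the screw transform, superposition RMSD,
hydrogen-bond ladders, helical pitch from AFM height traces, and the
expected mass-per-length of a fibril with a known number of molecules per
cross-beta repeat.

Conventions
-----------
* All coordinates are in Angstrom; nanometre is used only at documented
  interface points (pitch, mass-per-length).
* The fibril axis is +z.  Subunit ``s`` of a :class:`FibrilModel` carries
  coordinates ``Rz(twist * s) @ x + (0, 0, rise * s)`` applied to the
  protomer -- strict symmetry, exact to floating point.
* Twist is signed; positive twist is a right-handed screw about +z, so a
  left-handed fibril has negative twist.
* Amide and side-chain polar hydrogens are placed at build time from ideal
  geometry, so hydrogen-bond detection needs no external tool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks, periodogram
from scipy.spatial.transform import Rotation

__all__ = [
    "Protomer",
    "FibrilModel",
    "build_chain",
    "build_protomer",
    "replicate",
    "measure_rise_twist",
    "kabsch_rmsd",
    "kabsch_transform",
    "detect_hbond_ladder",
    "twist_from_pitch",
    "expected_mpl",
    "sequence_mass",
    "estimate_pitch",
    "PitchResult",
    "ideal_inregister_protomer",
    "validate_deposited_model",
    "read_fibril_pdb",
    "CHI_COUNTS",
    "VALID_ATOMS",
]

# --------------------------------------------------------------------------
# Canonical geometry tables
# --------------------------------------------------------------------------

# Backbone bond lengths (A) and angles (deg); standard single-conformer
# values used by internal-coordinate chain builders.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.020
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_CA_N_H = 119.0
BOND_CA_CB = 1.530
ANGLE_N_CA_CB = 110.5
# Position of CB about the N-CA axis relative to the carbonyl C of the same
# residue; the sign fixes L-stereochemistry.
TORSION_C_N_CA_CB = -122.6

# Average residue masses (Da) for the 20 standard residues; protein average
# mass = sum(residues) + one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

VDW_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}

# Side-chain internal-coordinate templates.  Each entry places one atom D
# from three previously placed reference atoms (A, B, C):
#   (name, A, B, C, bond C-D, angle B-C-D, chi_index or None, torsion_deg)
# When chi_index is k (1-based), the torsion is chi_k + torsion_deg;
# otherwise the torsion is the fixed value torsion_deg.  CB is placed
# generically for every non-glycine residue and is not listed here.
SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "G": [],
    "A": [],
    "S": [
        ("OG", "N", "CA", "CB", 1.417, 111.1, 1, 0.0),
        ("HG", "CA", "CB", "OG", 0.960, 109.5, None, 180.0),
    ],
    "C": [
        ("SG", "N", "CA", "CB", 1.808, 114.4, 1, 0.0),
        ("HG", "CA", "CB", "SG", 1.340, 96.0, None, 180.0),
    ],
    "T": [
        ("OG1", "N", "CA", "CB", 1.433, 109.6, 1, 0.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, 1, -120.0),
        ("HG1", "CA", "CB", "OG1", 0.960, 109.5, None, 180.0),
    ],
    "V": [
        ("CG1", "N", "CA", "CB", 1.527, 110.5, 1, 0.0),
        ("CG2", "N", "CA", "CB", 1.527, 110.5, 1, 122.3),
    ],
    "L": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, 1, 0.0),
        ("CD1", "CA", "CB", "CG", 1.521, 110.7, 2, 0.0),
        ("CD2", "CA", "CB", "CG", 1.521, 110.7, 2, 122.3),
    ],
    "I": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, 1, 0.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, 1, -122.3),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, 2, 0.0),
    ],
    "F": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, 1, 0.0),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, 2, 0.0),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, 2, 180.0),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.1, None, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.1, None, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.382, 119.9, None, 0.0),
    ],
    "Y": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, 1, 0.0),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, 2, 0.0),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, 2, 180.0),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.1, None, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.1, None, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.382, 119.9, None, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, None, 180.0),
        ("HH", "CE1", "CZ", "OH", 0.960, 109.5, None, 180.0),
    ],
    "W": [
        ("CG", "N", "CA", "CB", 1.498, 113.6, 1, 0.0),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, 2, 0.0),
        ("CD2", "CA", "CB", "CG", 1.433, 126.6, 2, 180.0),
        ("NE1", "CB", "CG", "CD1", 1.374, 110.2, None, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.2, None, 180.0),
        ("HE1", "CG", "CD1", "NE1", 1.010, 125.0, None, 180.0),
        ("CE3", "CB", "CG", "CD2", 1.398, 133.9, None, 0.0),
        ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, None, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.382, 118.8, None, 180.0),
        ("CH2", "CD2", "CE2", "CZ2", 1.368, 117.5, None, 180.0),
    ],
    "D": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, 1, 0.0),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, 2, 0.0),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, 2, 180.0),
    ],
    "N": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, 1, 0.0),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, 2, 0.0),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, 2, 180.0),
        ("HD21", "OD1", "CG", "ND2", 1.010, 120.0, None, 180.0),
        ("HD22", "OD1", "CG", "ND2", 1.010, 120.0, None, 0.0),
    ],
    "Q": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 1, 0.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 2, 0.0),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, 3, 0.0),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, 3, 180.0),
        ("HE21", "OE1", "CD", "NE2", 1.010, 120.0, None, 180.0),
        ("HE22", "OE1", "CD", "NE2", 1.010, 120.0, None, 0.0),
    ],
    "E": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 1, 0.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 2, 0.0),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, 3, 0.0),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, 3, 180.0),
    ],
    "K": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 1, 0.0),
        ("CD", "CA", "CB", "CG", 1.530, 111.3, 2, 0.0),
        ("CE", "CB", "CG", "CD", 1.530, 111.3, 3, 0.0),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, 4, 0.0),
        ("HZ1", "CD", "CE", "NZ", 1.010, 109.5, None, 60.0),
        ("HZ2", "CD", "CE", "NZ", 1.010, 109.5, None, 180.0),
        ("HZ3", "CD", "CE", "NZ", 1.010, 109.5, None, 300.0),
    ],
    "R": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 1, 0.0),
        ("CD", "CA", "CB", "CG", 1.530, 111.3, 2, 0.0),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, 3, 0.0),
        ("CZ", "CG", "CD", "NE", 1.329, 124.2, 4, 0.0),
        ("HE", "CG", "CD", "NE", 1.010, 118.0, 4, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, None, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, None, 180.0),
        ("HH11", "NE", "CZ", "NH1", 1.010, 120.0, None, 0.0),
        ("HH12", "NE", "CZ", "NH1", 1.010, 120.0, None, 180.0),
        ("HH21", "NE", "CZ", "NH2", 1.010, 120.0, None, 0.0),
        ("HH22", "NE", "CZ", "NH2", 1.010, 120.0, None, 180.0),
    ],
    "H": [
        ("CG", "N", "CA", "CB", 1.504, 113.8, 1, 0.0),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, 2, 0.0),
        ("CD2", "CA", "CB", "CG", 1.354, 131.2, 2, 180.0),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.3, None, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.2, None, 180.0),
        ("HE2", "CG", "CD2", "NE2", 1.010, 125.0, None, 180.0),
    ],
    "M": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 1, 0.0),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, 2, 0.0),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, 3, 0.0),
    ],
    # Proline ring atoms use fixed pucker torsions; the N-CD ring closure is
    # approximate (documented limitation) and the N-CD bond is recorded in
    # the bond graph so the clash term never penalises it.
    "P": [
        ("CG", "N", "CA", "CB", 1.492, 104.5, None, -25.4),
        ("CD", "CA", "CB", "CG", 1.503, 106.1, None, 37.5),
    ],
}

CHI_COUNTS = {
    "G": 0, "A": 0, "S": 1, "C": 1, "T": 1, "V": 1, "P": 0,
    "L": 2, "I": 2, "F": 2, "Y": 2, "W": 2, "D": 2, "N": 2, "H": 2,
    "Q": 3, "E": 3, "M": 3, "K": 4, "R": 4,
}

PRO_PHI_DEFAULT = -65.0

# Valid atom names per residue type (heavy atoms plus the polar hydrogens
# the builder places); "CO" is accepted everywhere as an alias for the
# backbone carbonyl carbon C'.
VALID_ATOMS: dict[str, frozenset] = {}
for _code, _tmpl in SIDECHAIN_TEMPLATES.items():
    _names = {"N", "CA", "C", "O", "H", "OXT"}
    if _code != "G":
        _names.add("CB")
    if _code == "P":
        _names.discard("H")
    _names.update(t[0] for t in _tmpl)
    VALID_ATOMS[_code] = frozenset(_names)


def _rad(x):
    return x * math.pi / 180.0


# --------------------------------------------------------------------------
# Internal-coordinate placement
# --------------------------------------------------------------------------

def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D given reference atoms A, B, C.

    D is at distance ``bond`` from C, with angle B-C-D ``angle_deg`` and
    torsion A-B-C-D ``torsion_deg`` measured about the B->C axis with the
    usual right-handed sign convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # Colinear reference frame; pick an arbitrary perpendicular.
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    ang = _rad(angle_deg)
    tor = _rad(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1n))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p0, p1, p2):
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# --------------------------------------------------------------------------
# Compiled z-matrix
# --------------------------------------------------------------------------

@dataclass
class ZMatrix:
    """Flat per-atom placement program for one protomer.

    Atom 0..2 are seeded explicitly; every later atom ``j`` is placed from
    reference atom indices ``(ref_a[j], ref_b[j], ref_c[j])`` with bond
    length ``bond[j]``, angle ``angle[j]`` and torsion
    ``tor0[j] + theta[tor_idx[j]]`` (``tor_idx[j] < 0`` means fixed).
    """

    sequence: str
    start_number: int
    atoms: list  # (resnum, resname1, atom_name)
    ref_a: np.ndarray
    ref_b: np.ndarray
    ref_c: np.ndarray
    bond: np.ndarray
    angle: np.ndarray
    tor0: np.ndarray
    tor_idx: np.ndarray
    torsion_names: list  # (resnum, "phi"|"psi"|"chi1"..)
    bonds: list = field(default_factory=list)  # (i, j) bonded atom pairs

    @property
    def n_atoms(self):
        return len(self.atoms)

    @property
    def n_torsions(self):
        return len(self.torsion_names)

    def atom_index(self):
        return {(r, n): i for i, (r, _t, n) in enumerate(self.atoms)}

    def torsion_index(self):
        return {k: i for i, k in enumerate(self.torsion_names)}


def compile_zmatrix(sequence: str, start_number: int = 1) -> ZMatrix:
    """Compile the placement program for ``sequence``.

    Free torsions are phi and psi of every residue (proline phi is fixed at
    -65 deg) plus the rotatable side-chain chi angles.  Omega is fixed at
    180 deg (trans peptide).
    """
    sequence = sequence.upper()
    for ch in sequence:
        if ch not in SIDECHAIN_TEMPLATES:
            raise ValueError(f"unknown residue code {ch!r}")
    if not sequence:
        raise ValueError("empty sequence")

    atoms: list[tuple] = []
    rows = {"a": [], "b": [], "c": [], "bond": [], "angle": [], "t0": [], "ti": []}
    torsion_names: list[tuple] = []
    bonds: list[tuple] = []
    index: dict[tuple, int] = {}

    def tor_id(resnum, name):
        torsion_names.append((resnum, name))
        return len(torsion_names) - 1

    def add(resnum, res1, name, ia, ib, ic, r, ang, t0, ti, bond_to):
        atoms.append((resnum, res1, name))
        rows["a"].append(ia)
        rows["b"].append(ib)
        rows["c"].append(ic)
        rows["bond"].append(r)
        rows["angle"].append(ang)
        rows["t0"].append(t0)
        rows["ti"].append(ti)
        j = len(atoms) - 1
        index[(resnum, name)] = j
        if bond_to is not None:
            bonds.append((bond_to, j))
        return j

    prev = {}
    for i, res1 in enumerate(sequence):
        resnum = start_number + i
        if i == 0:
            # Seed atoms: N at origin, CA along +x, C in the xy-plane.
            # phi of the first residue is undefined (no preceding carbonyl)
            # and is not a free torsion.
            iN = add(resnum, res1, "N", -1, -1, -1, 0, 0, 0, -1, None)
            iCA = add(resnum, res1, "CA", -1, -1, -1, 0, 0, 0, -1, iN)
            iC = add(resnum, res1, "C", -1, -1, -1, 0, 0, 0.0, -1, iCA)
        else:
            pN, pCA, pC = prev["N"], prev["CA"], prev["C"]
            psi_i = prev["psi_tor"]
            iN = add(resnum, res1, "N", pN, pCA, pC,
                     BOND_C_N, ANGLE_CA_C_N, 0.0, psi_i, pC)
            iCA = add(resnum, res1, "CA", pCA, pC, iN,
                      BOND_N_CA, ANGLE_C_N_CA, 180.0, -1, iN)  # omega fixed
            if res1 == "P":
                iC = add(resnum, res1, "C", pC, iN, iCA,
                         BOND_CA_C, ANGLE_N_CA_C, PRO_PHI_DEFAULT, -1, iCA)
            else:
                ti = tor_id(resnum, "phi")
                iC = add(resnum, res1, "C", pC, iN, iCA,
                         BOND_CA_C, ANGLE_N_CA_C, 0.0, ti, iCA)
            # Amide hydrogen, in the peptide plane anti to the previous
            # carbonyl oxygen.
            if res1 != "P":
                pO = prev["O"]
                add(resnum, res1, "H", pO, pC, iN,
                    BOND_N_H, ANGLE_CA_N_H, 180.0, -1, iN)
        psi_tor = tor_id(resnum, "psi")
        iO = add(resnum, res1, "O", iN, iCA, iC,
                 BOND_C_O, ANGLE_CA_C_O, 180.0, psi_tor, iC)
        if i == 0 and res1 != "P":
            add(resnum, res1, "H", iC, iCA, iN,
                BOND_N_H, ANGLE_CA_N_H, 180.0, -1, iN)
        sc_index = {"N": iN, "CA": iCA, "C": iC, "O": iO}
        if res1 != "G":
            iCB = add(resnum, res1, "CB", iC, iN, iCA,
                      BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB, -1, iCA)
            sc_index["CB"] = iCB
        chi_ids = {}
        for (name, A, B, C, r, ang, chi_k, t0) in SIDECHAIN_TEMPLATES[res1]:
            if chi_k is None:
                ti = -1
            else:
                if chi_k not in chi_ids:
                    chi_ids[chi_k] = tor_id(resnum, f"chi{chi_k}")
                ti = chi_ids[chi_k]
            parent = sc_index[C]
            j = add(resnum, res1, name, sc_index[A], sc_index[B], parent,
                    r, ang, t0, ti, parent)
            sc_index[name] = j
        if res1 == "P":
            bonds.append((iN, sc_index["CD"]))  # ring closure (approximate)
        prev = {"N": iN, "CA": iCA, "C": iC, "O": iO, "psi_tor": psi_tor}

    return ZMatrix(
        sequence=sequence,
        start_number=start_number,
        atoms=atoms,
        ref_a=np.array(rows["a"], np.int32),
        ref_b=np.array(rows["b"], np.int32),
        ref_c=np.array(rows["c"], np.int32),
        bond=np.array(rows["bond"], float),
        angle=np.array(rows["angle"], float),
        tor0=np.array(rows["t0"], float),
        tor_idx=np.array(rows["ti"], np.int32),
        torsion_names=torsion_names,
        bonds=bonds,
    )


def build_coordinates(zmat: ZMatrix, theta: np.ndarray) -> np.ndarray:
    """Evaluate the placement program; ``theta`` holds the free torsions in
    degrees, ordered as ``zmat.torsion_names``."""
    theta = np.asarray(theta, float)
    if theta.shape != (zmat.n_torsions,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({zmat.n_torsions},)")
    coords = np.zeros((zmat.n_atoms, 3))
    ang_NCAC = _rad(ANGLE_N_CA_C)
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (BOND_N_CA, 0.0, 0.0)
    coords[2] = coords[1] + (
        -BOND_CA_C * math.cos(ang_NCAC),
        BOND_CA_C * math.sin(ang_NCAC),
        0.0,
    )
    for j in range(3, zmat.n_atoms):
        ti = zmat.tor_idx[j]
        tor = zmat.tor0[j] + (theta[ti] if ti >= 0 else 0.0)
        coords[j] = place_atom(
            coords[zmat.ref_a[j]], coords[zmat.ref_b[j]], coords[zmat.ref_c[j]],
            zmat.bond[j], zmat.angle[j], tor,
        )
    return coords


# --------------------------------------------------------------------------
# Protomer / FibrilModel
# --------------------------------------------------------------------------

class Protomer:
    """A single polypeptide subunit defined by sequence and torsions.

    Parameters
    ----------
    sequence:
        One-letter residue codes.
    start_number:
        Residue number of the first residue (the numbering restraints use).
    phi, psi:
        Optional dicts ``{residue_number: degrees}``; unset torsions default
        to 180 deg (extended chain).  Proline phi is fixed at -65 deg.
    chi:
        Optional dict ``{(residue_number, "chi1"): degrees}``; rotatable
        chis default to 180 deg.
    """

    def __init__(self, sequence, start_number=1, phi=None, psi=None, chi=None):
        self.zmat = compile_zmatrix(sequence, start_number)
        self.sequence = self.zmat.sequence
        self.start_number = start_number
        self.theta = np.full(self.zmat.n_torsions, 180.0)
        self._tor_index = self.zmat.torsion_index()
        for (resnum, name), i in self._tor_index.items():
            if name.startswith("chi"):
                self.theta[i] = 180.0
        for d, angname in ((phi, "phi"), (psi, "psi")):
            if d:
                for resnum, val in d.items():
                    self.set_torsion(resnum, angname, val)
        if chi:
            for (resnum, name), val in chi.items():
                self.set_torsion(resnum, name, val)
        # Rigid orientation of the built chain relative to the fibril axis
        # (+z): rotations about x then y, degrees.  Torsions fix internal
        # geometry only; the orientation matters once the protomer is
        # stacked (rotation about z and translations are symmetry-neutral
        # for an untwisted stack and are not parameterized).
        self.orientation = (0.0, 0.0)
        self._coords = None
        self._atom_index = self.zmat.atom_index()

    # -- torsions ----------------------------------------------------------
    def set_torsion(self, resnum, name, value):
        key = (resnum, name)
        if key not in self._tor_index:
            raise KeyError(f"no free torsion {name} for residue {resnum}")
        self.theta[self._tor_index[key]] = float(value)
        self._coords = None

    def get_torsion(self, resnum, name):
        return float(self.theta[self._tor_index[(resnum, name)]])

    def has_torsion(self, resnum, name):
        return (resnum, name) in self._tor_index

    # -- coordinates -------------------------------------------------------
    @property
    def coords(self):
        if self._coords is None:
            xyz = build_coordinates(self.zmat, self.theta)
            rx, ry = self.orientation
            if rx or ry:
                R = (Rotation.from_euler("y", ry, degrees=True)
                     * Rotation.from_euler("x", rx, degrees=True)).as_matrix()
                xyz = xyz @ R.T
            self._coords = xyz
        return self._coords

    def set_orientation(self, rx, ry):
        self.orientation = (float(rx), float(ry))
        self._coords = None

    @property
    def atoms(self):
        return self.zmat.atoms

    def atom_index(self, resnum, atom_name):
        name = "C" if atom_name == "CO" else atom_name
        try:
            return self._atom_index[(resnum, name)]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} of residue {resnum} not present") from None

    def copy(self):
        p = Protomer(self.sequence, self.start_number)
        p.theta = self.theta.copy()
        p.orientation = self.orientation
        return p

    @property
    def residue_numbers(self):
        return list(range(self.start_number, self.start_number + len(self.sequence)))

    def residue_type(self, resnum):
        return self.sequence[resnum - self.start_number]


def build_chain(sequence, torsions=None, start_number=1):
    """Build coordinates for ``sequence`` from internal coordinates.

    ``torsions`` may carry ``phi``, ``psi`` and ``chi`` entries as accepted
    by :class:`Protomer`; missing values default to the extended chain.
    Returns the :class:`Protomer` (its ``coords`` attribute holds the
    Cartesian coordinates in Angstrom).
    """
    torsions = torsions or {}
    return Protomer(
        sequence,
        start_number=start_number,
        phi=torsions.get("phi"),
        psi=torsions.get("psi"),
        chi=torsions.get("chi"),
    )


def build_protomer(sequence, start_number=1, **kw):
    return Protomer(sequence, start_number=start_number, **kw)


def _rz(deg):
    c, s = math.cos(_rad(deg)), math.sin(_rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class FibrilModel:
    """A screw-symmetric stack of identical subunits.

    Subunit ``s`` carries ``Rz(twist * s) @ x + (0, 0, rise * s)`` applied
    to the protomer coordinates; the symmetry is exact by construction.
    """

    def __init__(self, protomer: Protomer, n_subunits: int, rise: float,
                 twist: float = 0.0):
        if n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if rise <= 0:
            raise ValueError("rise must be positive")
        self.protomer = protomer
        self.n_subunits = int(n_subunits)
        self.rise = float(rise)
        self.twist = float(twist)

    def subunit_coords(self, s: int) -> np.ndarray:
        x = self.protomer.coords
        if s == 0:
            return x.copy()
        return x @ _rz(self.twist * s).T + np.array([0.0, 0.0, self.rise * s])

    def all_coords(self) -> np.ndarray:
        return np.concatenate([self.subunit_coords(s) for s in range(self.n_subunits)])

    def get_atom(self, resnum, atom_name, subunit=0):
        if not 0 <= subunit < self.n_subunits:
            raise IndexError(f"subunit {subunit} outside 0..{self.n_subunits - 1}")
        i = self.protomer.atom_index(resnum, atom_name)
        return self.subunit_coords(subunit)[i]

    @property
    def atoms(self):
        return self.protomer.atoms

    # -- PDB I/O -----------------------------------------------------------
    def to_pdb(self, path, style="chains"):
        """Write the fibril; subunits become chains A.. (``style='chains'``)
        or MODEL records (``style='models'``)."""
        import gemmi

        st = gemmi.Structure()
        st.name = "fibril"
        chains_per_model = style == "chains"
        rem = (f"REMARK 300 FIBRIL SYMMETRY: N={self.n_subunits} "
               f"RISE={self.rise:.3f} A TWIST={self.twist:.3f} DEG "
               f"(AXIS +Z, RIGHT-HANDED POSITIVE)")
        st.raw_remarks = [rem]
        chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

        def fill_chain(model, s, chain_id):
            chain = gemmi.Chain(chain_id)
            xyz = self.subunit_coords(s)
            res = None
            last = None
            for i, (resnum, res1, name) in enumerate(self.atoms):
                if resnum != last:
                    res = gemmi.Residue()
                    res.name = THREE_LETTER[res1]
                    res.seqid = gemmi.SeqId(resnum, " ")
                    chain.add_residue(res)
                    res = chain[-1]
                    last = resnum
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0] if name[0] != "H" else "H")
                at.pos = gemmi.Position(*xyz[i])
                at.occ = 1.0
                res.add_atom(at)
            model.add_chain(chain)

        if chains_per_model:
            model = gemmi.Model("1")
            for s in range(self.n_subunits):
                fill_chain(model, s, chain_ids[s % len(chain_ids)])
            st.add_model(model)
        else:
            for s in range(self.n_subunits):
                model = gemmi.Model(str(s + 1))
                fill_chain(model, s, "A")
                st.add_model(model)
        st.setup_entities()
        doc = st.make_pdb_string()
        with open(path, "w") as fh:
            fh.write(rem + "\n")
            fh.write(doc)


def replicate(protomer: Protomer, n: int, rise: float, twist: float = 0.0) -> FibrilModel:
    """Stack ``n`` exact symmetry copies of ``protomer``.

    With ``twist = 0`` every inter-subunit displacement is ``(0, 0, rise)``
    so each atom's copy-to-copy distance equals the rise exactly.
    """
    return FibrilModel(protomer, n, rise, twist)


# --------------------------------------------------------------------------
# Superposition / geometry measurement
# --------------------------------------------------------------------------

def kabsch_transform(a, b):
    """Least-squares proper rotation R and translation t with
    ``b ~ R @ a + t``.  Returns (R, t, rmsd)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be (n, 3) and congruent")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (a @ R.T + t) - b
    rmsd = math.sqrt(float((diff * diff).sum()) / a.shape[0])
    return R, t, rmsd


def kabsch_rmsd(a, b):
    """Minimum RMSD between two corresponding coordinate sets after optimal
    rigid (proper rotation + translation) superposition."""
    return kabsch_transform(a, b)[2]


def measure_rise_twist(model, atoms_per_subunit=None):
    """Measure (rise, twist) of the screw transform mapping subunit s to
    s+1 by least-squares superposition.

    ``model`` is a :class:`FibrilModel` or a list of per-subunit coordinate
    arrays with corresponding atom order.  The twist sign follows the
    right-hand rule about +z (left-handed fibrils give negative twist).
    Returns ``(rise_A, twist_deg)``.
    """
    if isinstance(model, FibrilModel):
        subs = [model.subunit_coords(s) for s in range(model.n_subunits)]
    else:
        subs = [np.asarray(s, float) for s in model]
    if len(subs) < 2:
        raise ValueError("need at least 2 subunits")
    shapes = {s.shape for s in subs}
    if len(shapes) != 1:
        raise ValueError("subunits are not superposable: atom counts differ")

    rises, twists = [], []
    for s in range(len(subs) - 1):
        R, t, _ = kabsch_transform(subs[s], subs[s + 1])
        rot = Rotation.from_matrix(R)
        rotvec = rot.as_rotvec()
        angle = float(np.linalg.norm(rotvec))
        if angle < 1e-9:
            axis = np.array([0.0, 0.0, 1.0])
            theta = 0.0
        else:
            axis = rotvec / angle
            theta = math.degrees(angle)
            if axis[2] < 0:
                axis = -axis
                theta = -theta
        h = float(np.dot(t, axis))
        # Report rise as advance along the axis oriented with +z.
        rises.append(h)
        twists.append(theta)
    return float(np.mean(rises)), float(np.mean(twists))


# --------------------------------------------------------------------------
# Hydrogen-bond ladders
# --------------------------------------------------------------------------

# (residue code -> list of (H name, N/O donor-heavy name)) donors and
# (residue code -> list of (O name, C name)) acceptors; backbone entries are
# added for every residue.
_SIDECHAIN_DONORS = {
    "N": [("HD21", "ND2"), ("HD22", "ND2")],
    "Q": [("HE21", "NE2"), ("HE22", "NE2")],
    "K": [("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
    "R": [("HE", "NE"), ("HH11", "NH1"), ("HH12", "NH1"),
          ("HH21", "NH2"), ("HH22", "NH2")],
    "W": [("HE1", "NE1")],
    "H": [("HE2", "NE2")],
    "S": [("HG", "OG")],
    "T": [("HG1", "OG1")],
    "Y": [("HH", "OH")],
    "C": [("HG", "SG")],
}
_SIDECHAIN_ACCEPTORS = {
    "N": [("OD1", "CG")],
    "D": [("OD1", "CG"), ("OD2", "CG")],
    "Q": [("OE1", "CD")],
    "E": [("OE1", "CD"), ("OE2", "CD")],
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "Y": [("OH", "CZ")],
}


@dataclass
class HBondContact:
    donor_residue: int
    donor_h: str
    donor_heavy: str
    acceptor_residue: int
    acceptor_o: str
    h_o: float
    n_o: float
    interface: tuple  # (donor subunit, acceptor subunit)
    sidechain: bool


def detect_hbond_ladder(model: FibrilModel, donor_acceptor_pairs=None,
                        h_o_max=2.5, n_o_max=3.5):
    """Find inter-subunit hydrogen bonds repeated along the fibril.

    Scans donor N/O-H groups of one subunit against acceptor C=O / O groups
    of the adjacent subunits (interfaces (0, 1) and (1, 0) are
    representative of every interface under strict symmetry).  Restrict to
    residue pairs with ``donor_acceptor_pairs`` = iterable of
    ``(donor_residue, acceptor_residue)``; default scans all residues.
    Raises if the model carries no hydrogens.
    """
    if model.n_subunits < 2:
        raise ValueError("need at least 2 subunits for an inter-subunit ladder")
    names = {name for (_r, _t, name) in model.atoms}
    if not any(n.startswith("H") for n in names):
        raise ValueError(
            "model has no hydrogens; build coordinates with the chain builder "
            "(polar hydrogens are placed automatically)")

    pairs = set(map(tuple, donor_acceptor_pairs)) if donor_acceptor_pairs else None
    prot = model.protomer
    donors = []  # (resnum, hname, heavyname, sidechain)
    acceptors = []  # (resnum, oname, cname, sidechain)
    for resnum in prot.residue_numbers:
        code = prot.residue_type(resnum)
        if code != "P":
            try:
                prot.atom_index(resnum, "H")
                donors.append((resnum, "H", "N", False))
            except KeyError:
                pass
        acceptors.append((resnum, "O", "C", False))
        for h, heavy in _SIDECHAIN_DONORS.get(code, []):
            donors.append((resnum, h, heavy, True))
        for o, c in _SIDECHAIN_ACCEPTORS.get(code, []):
            acceptors.append((resnum, o, c, True))

    out = []
    sub0 = model.subunit_coords(0)
    sub1 = model.subunit_coords(1)
    coords = {0: sub0, 1: sub1}
    for d_sub, a_sub in ((1, 0), (0, 1)):
        for (dres, hname, heavy, dsc) in donors:
            h_xyz = coords[d_sub][prot.atom_index(dres, hname)]
            n_xyz = coords[d_sub][prot.atom_index(dres, heavy)]
            for (ares, oname, cname, asc) in acceptors:
                if pairs is not None and (dres, ares) not in pairs:
                    continue
                o_xyz = coords[a_sub][prot.atom_index(ares, oname)]
                h_o = float(np.linalg.norm(h_xyz - o_xyz))
                if h_o > h_o_max:
                    continue
                n_o = float(np.linalg.norm(n_xyz - o_xyz))
                if n_o > n_o_max:
                    continue
                out.append(HBondContact(dres, hname, heavy, ares, oname,
                                        h_o, n_o, (d_sub, a_sub), dsc or asc))
    out.sort(key=lambda c: c.h_o)
    return out


# --------------------------------------------------------------------------
# Scalar geometry relations
# --------------------------------------------------------------------------

def twist_from_pitch(pitch, rise):
    """Twist per subunit (degrees, unsigned) for a helical ``pitch`` and
    axial ``rise`` in the same unit: ``360 / (pitch / rise)``."""
    if pitch <= 0 or rise <= 0:
        raise ValueError("pitch and rise must be positive")
    return 360.0 / (pitch / rise)


def expected_mpl(monomer_mass_kda, rise_nm, molecules_per_unit=1):
    """Expected mass-per-length (kDa/nm) of a fibril with
    ``molecules_per_unit`` molecules in each cross-beta repeat."""
    if monomer_mass_kda <= 0 or rise_nm <= 0 or molecules_per_unit <= 0:
        raise ValueError("all arguments must be positive")
    return molecules_per_unit * monomer_mass_kda / rise_nm


def sequence_mass(sequence):
    """Average molecular mass of a polypeptide in kDa (residues + 1 water)."""
    sequence = sequence.upper().strip()
    if not sequence:
        warnings.warn("empty sequence: returning the mass of one water")
        return WATER_MASS / 1000.0
    total = WATER_MASS
    for ch in sequence:
        try:
            total += RESIDUE_MASS[ch]
        except KeyError:
            raise ValueError(f"unknown residue code {ch!r}") from None
    return total / 1000.0


# --------------------------------------------------------------------------
# Pitch from AFM height traces
# --------------------------------------------------------------------------

@dataclass
class PitchResult:
    pitch_nm: float | None
    periodic: bool
    acf_pitch_nm: float | None = None
    spectral_pitch_nm: float | None = None
    prominence: float = 0.0

    def __bool__(self):
        return self.periodic


def estimate_pitch(distance_nm, height_nm=None, min_prominence=0.2):
    """Dominant period of a fibril height trace.

    Primary estimator: first major off-origin peak of the detrended
    autocorrelation (quadratic sub-sample interpolation); secondary check:
    the periodogram's dominant period.  ``min_prominence`` is the required
    autocorrelation peak prominence relative to the zero-lag value; below
    it the trace is reported as non-periodic (``pitch_nm is None``).

    Accepts either two arrays (distance, height) or a single (n, 2) array.
    """
    if height_nm is None:
        arr = np.asarray(distance_nm, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (n, 2) trace or two arrays")
        x, y = arr[:, 0], arr[:, 1]
    else:
        x = np.asarray(distance_nm, float)
        y = np.asarray(height_nm, float)
    if x.size < 2:
        raise ValueError("trace shorter than 2 samples")
    dx = float(np.median(np.diff(x)))
    # Remove the baseline and any linear tilt.
    coeff = np.polyfit(x, y, 1)
    r = y - np.polyval(coeff, x)
    if float(np.std(r)) < 1e-12:
        return PitchResult(None, False)
    n = r.size
    acf = np.correlate(r, r, mode="full")[n - 1:]
    acf = acf / acf[0]
    peaks, props = find_peaks(acf, prominence=min_prominence)
    acf_pitch = None
    prominence = 0.0
    if peaks.size:
        k = int(peaks[0])
        prominence = float(props["prominences"][0])
        # Quadratic interpolation around the discrete peak.
        if 1 <= k < n - 1:
            y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
            denom = (y0 - 2 * y1 + y2)
            shift = 0.0 if abs(denom) < 1e-12 else 0.5 * (y0 - y2) / denom
            acf_pitch = (k + float(np.clip(shift, -0.5, 0.5))) * dx
        else:
            acf_pitch = k * dx
    freqs, power = periodogram(r, fs=1.0 / dx)
    spectral = None
    if power[1:].size:
        kmax = 1 + int(np.argmax(power[1:]))
        if freqs[kmax] > 0:
            spectral = float(1.0 / freqs[kmax])
    if acf_pitch is None:
        return PitchResult(None, False, None, spectral, prominence)
    return PitchResult(float(acf_pitch), True, float(acf_pitch), spectral,
                       prominence)


# --------------------------------------------------------------------------
# Idealized in-register protomer
# --------------------------------------------------------------------------

def ideal_inregister_protomer(sequence, start_number=1, rise=4.75,
                              hbond_pairs=None):
    """Uniform-torsion extended strand tuned for in-register stacking.

    Optimizes a single (phi, psi) pair, applied to every residue, together
    with the rigid orientation of the strand relative to the stacking axis,
    so that an exact-translation stack at the given rise forms backbone
    hydrogen bonds with the canonical H...O 2.3 A / N...O 3.3 A geometry
    between a residue's amide and the preceding residue's carbonyl on the
    adjacent subunit (whichever side of the pleat the amide points to).
    Used for round-trip restraint validation and as a sanity reference for
    cross-beta geometry.
    """
    if hbond_pairs is None:
        # Generic (i, i-1) amide-to-carbonyl ladder over the interior.
        numbers = list(range(start_number + 1, start_number + len(sequence)))
        hbond_pairs = [(i, i - 1) for i in numbers]
    prot = Protomer(sequence, start_number)
    shift = np.array([0.0, 0.0, rise])
    triples = []
    for (dres, ares) in hbond_pairs:
        if prot.residue_type(dres) == "P":
            continue
        triples.append((prot.atom_index(dres, "H"),
                        prot.atom_index(dres, "N"),
                        prot.atom_index(ares, "O")))
    ih = np.array([t[0] for t in triples])
    iN = np.array([t[1] for t in triples])
    io = np.array([t[2] for t in triples])

    def set_torsions(phi, psi):
        for resnum in prot.residue_numbers:
            if prot.has_torsion(resnum, "phi"):
                prot.set_torsion(resnum, "phi", phi)
            prot.set_torsion(resnum, "psi", psi)

    def cost_at(x0):
        ho = np.minimum(
            np.linalg.norm(x0[ih] - (x0[io] + shift), axis=1),
            np.linalg.norm(x0[ih] - (x0[io] - shift), axis=1))
        no = np.minimum(
            np.linalg.norm(x0[iN] - (x0[io] + shift), axis=1),
            np.linalg.norm(x0[iN] - (x0[io] - shift), axis=1))
        return float(((ho - 2.3) ** 2).sum() + ((no - 3.3) ** 2).sum())

    def orient_cost(angles, base):
        rx, ry = angles
        R = (Rotation.from_euler("y", ry, degrees=True)
             * Rotation.from_euler("x", rx, degrees=True)).as_matrix()
        return cost_at(base @ R.T)

    def objective(v):
        phi, psi = v
        set_torsions(phi, psi)
        prot.set_orientation(0.0, 0.0)
        base = prot.coords
        best_inner = None
        for g in ((0.0, 0.0), (90.0, 0.0), (-90.0, -30.0), (0.0, 90.0)):
            r = minimize(orient_cost, g, args=(base,), method="Nelder-Mead",
                         options={"xatol": 1e-6, "fatol": 1e-12,
                                  "maxiter": 400})
            if best_inner is None or r.fun < best_inner.fun:
                best_inner = r
        objective.last_orientation = tuple(best_inner.x)
        return best_inner.fun

    res = minimize(objective, (-135.0, 135.0), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200})
    phi, psi = res.x
    objective((phi, psi))
    set_torsions(phi, psi)
    prot.set_orientation(*objective.last_orientation)
    return prot


# --------------------------------------------------------------------------
# Reading deposited fibril coordinates
# --------------------------------------------------------------------------

def read_fibril_pdb(path):
    """Read a multi-subunit fibril PDB.

    Subunits may be deposited as chains within one MODEL or as separate
    MODEL records (both layouts occur in fibril depositions); the reader
    accepts either.  Returns ``(subunit_coord_list, atoms)`` where atoms is
    the per-subunit ``(resnum, res1, atom_name)`` list common to all
    subunits (atoms missing from any subunit are dropped).
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    units = []  # list of dict (resnum, atomname) -> (xyz, res1)
    if len(st) > 1:
        groups = [[ch for ch in model] for model in st]
        units_src = [chs for chs in groups]
    else:
        units_src = [[ch] for ch in st[0]]
    for chains in units_src:
        d = {}
        for ch in chains:
            for res in ch:
                code = ONE_LETTER.get(res.name)
                if code is None:
                    continue
                for at in res:
                    d[(res.seqid.num, at.name)] = (
                        np.array([at.pos.x, at.pos.y, at.pos.z]), code)
        if d:
            units.append(d)
    if not units:
        raise ValueError(f"no protein coordinates found in {path}")
    common = set(units[0])
    for d in units[1:]:
        common &= set(d)
    keys = sorted(common)
    atoms = [(r, units[0][(r, n)][1], n) for (r, n) in keys]
    subs = [np.array([d[k][0] for k in keys]) for d in units]
    return subs, atoms


def validate_deposited_model(path, q_residue=449, h_o_ref=1.97):
    """Cross-beta geometry checks on a deposited fibril model.

    Measures the inter-subunit rise/twist and the glutamine side-chain
    amide ladder H...O / N...O distances at ``q_residue``.  Works on any
    multi-subunit PDB (chains or MODEL records).  If the file carries no
    side-chain amide hydrogens the H...O distance is estimated from the
    NE2...O geometry assuming an ideal planar amide (N-H 1.01 A along the
    NE2->O direction component).

    Returns a dict with measured rise, twist, and the Q-ladder distances.
    """
    subs, atoms = read_fibril_pdb(path)
    rise, twist = measure_rise_twist(subs)
    index = {(r, n): i for i, (r, _t, n) in enumerate(atoms)}
    result = {"rise": rise, "twist": twist, "q_residue": q_residue,
              "h_o": None, "n_o": None, "h_o_reference": h_o_ref}

    def get(sub, key):
        i = index.get(key)
        return None if i is None else subs[sub][i]

    best = None
    for dsub, asub in ((1, 0), (0, 1)):
        ne2 = get(dsub, (q_residue, "NE2"))
        oe1 = get(asub, (q_residue, "OE1"))
        if ne2 is None or oe1 is None:
            continue
        n_o = float(np.linalg.norm(ne2 - oe1))
        h_o = None
        for hname in ("HE21", "HE22", "1HE2", "2HE2"):
            h = get(dsub, (q_residue, hname))
            if h is not None:
                d = float(np.linalg.norm(h - oe1))
                h_o = d if h_o is None else min(h_o, d)
        if h_o is None:
            h_o = max(n_o - 1.01, 0.0)  # linear-amide estimate
        if best is None or h_o < best[0]:
            best = (h_o, n_o)
    if best:
        result["h_o"], result["n_o"] = best
    return result
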