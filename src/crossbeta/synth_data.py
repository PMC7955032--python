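"""Synthetic inputs with known ground truth for every pipeline stage.

Generators produce: chemical-shift tables with planted beta-strand
segments, restraint sets back-computed from known coordinates, dark-field
TEM images containing fibrils of known mass density plus TMV-like
internal-standard rods, and periodic AFM height traces with a planted
pitch.  Every generator is seeded and deterministic (identical
configuration => bit-identical output) and records its ground truth in a
sidecar structure that downstream recovery tests read instead of peeking
at the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .chemshift import RandomCoilTable, ShiftTable
from .fibril_model import FibrilModel, Protomer
from .mpl_tem import TMV_MPL, DarkFieldImage
from .restraints import AtomRef, DistanceRestraint, RestraintSet

__all__ = [
    "SynthConfig",
    "load_construct",
    "mini_arch_fixture",
    "reference_fold",
    "fibril_core_inputs",
    "CONSTRUCT_STRAND_SEGMENTS",
    "gen_shift_table",
    "emulate_deposited_shifts",
    "gen_dihedral_predictions",
    "gen_restraints_from_structure",
    "gen_darkfield_image",
    "random_filament_layout",
    "gen_afm_profile",
    "write_sidecar",
    "read_sidecar",
]

# Strand segments of the fibril core in construct numbering: the three
# beta-strands called from the secondary chemical shifts.
CONSTRUCT_STRAND_SEGMENTS = ((441, 444), (448, 452), (454, 460))

# AFM fibril diameter (nm); the rendered filament cross-section uses a
# Gaussian with this FWHM.
FIBRIL_DIAMETER_NM = 1.8
TMV_DIAMETER_NM = 18.0

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults reproduce the documented measurement conditions: three
    planted strand segments, TMV internal standard at 131 kDa/nm,
    60 x 120 nm measurement rectangles downstream, a ~28.5 nm AFM pitch,
    and mixed Poisson + read-noise image statistics.
    """

    seed: int = 0
    strand_segments: tuple = CONSTRUCT_STRAND_SEGMENTS
    shift_noise_sd: float = 0.2  # ppm, ~ measured 13C linewidth / 4
    image_pixel_size: float = 1.0  # nm/pixel
    fibril_mpl_true: float = 20.3  # kDa/nm, one molecule per 4.7 A repeat
    tmv_mpl: float = TMV_MPL
    background_level: float = 40.0  # counts
    noise_model: str = "mixed"  # poisson | gaussian | mixed
    afm_pitch_true: float = 28.5  # nm
    afm_noise_sd: float = 0.06  # nm

    def __post_init__(self):
        if self.tmv_mpl <= 0:
            raise ValueError("tmv_mpl must be positive")
        if self.noise_model not in ("poisson", "gaussian", "mixed", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        segs = sorted(tuple(map(tuple, self.strand_segments)))
        for (a, b) in segs:
            if a > b:
                raise ValueError(f"segment {(a, b)} reversed")
        for (a0, b0), (a1, b1) in zip(segs, segs[1:]):
            if a1 <= b0:
                raise ValueError("strand segments overlap")
        self.strand_segments = tuple(segs)


# --------------------------------------------------------------------------
# Construct sequence (bundled stand-in)
# --------------------------------------------------------------------------

def load_construct():
    """The bundled 86-residue RHIM-construct stand-in.

    Returns ``(sequence, start_number)`` with numbering aligned to the
    full-length protein (the His-tag leader occupies 401-408 so that the
    RHIM core carries its native numbers 441-460).  The fibril-core region
    440-461 follows the experimentally characterized sequence; the
    disordered flanks are synthetic filler (see the FASTA header).
    """
    ref = resources.files("crossbeta.data") / "construct_mripk3_synthetic.fasta"
    text = ref.read_text()
    seq = "".join(line.strip() for line in text.splitlines()
                  if not line.startswith(">"))
    return seq, 401


# --------------------------------------------------------------------------
# Shift tables
# --------------------------------------------------------------------------

def gen_shift_table(sequence, strand_segments, shift_noise_sd, seed,
                    start_number=1, residue_range=None, strand_offset=2.0,
                    nonstrand_delta=0.0, rc: RandomCoilTable | None = None):
    """Shift table with planted beta-strand segments.

    Residues inside a strand segment get Ca shifted ``-strand_offset`` and
    Cb ``+strand_offset`` from random coil (the beta-sheet secondary-shift
    convention); other residues sit at random coil, optionally biased by
    ``nonstrand_delta`` (Ca +delta/2, Cb -delta/2) to emulate rigid
    non-strand residues with positive secondary shifts.  Gaussian noise of
    ``shift_noise_sd`` ppm is added per shift; glycines carry Ca only.

    Returns ``(ShiftTable, truth)``; truth records the planted segments.
    """
    if shift_noise_sd < 0:
        raise ValueError("shift_noise_sd must be >= 0")
    rc = rc or RandomCoilTable.bundled()
    segs = tuple(map(tuple, strand_segments))
    last = start_number + len(sequence) - 1
    for (a, b) in segs:
        if a < start_number or b > last or a > b:
            raise ValueError(
                f"segment {(a, b)} outside sequence range "
                f"{start_number}-{last}")
    rng = np.random.default_rng(seed)
    in_strand = set()
    for (a, b) in segs:
        in_strand.update(range(a, b + 1))
    rows = []
    lo, hi = residue_range if residue_range else (start_number, last)
    for i, code in enumerate(sequence):
        resnum = start_number + i
        if not lo <= resnum <= hi:
            continue
        if resnum in in_strand:
            d_ca, d_cb = -strand_offset, +strand_offset
        else:
            d_ca, d_cb = +nonstrand_delta / 2.0, -nonstrand_delta / 2.0
        ca = rc.ca[code] + d_ca + rng.normal(0.0, shift_noise_sd)
        rows.append((resnum, code, "CA", ca))
        if code != "G":
            cb = rc.cb[code] + d_cb + rng.normal(0.0, shift_noise_sd)
            rows.append((resnum, code, "CB", cb))
    table = ShiftTable(rows, sequence=sequence, start_number=start_number)
    truth = {"generator": "gen_shift_table", "seed": seed,
             "strand_segments": list(map(list, segs)),
             "shift_noise_sd": shift_noise_sd,
             "strand_offset": strand_offset,
             "nonstrand_delta": nonstrand_delta,
             "residue_range": [lo, hi]}
    return table, truth


def emulate_deposited_shifts(seed=0, noise_sd=0.2):
    """Shift table emulating the deposited fibril-core assignments.

    Only the rigid, sequentially assigned core (441-461) carries shifts;
    strand residues show clearly negative secondary shifts and the
    assigned non-strand residues (the beta-arc 445-447, the turn residue
    453 and the final assigned residue 461) show positive values, matching
    the qualitative features of the deposited data (negative secondary
    shifts only within the three strands).
    """
    seq, start = load_construct()
    return gen_shift_table(
        seq, CONSTRUCT_STRAND_SEGMENTS, noise_sd, seed,
        start_number=start, residue_range=(441, 461), strand_offset=2.0,
        nonstrand_delta=2.0)


def gen_dihedral_predictions(segments=CONSTRUCT_STRAND_SEGMENTS,
                             phi=-125.0, psi=130.0, uncertainty=25.0,
                             jitter=6.0, seed=0, exclude=("P",),
                             sequence=None, start_number=None,
                             source_tag="pred"):
    """TALOS-style backbone predictions for strand residues.

    Emits phi/psi predictions at extended-strand values for every residue
    inside the given segments, with per-residue jitter (seeded) standing
    in for predictor variability.  Used to emulate the two dihedral
    prediction sources consumed by the consensus merge.
    """
    from .chemshift import DihedralPrediction

    rng = np.random.default_rng(seed)
    preds = []
    for (a, b) in segments:
        for resnum in range(a, b + 1):
            if sequence is not None and start_number is not None:
                code = sequence[resnum - start_number]
                if code in exclude:
                    continue
            for name, center in (("phi", phi), ("psi", psi)):
                val = center + rng.normal(0.0, jitter)
                val = (val + 180.0) % 360.0 - 180.0
                if val == -180.0:
                    val = 180.0
                preds.append(DihedralPrediction(resnum, name, float(val),
                                                uncertainty, source_tag))
    return preds


# --------------------------------------------------------------------------
# Restraints from known coordinates
# --------------------------------------------------------------------------

def gen_restraints_from_structure(structure, contact_cutoff,
                                  margin=1.5, min_seq_sep=2,
                                  include_hydrogens=False):
    """Flat-bottom distance restraints for every non-sequential heavy-atom
    pair under ``contact_cutoff`` (A) in a known structure.

    ``structure`` is a :class:`Protomer` (intramolecular restraints only)
    or a :class:`FibrilModel` (adjacent-subunit pairs are emitted too,
    tagged by subunit offset).  Each restraint targets the true distance
    with symmetric ``margin`` bounds, so a violation report on the
    generating coordinates is identically zero.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    if isinstance(structure, FibrilModel):
        prot = structure.protomer
        cross = structure.n_subunits > 1
        shift = np.array([0.0, 0.0, structure.rise])
        if structure.twist != 0.0:
            raise ValueError(
                "restraint generation supports untwisted stacks only")
    else:
        prot = structure
        cross = False
        shift = None
    atoms = prot.atoms
    xyz = prot.coords
    heavy = [i for i, (_r, _t, n) in enumerate(atoms)
             if include_hydrogens or not n.startswith("H")]
    rs = RestraintSet()
    for ii, i in enumerate(heavy):
        ri, _ti, ni = atoms[i]
        for j in heavy[ii + 1:]:
            rj, _tj, nj = atoms[j]
            if abs(ri - rj) < min_seq_sep:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d > contact_cutoff or d <= margin:
                continue
            rs.add(DistanceRestraint(
                AtomRef(ri, ni, 0), AtomRef(rj, nj, 0),
                d, margin, margin, rclass="unambiguous"),
                note=f"from-structure intra {ri}{ni}-{rj}{nj} {d:.2f}A")
    if cross:
        for i in heavy:
            ri, _ti, ni = atoms[i]
            for j in heavy:
                rj, _tj, nj = atoms[j]
                d = float(np.linalg.norm(xyz[i] - (xyz[j] + shift)))
                if d > contact_cutoff or d <= margin:
                    continue
                try:
                    rs.add(DistanceRestraint(
                        AtomRef(ri, ni, 0), AtomRef(rj, nj, 1),
                        d, margin, margin, rclass="intermolecular"),
                        note=f"from-structure inter {ri}{ni}-{rj}{nj}'")
                except Exception:
                    continue
    return rs


# --------------------------------------------------------------------------
# Canonical test systems
# --------------------------------------------------------------------------

def mini_arch_fixture():
    """Six-residue bent-peptide fixture with known ground truth.

    Extended arms flanking a tight two-residue turn, giving a compact
    strand-turn-strand ("arch"-like) conformation with a dense set of
    non-sequential heavy-atom contacts under 5.5 A.  Returns
    ``(protomer, restraint_set)`` where the restraints were back-computed
    from the protomer, so the protomer itself scores zero violations.
    """
    p = Protomer("AVGNQL")
    for r, v in {2: -140, 3: -60, 4: -90, 5: -140, 6: -140}.items():
        p.set_torsion(r, "phi", v)
    for r, v in {1: 140, 2: 140, 3: -30, 4: 0, 5: 140, 6: 140}.items():
        p.set_torsion(r, "psi", v)
    rs = gen_restraints_from_structure(p, 5.5)
    return p, rs


def reference_fold():
    """The bundled synthetic reference conformation of the fibril core.

    A residues-441-460 protomer whose torsions satisfy the ten printed
    unambiguous contacts and the in-register stacking restraints exactly
    (H-bond components within ~0.06 A), with beta-region backbone torsions
    in the three strand interiors.  It serves as the planted ground truth
    behind the emulated dihedral-prediction tables; it is NOT the
    deposited structure.  Returns a :class:`Protomer`.
    """
    seq_full, start_full = load_construct()
    sequence = seq_full[441 - start_full:461 - start_full]
    prot = Protomer(sequence, start_number=441)
    ref = resources.files("crossbeta.data") / "reference_fold_synthetic.tsv"
    rx = ry = 0.0
    for line in ref.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        res_s, angle, val_s = line.split("\t")
        val = float(val_s)
        if angle == "orient_rx":
            rx = val
        elif angle == "orient_ry":
            ry = val
        else:
            prot.set_torsion(int(res_s), angle, val)
    prot.set_orientation(rx, ry)
    return prot


def q_ladder_fixture(n_subunits=4, rise=4.75):
    """Glutamine side-chain ladder demonstration fibril (synthetic).

    An ideal in-register strand (sequence AQAQA) whose glutamine chi
    angles are tuned so the side-chain amides of successive subunits form
    the canonical inter-subunit hydrogen-bond ladder with H...O =
    1.97 A.  Returns the replicated :class:`FibrilModel`.
    """
    from .fibril_model import ideal_inregister_protomer, replicate

    prot = ideal_inregister_protomer("AQAQA", start_number=1, rise=rise)
    for resnum in (2, 4):
        prot.set_torsion(resnum, "chi1", -57.43)
        prot.set_torsion(resnum, "chi2", 65.01)
        prot.set_torsion(resnum, "chi3", 0.0)
    return replicate(prot, n_subunits, rise, 0.0)


def fibril_core_inputs(seed=0, prediction_jitter=4.0,
                       prediction_uncertainty=20.0):
    """The fibril-core calculation inputs at study conditions.

    Returns a dict with the core sequence (residues 441-460), the parsed
    ten unambiguous contacts, the in-register intermolecular set, the
    merged backbone dihedral restraints, and the refinement-round
    side-chain chi-1 restraints for I450, Y453, N454, L456 and V457.

    The dihedral predictions emulate two independent predictor outputs:
    each reports the reference conformation's backbone torsions perturbed
    by seeded Gaussian jitter, for the strand-interior residues only
    (turn-flanking residues are where real predictors disagree or return
    ambiguous classes, and the two-source consensus drops them); the two
    sources then pass through the 20-degree agreement rule.  The chi-1
    restraints likewise derive from the reference conformation.
    """
    from .chemshift import DihedralPrediction, merge_dihedral_predictions
    from .restraints import (
        INREGISTER_HBOND_PAIRS,
        INREGISTER_REGISTRY,
        UNAMBIGUOUS_CONTACTS,
        DihedralRestraint,
        make_inregister_restraints,
        parse_contact_list,
    )

    seq_full, start_full = load_construct()
    start = 441
    sequence = seq_full[start - start_full:461 - start_full]  # 441-460
    contacts = parse_contact_list(UNAMBIGUOUS_CONTACTS, sequence=sequence,
                                  start_number=start)
    inregister = make_inregister_restraints(
        INREGISTER_REGISTRY, INREGISTER_HBOND_PAIRS,
        sequence=sequence, start_number=start)
    ref = reference_fold()
    segments = [(442, 444), (448, 451), (455, 459)]
    rng = np.random.default_rng(seed)

    def prediction_source(tag):
        preds = []
        for (a, b) in segments:
            for resnum in range(a, b + 1):
                for angle in ("phi", "psi"):
                    if not ref.has_torsion(resnum, angle):
                        continue
                    val = ref.get_torsion(resnum, angle) \
                        + rng.normal(0.0, prediction_jitter)
                    val = (val + 180.0) % 360.0 - 180.0
                    if val == -180.0:
                        val = 180.0
                    preds.append(DihedralPrediction(
                        resnum, angle, float(val), prediction_uncertainty,
                        tag))
        return preds

    pred_a = prediction_source("primary")
    pred_b = prediction_source("secondary")
    dihedrals = merge_dihedral_predictions(pred_a, pred_b)
    chi_extras = RestraintSet()
    for resnum in (450, 453, 454, 456, 457):
        chi_extras.add(DihedralRestraint(
            resnum, "chi1", ref.get_torsion(resnum, "chi1"), 30.0))
    round1 = RestraintSet()
    round1.extend(contacts)
    round1.extend(inregister)
    for d in dihedrals:
        round1.add(d)
    return {"sequence": sequence, "start_number": start,
            "contacts": contacts, "inregister": inregister,
            "dihedrals": dihedrals, "round1": round1,
            "round2_extras": chi_extras, "reference": ref}


# --------------------------------------------------------------------------
# Dark-field images
# --------------------------------------------------------------------------

def _render_polyline(canvas, path, linear_density, sigma, pixel_size):
    """Add a filament's mass (kDa per pixel) to the canvas: a Gaussian
    cross-section of width ``sigma`` around the polyline, normalized so the
    integrated mass per unit length equals ``linear_density``."""
    h, w = canvas.shape
    pts = np.asarray(path, float)
    reach = 4.0 * sigma + 2.0 * pixel_size
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = p1 - p0
        seg_len = float(np.linalg.norm(seg))
        if seg_len < 1e-9:
            continue
        lo = np.minimum(p0, p1) - reach
        hi = np.maximum(p0, p1) + reach
        c0 = max(0, int(lo[0] / pixel_size))
        c1 = min(w, int(math.ceil(hi[0] / pixel_size)) + 1)
        r0 = max(0, int(lo[1] / pixel_size))
        r1 = min(h, int(math.ceil(hi[1] / pixel_size)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * pixel_size
        ys = (np.arange(r0, r1) + 0.5) * pixel_size
        X, Y = np.meshgrid(xs, ys)
        rel = np.stack([X - p0[0], Y - p0[1]], axis=-1)
        t = np.clip((rel @ seg) / (seg_len ** 2), 0.0, 1.0)
        proj = p0 + t[..., None] * seg
        d = np.hypot(X - proj[..., 0], Y - proj[..., 1])
        # Avoid double-counting rounded caps of interior joints: weight by
        # the projected-arc ownership (end caps only at the polyline ends).
        amp = linear_density * pixel_size ** 2 / (sigma * math.sqrt(2 * math.pi))
        canvas[r0:r1, c0:c1] += amp * np.exp(-(d ** 2) / (2 * sigma ** 2))


def _path_intersections(paths, radius):
    """Crossing points between distinct polylines (nm)."""
    out = []
    lines = [LineString(np.asarray(p, float)) for p in paths]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            if not lines[i].intersects(lines[j]):
                continue
            inter = lines[i].intersection(lines[j])
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Point":
                    out.append((float(g.x), float(g.y)))
                else:
                    c = g.centroid
                    out.append((float(c.x), float(c.y)))
    return out


def gen_darkfield_image(fibril_paths, fibril_mpl_true, tmv_paths,
                        pixel_size=1.0, background=40.0,
                        noise_model="mixed", seed=0, shape=(1024, 1024),
                        tmv_mpl=TMV_MPL, counts_per_kda=2.0,
                        background_variation=0.1,
                        background_corr_nm=600.0, read_noise_sd=2.0,
                        bit_depth=8, quantize=True):
    """Synthetic dark-field TEM image of fibrils plus TMV standard rods.

    Scattered intensity per pixel is proportional to the local projected
    mass density (the linearity at the heart of the MPL method): filaments
    are rendered as Gaussian-cross-section lines whose integrated mass per
    unit length equals their MPL, TMV rods at ``tmv_mpl``.  The background
    is a smoothly varying 2D field (mean ``background`` counts, fractional
    variation ``background_variation`` with correlation length
    ``background_corr_nm``); noise is Poisson on signal + background, plus
    Gaussian read noise, per ``noise_model``.  Overlapping filament/rod
    segments are located geometrically and flagged in the ground-truth
    metadata so measurement rectangles can avoid them.

    Returns a :class:`DarkFieldImage` with the truth attached.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    h, w = shape
    frame_w, frame_h = w * pixel_size, h * pixel_size
    for path in list(fibril_paths) + list(tmv_paths):
        pts = np.asarray(path, float)
        if (pts < 0).any() or (pts[:, 0] > frame_w).any() \
                or (pts[:, 1] > frame_h).any():
            raise ValueError("filament path outside the image frame")
    rng = np.random.default_rng(seed)
    mass = np.zeros(shape, float)  # kDa per pixel
    sigma_f = FIBRIL_DIAMETER_NM / _FWHM
    sigma_t = TMV_DIAMETER_NM / _FWHM
    for path in fibril_paths:
        _render_polyline(mass, path, fibril_mpl_true, sigma_f, pixel_size)
    for path in tmv_paths:
        _render_polyline(mass, path, tmv_mpl, sigma_t, pixel_size)
    signal = counts_per_kda * mass

    bg = np.full(shape, float(background))
    if background_variation > 0 and background > 0:
        fieldarr = rng.standard_normal(shape)
        fieldarr = gaussian_filter(fieldarr, background_corr_nm / pixel_size,
                                   mode="reflect")
        std = fieldarr.std()
        if std > 0:
            fieldarr /= std
        bg = bg * np.clip(1.0 + background_variation * fieldarr, 0.05, None)

    expected = signal + bg
    if noise_model == "none":
        data = expected
    elif noise_model == "poisson":
        data = rng.poisson(expected).astype(float)
    elif noise_model == "gaussian":
        data = expected + rng.normal(0.0, read_noise_sd, shape)
    elif noise_model == "mixed":
        data = rng.poisson(expected).astype(float) \
            + rng.normal(0.0, read_noise_sd, shape)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    data = np.clip(data, 0.0, None)
    if quantize:
        data = np.clip(np.rint(data), 0, 2 ** bit_depth - 1)

    crossings = _path_intersections(
        list(fibril_paths) + list(tmv_paths),
        radius=max(sigma_f, sigma_t))
    truth = {
        "generator": "gen_darkfield_image",
        "seed": seed,
        "fibril_mpl_true": fibril_mpl_true,
        "tmv_mpl": tmv_mpl,
        "pixel_size": pixel_size,
        "counts_per_kda": counts_per_kda,
        "background": background,
        "background_variation": background_variation,
        "noise_model": noise_model,
        "fibril_paths": [np.asarray(p, float).tolist() for p in fibril_paths],
        "tmv_paths": [np.asarray(p, float).tolist() for p in tmv_paths],
        "crossings": crossings,
        "sigma_fibril": sigma_f,
        "sigma_tmv": sigma_t,
    }
    return DarkFieldImage(data, pixel_size, bit_depth, "synthetic", truth)


def random_filament_layout(config: SynthConfig, shape=(1024, 1024),
                           n_fibrils=4, n_tmv=2, seed=None,
                           lane_spacing=170.0, angle_jitter=1.5):
    """Quasi-aligned filament layout for one synthetic image.

    Filaments and TMV rods lie in parallel "lanes" sharing one dominant
    direction per image (as in flow-aligned depositions), with small
    per-filament angular jitter and random along-lane placement; lanes are
    spaced so measurement and flanking background rectangles of one
    filament stay clear of its neighbours.  Returns
    ``(fibril_paths, tmv_paths)`` in nm.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = shape
    fw, fh = w * config.image_pixel_size, h * config.image_pixel_size
    margin = 120.0
    base_angle = rng.uniform(0.0, 180.0)
    u = np.array([math.cos(math.radians(base_angle)),
                  math.sin(math.radians(base_angle))])
    v = np.array([-u[1], u[0]])
    center = np.array([fw / 2.0, fh / 2.0])
    n_total = n_fibrils + n_tmv
    offsets = (np.arange(n_total) - (n_total - 1) / 2.0) * lane_spacing
    # Standards on inner lanes (they must always yield usable boxes);
    # fibril lanes shuffled among the rest.
    order = np.argsort(np.abs(offsets), kind="stable")
    tmv_offsets = [offsets[i] for i in order[:n_tmv]]
    fib_offsets = [offsets[i] for i in order[n_tmv:]]
    rng.shuffle(fib_offsets)
    offsets = tmv_offsets + fib_offsets
    half_span = min(fw, fh) / 2.0 - margin
    kinds = ["tmv"] * n_tmv + ["fibril"] * n_fibrils
    fibrils, tmvs = [], []
    lo = margin / 2.0
    hi = np.array([fw, fh]) - margin / 2.0
    for kind, off in zip(kinds, offsets):
        jit = math.radians(rng.uniform(-angle_jitter, angle_jitter))
        uj = np.array([math.cos(math.radians(base_angle) + jit),
                       math.sin(math.radians(base_angle) + jit)])
        length = rng.uniform(0.75, 1.0) * 2.0 * half_span
        mid_shift = rng.uniform(-0.15, 0.15) * half_span
        c = center + off * v + mid_shift * uj
        # Parametric clip of c + t*uj against the margin frame, keeping
        # the lane direction intact.
        t_lo, t_hi = -length / 2.0, length / 2.0
        for dim in (0, 1):
            if abs(uj[dim]) < 1e-12:
                continue
            t_a = (lo - c[dim]) / uj[dim]
            t_b = (hi[dim] - c[dim]) / uj[dim]
            t_lo = max(t_lo, min(t_a, t_b))
            t_hi = min(t_hi, max(t_a, t_b))
        if t_hi - t_lo < 150.0:
            continue
        pts = np.array([c + t_lo * uj, c + t_hi * uj])
        (fibrils if kind == "fibril" else tmvs).append(pts)
    return fibrils, tmvs


# --------------------------------------------------------------------------
# AFM traces
# --------------------------------------------------------------------------

def gen_afm_profile(pitch, amplitude, length, sampling, noise_sd, seed=0,
                    baseline=FIBRIL_DIAMETER_NM, phase=0.0):
    """Periodic fibril height trace: baseline + sinusoid + noise.

    ``sampling`` must resolve the pitch (>= 4 samples per period) or an
    aliasing error is raised.  Returns ``((distance_nm, height_nm),
    truth)``.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if sampling <= 0 or length <= 0:
        raise ValueError("length and sampling must be positive")
    if sampling >= pitch / 4.0:
        raise ValueError(
            f"sampling step {sampling} nm too coarse for pitch {pitch} nm "
            "(needs >= 4 samples per period)")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length + sampling / 2.0, sampling)
    y = baseline + amplitude * np.sin(2 * math.pi * x / pitch + phase)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.shape)
    truth = {"generator": "gen_afm_profile", "seed": seed,
             "pitch_true": pitch, "amplitude": amplitude,
             "baseline": baseline, "noise_sd": noise_sd,
             "sampling": sampling, "length": length}
    return (x, y), truth


# --------------------------------------------------------------------------
# Ground-truth sidecars
# --------------------------------------------------------------------------

_SIDECAR_HEADER = "# crossbeta ground-truth sidecar\nrecord\tfield\tvalue\n"


def write_sidecar(truth: dict, path):
    """Plain tabular ground-truth sidecar: record / field / JSON value."""
    gen = truth.get("generator", "unknown")
    lines = [_SIDECAR_HEADER.rstrip("\n")]
    for key, value in truth.items():
        lines.append(f"{gen}\t{key}\t{json.dumps(value)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sidecar(path):
    truth = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or \
                    line.startswith("record\t"):
                continue
            _rec, fieldname, value = line.split("\t", 2)
            truth[fieldname] = json.loads(value)
    return truth
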