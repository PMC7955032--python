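# Methods

This note documents the models, parameter choices and limitations behind
`crossbeta`.  Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Secondary chemical shifts and strand calling

The per-residue statistic is Δ = (δCα−δCα_rc) − (δCβ−δCβ_rc) in ppm,
computed against a bundled peptide random-coil reference table
(`data/random_coil_shifts.tsv`, Wishart-type values; any table with the
same layout can be substituted).  Δ < 0 indicates β-strand.  Glycine has
no Cβ and contributes ΔδCα alone; because the Cα secondary shift is
itself negative in strands, no sign change is applied and negative still
flags β.  Δ is invariant under a constant referencing offset applied
consistently to one atom type in both the observed and reference tables
(property-tested).

Strand calling takes maximal runs of consecutive assigned residues with
Δ below a threshold (default 0.0 ppm) of length ≥ `min_len` (default 3);
unassigned residues break runs, and there is no gap tolerance.  These
defaults treat the three RHIM-core strands as contiguous runs.

**Consensus of two dihedral predictors.**  Predictions for the same
(residue, angle) from two sources are kept only when they agree within
20° on the circle.  The emitted restraint is centred on the primary
source with half-width `max(u_a, u_b, d/2 + max(u_a, u_b), d)` where `d`
is the circular difference — the final `d` term is this package's
addition to the conventional expansion, needed to make the guarantee
"both predictions lie inside the bound" hold unconditionally (without it
the guarantee fails when `d > 2·max(u_a, u_b)`).

## Restraints

* Contact-list tokens (`V441Cγ−G451Cα`, Greek or PDB atom names, any
  dash) become flat-bottom distance restraints: carbon–carbon pairs
  5.5 ± 1.5 Å (long-mixing ¹³C–¹³C recoupling class), nitrogen-involving
  pairs 4.5 ± 2.5 Å (¹⁵N–¹³C TEDOR class).  Bounds are assigned by atom
  type because the experiment class, not a per-contact table, is what is
  published.  Degenerate Greek labels on branched side chains (Val Cγ,
  Leu Cδ) resolve to branch 1.
* All printed contacts are intramolecular (subunit offset 0): the MPL
  result of one molecule per cross-β unit makes within-molecule
  assignment the only consistent reading.
* The in-register generator emits, per subunit interface, three same-atom
  stacking restraints (N444Cβ, V448Cβ, S455C′ at 4.75 ± 0.1 Å — the C′
  reading of "CO" is assumed) and five explicit backbone hydrogen bonds
  (H…O 2.3 ± 0.1 Å, N…O 3.3 ± 0.1 Å).  The published H-bond pair list
  "I451NH and G450CO" is kept as printed (donor 451, acceptor 450) even
  though the residue-type labels conflict with the numbering used
  elsewhere (I450/G451); the restraint is defined by residue numbers and
  backbone atoms, so it is well-formed either way, and the pair list is
  exposed as data (`INREGISTER_HBOND_PAIRS`) rather than silently
  "corrected".
* In a pleated strand consecutive amides point to alternating adjacent
  subunits, so H-bond components are evaluated against the nearer of the
  ±1 images ("adjacent either side").  This is what lets a uniform
  extended strand satisfy all five published H-bonds simultaneously.
* Violation energy is a flat-bottom square well, `k·(excess)²` with
  k = 50 energy-units/Å² by default; ambiguity groups combine member
  distances as `(Σ r⁻⁶)^(−1/6)`; dihedral violations are computed on the
  circle and weighted `k/5` by default (distance-dominant weighting —
  the relative weights among terms are not published and are exposed as
  configuration).  Only relative energies matter to the annealing.
  Inside the annealing energy (not the report) wide wells (total width
  > 0.5 Å, i.e. the assignment-derived contacts) additionally carry a
  small linear wall component (1 energy-unit/Å): a purely quadratic well
  has zero slope at its boundary, so weak soft terms would otherwise park
  the minimum a few mÅ outside the flat bottom.  They also carry a weak
  harmonic centering on the target distance (0.15 energy-units/Å², more
  than two orders below the wall constant) — the target is the best
  available distance estimate, and with a perfectly flat bottom the
  zero-violation set leaves ~1.5 Å of conformational slack per contact,
  enough to admit distinct backbone arrangements.  Tight wells (stacking,
  H-bonds) stay purely quadratic — with fixed covalent geometry small
  deviations there are expected, and pulling on them would displace the
  error into the contacts.

## Chain building and fibril geometry

Coordinates are built from internal coordinates by sequential frame
placement with fixed canonical geometry (N–Cα 1.458 Å, Cα–C′ 1.525 Å,
C′–N 1.329 Å, C′=O 1.231 Å, standard angles), ω fixed trans, proline φ
fixed at −65°, and CB placed at −122.6° from C′ about the N–Cα axis
(L-stereochemistry).  Side-chain heavy atoms and polar hydrogens come
from per-residue internal-coordinate templates with rotatable χ angles;
amide hydrogens are placed in the peptide plane anti to the carbonyl
oxygen, so hydrogen-bond detection needs no external tool.  Two
approximations: the proline ring is placed with fixed pucker torsions and
its N–CD closure is approximate (the bond is recorded so the clash term
ignores it), and β-branch stereo assignments (Thr, Ile) are idealized.
A three-residue build is verified against an independent closed-form
planar-chain oracle to 10⁻⁶ Å.

A fibril is a protomer plus screw parameters: subunit *s* carries
`Rz(twist·s)·x + (0,0,rise·s)` exactly.  The axis is +z and positive
twist is right-handed, so a left-handed fibril has negative twist.
Rise/twist are measured back via the least-squares (SVD) superposition of
adjacent subunits and the screw decomposition of the resulting transform;
RMSD uses proper rotations only and is cross-checked in the tests against
an independent quaternion (Horn) implementation.  Pitch is estimated from
AFM height traces by detrended autocorrelation (first prominent
off-origin peak, quadratic sub-sample interpolation) with a periodogram
cross-check; traces whose peak prominence is below 0.2 of the zero-lag
value are reported non-periodic.

## Strict-symmetry annealing

Torsion-angle dynamics is replaced by Metropolis Monte Carlo in torsion
space.  State: all free φ/ψ (proline φ and the first residue's φ are
fixed), rotatable χ, plus two rigid orientation angles of the protomer
relative to the fibril axis (rotations about z and translations are
symmetry-neutral for an untwisted stack).  Energy is evaluated on the
full symmetric stack (default 5 subunits at rise 4.75 Å, twist 0 as in
the published calculation): intra-subunit terms count n-fold and
interface terms (n−1)-fold, which is exact under strict symmetry.  The
images exist only implicitly, so the strict-symmetry invariant holds to
floating-point exactness at every step.

Schedule and moves:

* Ladder 4000 → 25 in 12.5 decrements (as published), acting through the
  Metropolis criterion at `temperature_scale` energy-units per
  kelvin-equivalent.  The published MD timesteps do not transfer; one
  "step" is a sweep of one proposal per free variable, default 20 sweeps
  per level (the fibril-core runs in the tests and acceptance script use
  6 — the package's desk-scale problem size).  `temperature_scale`
  defaults to 0.025; the 20-residue 5-subunit system uses 0.125 because
  per-move energy changes scale with the subunit multiplicity.
* Proposals: single-variable Gaussian steps with per-variable adaptive
  widths (target acceptance 0.3), occasional uniform resampling
  (p = 0.12), and anti-correlated (φᵢ, ψᵢ) coupled moves (p = 0.35 where
  both exist) that adjust the local backbone while approximately
  preserving the downstream chain direction — the standard cure for the
  lever-arm stiffness of sequential torsion moves.
* The soft-sphere repulsion (quadratic below 0.85·ΣvdW, heavy atoms
  only, intra-residue and ≤ 4-bond pairs excluded, images ±1) is ramped
  quadratically from 1% to full strength over the descending ladder, the
  usual annealing device for escaping chain-threading traps.
* After the ladder: extra levels at the final temperature and two reheat
  ("polish") mini-cycles from 400 down that let the structure hop out of
  shallow cold traps.  Throughout the cold (full-repulsion) phase the
  kernel tracks the lexicographically best state visited — assignment-well
  violation energy first, total energy second — so a transient visit to a
  restraint-satisfying basin is never lost.
* Endgame from the tracked state: a satisfaction-directed stage
  (stochastic sweeps and a deterministic pattern search accepting moves
  by the same lexicographic rule), then a final monotone descent — pure
  energy minimization that never worsens the assignment-well violations,
  with shrinking steps.  The final descent is monotone: final energy ≤
  the energy entering it, asserted in the tests.
* The refinement round adds a short-range attraction between hydrophobic
  side-chain carbons (−ε inside 5.5 Å, linear to zero at 6.5 Å,
  ε = 0.5 ≪ k) standing in for implicit solvation; it can never override
  a restraint.

The two-round protocol anneals `counts[0]` structures from random
torsions, keeps the `keep[0]` lowest-energy members, then anneals
`counts[1]` structures warm-started from the keepers (first pass exact,
repeats perturbed by 5°) with χ restraints and the compaction term, and
reports the best `keep[1]` plus their medoid (minimum summed backbone
RMSD).  The final selection is curated in the conventional NMR-ensemble
way (`select_accepted`): members whose assignment-derived distance
restraints are violated are rejected before energy ranking, falling back
to pure energy rank when too few qualify; `select_best` (pure
lowest-energy, seed tie-break) remains available.  Published counts are 108/200 with best-5/best-10; the bundled
tests and acceptance run the reduced 8/8, keep 3/3 protocol.  All seeds
are recorded for replay, and equal energies break ties by seed index.

Degenerate input: if no annealed structure satisfies every restraint the
minimum-violation ensemble is returned with a warning rather than an
error.

## Synthetic data: what it emulates, and what it does not

Every generator is seeded (identical configuration ⇒ bit-identical
output) and writes its ground truth to a sidecar record; recovery tests
read truth only from the sidecar.

* **Shift tables.**  Strand residues get Cα −2.0 / Cβ +2.0 ppm from
  random coil (typical β-sheet magnitudes; the data fix only the sign),
  plus Gaussian noise (default 0.2 ppm, ≈ linewidth/4).  The
  deposited-assignment emulator restricts shifts to the rigid core
  441–461 and gives the assigned non-strand residues (the 445–447 arc,
  the 453 turn, residue 461) a positive Δ bias of +1 ppm per shift,
  matching the qualitative feature that only the three strands show
  negative values.  Leaving those residues exactly at random coil would
  make the called segments flip with the noise seed — a degenerate
  boundary, not a property of the data being emulated.
* **Construct sequence.**  The bundled FASTA is a labelled stand-in: the
  fibril-core region 440–461 follows the experimentally characterized
  sequence; the His-tag leader and the disordered flanks (invisible in
  the fibril core and irrelevant to every computation except length and
  mass) are synthetic filler chosen so the stand-in reproduces the
  documented bulk properties, 86 residues and 9.57 kDa average mass.
* **Reference fold.**  The emulated dihedral-prediction tables report
  the torsions of a bundled synthetic reference conformation
  (`data/reference_fold_synthetic.tsv`), perturbed per source by seeded
  4° jitter, for the strand-interior residues only (442–444, 448–451,
  455–459 — turn-flanking residues are where real predictors disagree
  and the consensus drops them).  The reference was constructed once by
  annealing under only the printed contacts + in-register restraints
  (with broad β guidance wells) and polishing until every contact is
  satisfied; its strand interiors sit in the β region.  This mirrors how
  real predictions relate to the real structure: they are consistent
  with the other restraints because both derive from the same molecule.
  The reference is *not* the deposited structure, and no test asserts
  coordinate agreement with the deposition — only restraint satisfaction
  and geometry properties.
* **Dark-field images.**  Scattered intensity is proportional to local
  projected mass (the method's core assumption; no electron optics are
  modelled).  Filaments are rendered as Gaussian-cross-section lines
  (fibril FWHM 1.8 nm from the AFM diameter, standard rods FWHM 18 nm at
  131 kDa/nm), over a smoothly varying background field (default 40
  counts, 10% fractional variation, 600 nm correlation length) with
  Poisson shot noise plus Gaussian read noise and 8-bit quantization.
  The spatial correlation of the real background is not published; the
  default is set so flanking-box subtraction leaves only a small
  curvature residual and the generator satisfies the module's recovery
  property (pooled mean within 5% of truth over ≥ 100 boxes) while the
  per-box histogram width stays background-dominated (several-fold wider
  than counting statistics alone) — a rougher field at ~200 nm makes the
  width more extreme but biases the pooled mean beyond what rectangle
  background subtraction can correct.  Layouts place filaments in quasi-parallel lanes (as in
  flow-aligned depositions) so measurement and background rectangles
  have room; crossings between filaments are located geometrically and
  recorded so rectangles avoid them.
* **AFM traces.**  Baseline + sinusoid + Gaussian noise; sampling must
  resolve ≥ 4 points per period or the generator refuses (aliasing).

What passing these tests does *not* show: recovery from real
micrographs (defocus/astigmatism gradients, stain artefacts, filament
curvature), real spectra (assignment errors, peak overlap), or agreement
of the calculated fold with the deposition.

## Mass-per-length measurement

Rectangles (60 × 120 nm) are laid along each filament at the local
tangent and sampled bilinearly on a pixel-pitch grid.  Background is the
mean of two flanking rectangles one box-width to either side; measurement
boxes are excluded if they touch the frame edge (including room for
their background boxes), intersect another filament or a known crossing,
or contain saturated pixels, and background boxes must additionally keep
30 nm clear of every *other* filament centerline (wide rods' intensity
tails would otherwise bias the background).  Excluded boxes are counted
by reason in the report.  Calibration is per image:
`kDa/intensity = mean(131 · length / net)` over that image's standard
boxes.  Calibrated MPL is invariant to global intensity scaling and to
uniform background offsets (tested).  The histogram fit is least-squares
Gaussian on 2 kDa/nm bins, FWHM = 2√(2 ln 2)·σ, centre standard error
from the fit covariance, with a sample-statistics fallback on
non-convergence.  Stoichiometry is m = MPL·rise/monomer-mass, reported
as the real value, nearest integer and discrepancy.

## Numerical choices and edge cases

* All coordinates in Å; nm at the pitch/MPL interfaces.
* Flat-bottom wells have exactly zero energy and zero violation inside
  their bounds; reports sort by violation with stable ties.
* `measure_rise_twist` with a near-identity rotation (< 10⁻⁹ rad)
  reports twist 0 with the axis taken as +z.
* Histogram fit requires n ≥ 10; degenerate (zero-variance) samples
  return the sample value with FWHM 0.
* Kernels are compiled with numba (cached); the annealing RNG is the
  kernel's own seeded generator, so replays are bit-identical on a given
  platform.

## Known limitations

* Fixed canonical covalent geometry (no bond/angle relaxation) makes the
  tight H-bond wells (±0.1 Å) satisfiable only to ~0.05–0.1 Å on some
  donors of the idealized reference; contacts and stacking are exactly
  satisfiable.
* The annealing is a Monte-Carlo stand-in for torsion-angle dynamics;
  at the reduced 8/8 counts an occasional seed may leave its best
  structure marginally short of full contact satisfaction.
* No ambiguous-restraint assignment bookkeeping beyond r⁻⁶ groups; no
  TorsionDB/EEFx-class force-field terms; no twist during calculation
  (twisted replication is available for geometry work only).
* The auto-tracer in `mpl_tem` is a convenience (ridge filter +
  skeletonization); quantitative work should use curated centerlines.
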