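"""Mass-per-length quantitation from dark-field TEM images.

Dark-field (beam-tilted) TEM intensity is, to a good approximation, linear
in the local projected mass density.  Mass-per-length (MPL, kDa/nm) of a
filament is therefore measured by integrating the net intensity in a
rectangle laid along the filament (default 60 nm x 120 nm), subtracting
the local background estimated from flanking rectangles, and calibrating
against tobacco mosaic virus (TMV) rods co-deposited on the same grid
(internal standard, 131 kDa/nm).  Per-box MPL values are summarized in a
histogram and fit with a Gaussian; the center value divided into
monomer-mass-per-rise gives the number of molecules per cross-beta unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from shapely.geometry import LineString, Polygon

__all__ = [
    "DarkFieldImage",
    "SegmentBox",
    "MplMeasurement",
    "MplFit",
    "TMV_MPL",
    "integrate_box",
    "calibrate",
    "boxes_along_path",
    "measure_image",
    "measure_image_set",
    "fit_mpl_histogram",
    "stoichiometry",
    "trace_filaments",
]

TMV_MPL = 131.0  # kDa/nm, tobacco mosaic virus internal standard
BOX_LENGTH = 120.0  # nm
BOX_WIDTH = 60.0  # nm


class MplError(ValueError):
    pass


# --------------------------------------------------------------------------
# Image container
# --------------------------------------------------------------------------

@dataclass
class DarkFieldImage:
    """Calibrated dark-field intensity grid.

    ``data`` is a 2D array (row = y, col = x), ``pixel_size`` in nm/pixel.
    ``provenance`` is "real" or "synthetic"; synthetic images carry their
    ground truth in ``truth`` (and in a sidecar file on disk).
    """

    data: np.ndarray
    pixel_size: float
    bit_depth: int = 8
    provenance: str = "real"
    truth: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.pixel_size <= 0:
            raise MplError("pixel_size must be positive")
        if (np.asarray(self.data, float) < 0).any():
            raise MplError("intensities must be non-negative")

    @property
    def shape_nm(self):
        return (self.data.shape[0] * self.pixel_size,
                self.data.shape[1] * self.pixel_size)

    @property
    def saturation_level(self):
        return float(2 ** self.bit_depth - 1)

    def to_tiff(self, path):
        import tifffile

        dtype = np.uint8 if self.bit_depth <= 8 else np.uint16
        arr = np.clip(np.rint(self.data), 0, self.saturation_level)
        tifffile.imwrite(str(path), arr.astype(dtype))

    @classmethod
    def from_tiff(cls, path, pixel_size, provenance="real", truth=None):
        import tifffile

        arr = tifffile.imread(str(path))
        bit_depth = 16 if arr.dtype.itemsize > 1 else 8
        return cls(arr, pixel_size, bit_depth, provenance, truth)


# --------------------------------------------------------------------------
# Measurement boxes
# --------------------------------------------------------------------------

@dataclass
class SegmentBox:
    """A measurement rectangle: center (x, y) in nm, orientation of the
    long axis in degrees, and the role it plays (fibril / standard /
    background)."""

    center: tuple
    orientation: float
    length: float = BOX_LENGTH
    width: float = BOX_WIDTH
    role: str = "fibril"

    def axes(self):
        t = math.radians(self.orientation)
        u = np.array([math.cos(t), math.sin(t)])  # along length
        v = np.array([-math.sin(t), math.cos(t)])  # across width
        return u, v

    def corners(self):
        c = np.asarray(self.center, float)
        u, v = self.axes()
        hl, hw = self.length / 2.0, self.width / 2.0
        return np.array([c + hl * u + hw * v, c + hl * u - hw * v,
                         c - hl * u - hw * v, c - hl * u + hw * v])

    def polygon(self):
        return Polygon(self.corners())

    def within(self, image: DarkFieldImage, margin=0.0):
        h_nm, w_nm = image.shape_nm
        corners = self.corners()
        return (corners[:, 0] >= margin).all() and \
               (corners[:, 1] >= margin).all() and \
               (corners[:, 0] <= w_nm - margin).all() and \
               (corners[:, 1] <= h_nm - margin).all()

    def shifted(self, offset_across, role="background"):
        u, v = self.axes()
        c = np.asarray(self.center, float) + offset_across * v
        return SegmentBox(tuple(c), self.orientation, self.length,
                          self.width, role)


@dataclass
class MplMeasurement:
    net_intensity: float
    length: float
    calibration: float  # kDa per intensity-unit
    mpl: float
    box: SegmentBox | None = None
    flags: tuple = ()

    def __post_init__(self):
        expected = self.net_intensity * self.calibration / self.length
        if abs(expected - self.mpl) > 1e-6 * max(1.0, abs(self.mpl)):
            raise MplError("mpl inconsistent with net * calibration / length")


def _sample_box(image: DarkFieldImage, box: SegmentBox):
    """Bilinear samples on a pixel-pitch grid covering the box."""
    px = image.pixel_size
    n_u = max(2, int(round(box.length / px)))
    n_v = max(2, int(round(box.width / px)))
    u_off = (np.arange(n_u) - (n_u - 1) / 2.0) * px
    v_off = (np.arange(n_v) - (n_v - 1) / 2.0) * px
    u, v = box.axes()
    c = np.asarray(box.center, float)
    pts = (c[None, None, :]
           + u_off[:, None, None] * u[None, None, :]
           + v_off[None, :, None] * v[None, None, :])
    rows = pts[..., 1] / px - 0.5
    cols = pts[..., 0] / px - 0.5
    vals = map_coordinates(image.data.astype(float), [rows.ravel(),
                                                      cols.ravel()], order=1)
    return vals.reshape(n_u, n_v)


def integrate_box(image: DarkFieldImage, box: SegmentBox,
                  background_boxes=None):
    """Net integrated intensity of a box after local background subtraction.

    The box is sampled on a pixel-pitch grid with bilinear interpolation
    (boxes need not be axis-aligned); the mean per-sample background from
    the background boxes (default: two flanking boxes one box-width to
    either side) times the sample count is subtracted.  Returns
    ``(net_intensity, info)`` where info carries flags ('saturated' when
    any sample reaches the bit-depth maximum) and the background level.
    """
    if not box.within(image):
        raise MplError("measurement box exceeds the image frame")
    if background_boxes is None:
        background_boxes = [box.shifted(+box.width), box.shifted(-box.width)]
    background_boxes = [b for b in background_boxes if b.within(image)]
    if not background_boxes:
        raise MplError("no background box fits inside the frame")
    samples = _sample_box(image, box)
    flags = []
    if (samples >= image.saturation_level).any():
        flags.append("saturated")
    bg_means = [float(_sample_box(image, b).mean()) for b in background_boxes]
    bg_per_sample = float(np.mean(bg_means))
    net = float(samples.sum() - bg_per_sample * samples.size)
    info = {"flags": tuple(flags), "background_per_pixel": bg_per_sample,
            "n_samples": samples.size, "raw_sum": float(samples.sum())}
    return net, info


def calibrate(standard_measurements, tmv_mpl=TMV_MPL):
    """Calibration factor (kDa per intensity-unit) from internal-standard
    boxes: ``mean(tmv_mpl * length / net_intensity)`` over the standard
    boxes of one image (per-image calibration)."""
    ms = list(standard_measurements)
    if not ms:
        raise MplError("need at least one standard box")
    factors = []
    for net, length in ms:
        if net <= 0:
            raise MplError("non-positive standard intensity")
        factors.append(tmv_mpl * length / net)
    return float(np.mean(factors))


# --------------------------------------------------------------------------
# Box placement along filaments
# --------------------------------------------------------------------------

def boxes_along_path(path, length=BOX_LENGTH, width=BOX_WIDTH, step=None,
                     role="fibril"):
    """Rectangles centred on a polyline, oriented along the local tangent,
    spaced ``step`` (default: the box length, i.e. non-overlapping)."""
    pts = np.asarray(path, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise MplError("path must be a polyline of >= 2 (x, y) points")
    step = step or length
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = []
    s = length / 2.0
    while s <= total - length / 2.0 + 1e-9:
        k = int(np.searchsorted(cum, s, side="right") - 1)
        k = min(k, len(seg) - 1)
        frac = (s - cum[k]) / max(seg_len[k], 1e-12)
        c = pts[k] + frac * seg[k]
        ang = math.degrees(math.atan2(seg[k][1], seg[k][0]))
        out.append(SegmentBox(tuple(c), ang, length, width, role))
        s += step
    return out


def _box_flags(box, own_path, all_paths, image, exclusion_points=(),
               exclusion_radius=None, clearance=30.0):
    """One-filament guard: a measurement box must contain exactly one
    filament, stay inside the frame (with room for its background boxes),
    and keep clear of known filament crossings.  Background boxes must
    additionally keep ``clearance`` nm from every filament centerline so
    that wide rods' intensity tails cannot leak into the background
    estimate."""
    flags = []
    margin_ok = box.within(image) and \
        box.shifted(+box.width).within(image) and \
        box.shifted(-box.width).within(image)
    if not margin_ok:
        flags.append("edge")
        return flags
    poly = box.polygon()
    for p in all_paths:
        if p is own_path:
            continue
        if poly.intersects(LineString(np.asarray(p, float))):
            flags.append("crossing")
            break
    r = exclusion_radius if exclusion_radius is not None else box.width
    for pt in exclusion_points:
        if np.linalg.norm(np.asarray(box.center) - np.asarray(pt)) < r:
            if "crossing" not in flags:
                flags.append("crossing")
            break
    for side in (+1, -1):
        bg = box.shifted(side * box.width)
        bgp = bg.polygon()
        bgp_buffered = bgp.buffer(clearance)
        contaminated = False
        for p in all_paths:
            line = LineString(np.asarray(p, float))
            # own filament flanks the background box by construction; any
            # other filament must keep an extra clearance so its intensity
            # tail cannot leak into the background estimate.
            region = bgp if p is own_path else bgp_buffered
            if region.intersects(line):
                contaminated = True
                break
        if contaminated:
            flags.append("background_contaminated")
            break
    return flags


def measure_image(image: DarkFieldImage, fibril_paths, standard_paths,
                  length=BOX_LENGTH, width=BOX_WIDTH, tmv_mpl=TMV_MPL,
                  exclusion_points=()):
    """Full per-image MPL measurement.

    Places boxes along each filament path, applies the one-filament /
    edge / saturation guards, calibrates on the internal-standard boxes of
    this image and converts fibril box intensities to kDa/nm.  Returns
    ``(DataFrame of accepted measurements, report dict)``; the report
    counts excluded boxes by reason.
    """
    report = {"excluded": {}, "n_standard": 0, "n_fibril": 0}

    def note(reason):
        report["excluded"][reason] = report["excluded"].get(reason, 0) + 1

    all_paths = list(fibril_paths) + list(standard_paths)
    std = []
    for path in standard_paths:
        for box in boxes_along_path(path, length, width, role="standard"):
            flags = _box_flags(box, path, all_paths, image,
                               exclusion_points)
            if flags:
                note(";".join(sorted(flags)))
                continue
            net, info = integrate_box(image, box)
            if info["flags"]:
                note(";".join(info["flags"]))
                continue
            std.append((net, box.length))
    if not std:
        raise MplError("no usable internal-standard box in this image")
    cal = calibrate(std, tmv_mpl)
    report["n_standard"] = len(std)
    report["calibration"] = cal

    rows = []
    for path in fibril_paths:
        for box in boxes_along_path(path, length, width, role="fibril"):
            flags = _box_flags(box, path, all_paths, image,
                               exclusion_points)
            if flags:
                note(";".join(sorted(flags)))
                continue
            net, info = integrate_box(image, box)
            if info["flags"]:
                note(";".join(info["flags"]))
                continue
            rows.append({"x": box.center[0], "y": box.center[1],
                         "orientation": box.orientation,
                         "net_intensity": net, "length": box.length,
                         "calibration": cal,
                         "mpl": net * cal / box.length})
    report["n_fibril"] = len(rows)
    df = pd.DataFrame(rows, columns=["x", "y", "orientation",
                                     "net_intensity", "length",
                                     "calibration", "mpl"])
    return df, report


def measure_image_set(images_with_paths, **kw):
    """Measure several images (each entry: ``(image, fibril_paths,
    standard_paths, exclusion_points)``); calibration is per image.
    Returns the pooled measurement DataFrame and the per-image reports."""
    frames, reports = [], []
    for entry in images_with_paths:
        image, fpaths, spaths, excl = entry
        df, rep = measure_image(image, fpaths, spaths,
                                exclusion_points=excl, **kw)
        frames.append(df)
        reports.append(rep)
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return pooled, reports


# --------------------------------------------------------------------------
# Histogram fit and stoichiometry
# --------------------------------------------------------------------------

@dataclass
class MplFit:
    center: float
    center_se: float
    fwhm: float
    n: int
    converged: bool = True
    bin_width: float = 2.0

    _FWHM_OF_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fit_mpl_histogram(measurements, bin_width=2.0):
    """Gaussian fit to the binned MPL histogram.

    Least-squares fit of ``a * exp(-(x - mu)^2 / (2 sigma^2))`` to the bin
    counts; FWHM = 2 sqrt(2 ln 2) sigma; the center standard error comes
    from the fit covariance.  Falls back (with a warning) to the sample
    mean/sd when the fit cannot converge.  Requires n >= 10.
    """
    vals = np.asarray(list(measurements), float)
    n = vals.size
    if n < 10:
        raise MplError("need at least 10 measurements to fit a histogram")
    sd = float(vals.std(ddof=1))
    mean = float(vals.mean())
    if sd < 1e-12:
        return MplFit(mean, 0.0, 0.0, n, True, bin_width)
    lo = math.floor(vals.min() / bin_width) * bin_width
    hi = math.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    if len(edges) < 4:
        edges = np.linspace(lo, hi, 5)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[1:] + edges[:-1])

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))

    try:
        p0 = (counts.max(), mean, sd)
        popt, pcov = curve_fit(gauss, centers, counts, p0=p0, maxfev=5000)
        a, mu, sigma = popt
        sigma = abs(float(sigma))
        se = float(math.sqrt(max(pcov[1, 1], 0.0)))
        return MplFit(float(mu), se, MplFit._FWHM_OF_SIGMA * sigma, n, True,
                      bin_width)
    except Exception:
        warnings.warn("Gaussian histogram fit failed; falling back to "
                      "sample statistics")
        return MplFit(mean, sd / math.sqrt(n), MplFit._FWHM_OF_SIGMA * sd,
                      n, False, bin_width)


def stoichiometry(center_mpl, monomer_mass_kda, rise_nm):
    """Molecules per cross-beta unit from a measured MPL center:
    ``m = MPL * rise / monomer_mass``.  Returns ``(m, nearest integer,
    |m - nearest|)``."""
    if center_mpl <= 0 or monomer_mass_kda <= 0 or rise_nm <= 0:
        raise MplError("all arguments must be positive")
    m = center_mpl * rise_nm / monomer_mass_kda
    return m, int(round(m)), abs(m - round(m))


# --------------------------------------------------------------------------
# Optional auto-tracing (plumbing; manual/TSV paths are authoritative)
# --------------------------------------------------------------------------

def trace_filaments(image: DarkFieldImage, min_length_nm=150.0,
                    ridge_sigma_nm=5.0):
    """Rudimentary filament auto-tracer: ridge filter + skeletonization,
    returning polylines (nm) of connected skeleton branches longer than
    ``min_length_nm``.  Intended as a convenience; curated centerline TSVs
    take precedence in quantitative work."""
    from skimage.filters import sato, threshold_otsu
    from skimage.morphology import skeletonize

    px = image.pixel_size
    ridge = sato(image.data.astype(float),
                 sigmas=[max(1.0, ridge_sigma_nm / px)], black_ridges=False)
    mask = ridge > threshold_otsu(ridge[ridge > 0]) if (ridge > 0).any() \
        else ridge > 0
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if xs.size == 0:
        return []
    # Greedy path extraction over skeleton pixels.
    remaining = set(zip(ys.tolist(), xs.tolist()))
    paths = []
    while remaining:
        seed = next(iter(remaining))
        chain = [seed]
        remaining.discard(seed)
        grew = True
        while grew:
            grew = False
            y, x = chain[-1]
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    nb = (y + dy, x + dx)
                    if nb in remaining:
                        chain.append(nb)
                        remaining.discard(nb)
                        grew = True
                        break
                if grew:
                    break
        if len(chain) * px >= min_length_nm:
            pts = np.array([[ (x + 0.5) * px, (y + 0.5) * px]
                            for (y, x) in chain])
            paths.append(pts)
    return paths
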