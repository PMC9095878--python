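"""Particle morphometry on leveled topographs.

Measures what is read off AFM topographs of membrane-inserted oligomers:
maximum protrusion height above the membrane baseline, the diameter of
maximum height (the crest circle), how deep the lumen penetrates the
membrane and the resulting pre-pore/pore call (pore iff penetration
>= 2 nm, threshold inclusive), Gaussian fits of measured distributions,
per-subunit crest spacing, time-lapse track linking with a mobile/immobile
call, and categorical outcome tallies.

The maximum height is not the raw pixel maximum: the maximum of a noisy
field carries a positive extreme-value bias of order twice the noise SD, so
the apex is located on a lightly smoothed copy and refined by a local
log-quadratic fit to the raw heights, which is exact for Gaussian-shaped
crests and unbiased under pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .topograph import Topograph

__all__ = [
    "PORE_THRESHOLD_NM", "ParticleRecord", "GaussianFit", "Track",
    "classify_pore_state", "extract_height_profile", "measure_particle",
    "fit_gaussian", "subunit_spacing", "track_particles", "tally_outcomes",
    "particle_table", "write_profile",
]

#: Lumen penetration (nm, inclusive) at which an oligomer is called a pore.
PORE_THRESHOLD_NM = 2.0

#: Fraction of the apex height defining crest pixels.
CREST_FRACTION = 0.4

#: Minimum apex height (nm) for a ROI to count as containing a particle.
MIN_PARTICLE_HEIGHT_NM = 1.0


def classify_pore_state(lumen_min: float,
                        threshold: float = PORE_THRESHOLD_NM) -> str:
    """Pre-pore/pore call from the deepest lumen height (nm, <=0 inside).

    ``pore`` iff the lumen penetrates the membrane by at least ``threshold``
    (i.e. ``lumen_min <= -threshold``; the boundary itself is a pore).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "pore" if lumen_min <= -threshold else "pre_pore"


@dataclass
class ParticleRecord:
    """Morphometry of one oligomer."""

    particle_id: int
    roi: tuple[int, int, int, int]         # (row0, row1, col0, col1), px
    center: tuple[float, float]            # (x, y) nm, full-image frame
    shape_class: str                       # arc | slit | ring
    max_height: float                      # nm above membrane
    crest_diameter: float                  # nm
    lumen_min: float                       # nm, most negative interior height
    pore_state: str
    stoichiometry: int | None = None
    accepted: bool = True


@dataclass
class GaussianFit:
    mean: float
    sd: float
    n: int
    fit_rmse: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 3:
            raise ValueError("need n >= 3")


def extract_height_profile(t: Topograph, start_nm: tuple[float, float],
                           end_nm: tuple[float, float]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear height profile along a line between two (x, y) nm points.

    Returns ``(distance_nm, height_nm)`` sampled at half-pixel spacing.
    """
    (x0, y0), (x1, y1) = start_nm, end_nm
    ext_y, ext_x = t.extent_nm
    for x, y in (start_nm, end_nm):
        if not (0 <= x <= ext_x - t.pixel_size[1]
                and 0 <= y <= ext_y - t.pixel_size[0]):
            raise ValueError("profile endpoint outside the image")
    length = math.hypot(x1 - x0, y1 - y0)
    step = min(t.pixel_size) / 2
    n = max(2, int(np.ceil(length / step)) + 1)
    dist = np.linspace(0.0, length, n)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    rows = ys / t.pixel_size[0]
    cols = xs / t.pixel_size[1]
    vals = ndi.map_coordinates(t.heights, [rows, cols], order=1)
    return dist, vals


# ---------------------------------------------------------------------------
# Single-particle measurement
# ---------------------------------------------------------------------------

def _apex_fit(patch: np.ndarray) -> float:
    """Apex height from a log-quadratic fit to a (2k+1)^2 patch.

    Exact for a Gaussian crest; falls back to the patch centre value when
    the fit is not concave or the stationary point leaves the patch.
    """
    k = patch.shape[0] // 2
    centre = patch[k, k]
    if np.any(patch <= 0.1 * centre) or centre <= 0:
        return float(patch.max())
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    a = np.column_stack([np.ones(patch.size), yy.ravel(), xx.ravel(),
                         yy.ravel() ** 2, xx.ravel() ** 2,
                         (yy * xx).ravel()])
    coef, *_ = np.linalg.lstsq(a, np.log(patch).ravel(), rcond=None)
    c0, cy, cx, cyy, cxx, cxy = coef
    hess = np.array([[2 * cyy, cxy], [cxy, 2 * cxx]])
    if np.any(np.linalg.eigvalsh(hess) >= 0):     # not a concave apex
        return float(centre)
    sy, sx = np.linalg.solve(hess, [-cy, -cx])
    if max(abs(sy), abs(sx)) > k:
        return float(centre)
    val = (c0 + cy * sy + cx * sx + cyy * sy ** 2 + cxx * sx ** 2
           + cxy * sy * sx)
    return float(np.exp(val))


def _radial_profile(heights: np.ndarray, center_px: tuple[float, float],
                    pixel_size: tuple[float, float], r_max: float,
                    bin_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged height vs radius about a (row, col) centre."""
    rows, cols = heights.shape
    yy = (np.arange(rows)[:, None] - center_px[0]) * pixel_size[0]
    xx = (np.arange(cols)[None, :] - center_px[1]) * pixel_size[1]
    rr = np.hypot(yy, xx)
    nbins = int(np.ceil(r_max / bin_nm))
    idx = np.minimum((rr / bin_nm).astype(int), nbins)
    sums = np.bincount(idx.ravel(), heights.ravel(), minlength=nbins + 1)
    counts = np.bincount(idx.ravel(), minlength=nbins + 1)
    valid = counts[:nbins] > 0
    radii = (np.arange(nbins) + 0.5) * bin_nm
    prof = np.full(nbins, np.nan)
    prof[valid] = sums[:nbins][valid] / counts[:nbins][valid]
    return radii[valid], prof[valid]


def _peak_parabolic(x: np.ndarray, y: np.ndarray) -> float:
    """Sub-bin peak location by parabolic interpolation around the argmax."""
    i = int(np.nanargmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + shift * (x[i + 1] - x[i]))


def _angular_coverage(angles: np.ndarray, bin_deg: float = 5.0) -> float:
    """Total angular coverage (degrees) of a point set about its centroid."""
    bins = np.zeros(int(360 / bin_deg), dtype=bool)
    bins[(np.degrees(angles) % 360 / bin_deg).astype(int)] = True
    return float(bins.sum() * bin_deg)


def _classify_shape(crest_rows: np.ndarray, crest_cols: np.ndarray,
                    pixel_size: tuple[float, float]) -> str:
    """Ring / slit / arc from angular coverage and elongation of the crest.

    Rings close the full circle and are round; slits are closed (or nearly
    closed, two arcs touching end to end) but elongated; anything with a
    large angular gap is an arc.
    """
    y = crest_rows * pixel_size[0]
    x = crest_cols * pixel_size[1]
    y = y - y.mean()
    x = x - x.mean()
    coverage = _angular_coverage(np.arctan2(y, x))
    cov_mat = np.cov(np.vstack([x, y]))
    evals = np.sort(np.linalg.eigvalsh(cov_mat))
    aspect = math.sqrt(evals[1] / max(evals[0], 1e-12))
    if coverage >= 330 and aspect < 1.25:
        return "ring"
    if coverage >= 300:
        return "slit"
    return "arc"


def measure_particle(t: Topograph, roi: tuple[int, int, int, int] | None,
                     particle_id: int = 0,
                     pore_threshold: float = PORE_THRESHOLD_NM,
                     smooth_px: float = 1.0) -> ParticleRecord:
    """Measure one oligomer inside a pixel ROI of a leveled topograph.

    ``roi`` is ``(row0, row1, col0, col1)`` (half-open, as in slicing);
    ``None`` measures the whole image.  A ROI whose apex stays below 1 nm is
    returned with ``accepted=False``.
    """
    if roi is None:
        roi = (0, t.shape[0], 0, t.shape[1])
    r0, r1, c0, c1 = roi
    sub = t.heights[r0:r1, c0:c1]
    smoothed = ndi.gaussian_filter(sub, smooth_px)
    # Apex selection uses a stronger smoothing than the crest mask so the
    # chosen bump is nearly independent of the local noise the fit sees
    # (selection by the noisy field itself would bias the maximum upward).
    peak = np.unravel_index(np.argmax(ndi.gaussian_filter(sub, 2 * smooth_px)),
                            sub.shape)

    if sub.max() < MIN_PARTICLE_HEIGHT_NM:
        return ParticleRecord(particle_id, roi, (np.nan, np.nan), "arc",
                              float(sub.max()), np.nan, float(sub.min()),
                              "pre_pore", accepted=False)

    # Apex height: log-quadratic refinement around the smoothed argmax.
    k = 2
    if (k <= peak[0] < sub.shape[0] - k) and (k <= peak[1] < sub.shape[1] - k):
        patch = sub[peak[0] - k:peak[0] + k + 1, peak[1] - k:peak[1] + k + 1]
        max_height = _apex_fit(patch)
    else:
        max_height = float(sub.max())

    # Crest pixels and shape class.
    crest = smoothed >= CREST_FRACTION * smoothed.max()
    rows_c, cols_c = np.nonzero(crest)
    shape_class = _classify_shape(rows_c, cols_c, t.pixel_size)

    # Centre = crest centroid (px within the ROI).
    cy_px = rows_c.mean()
    cx_px = cols_c.mean()

    if shape_class == "ring":
        r_max = max(sub.shape[0] * t.pixel_size[0],
                    sub.shape[1] * t.pixel_size[1]) / 2
        radii, prof = _radial_profile(smoothed, (cy_px, cx_px), t.pixel_size,
                                      r_max, bin_nm=min(t.pixel_size) / 2)
        crest_radius = _peak_parabolic(radii, prof)
        crest_diameter = 2 * crest_radius
    else:
        # Maximal separation of crest points (hull is enough for the max).
        pts = np.column_stack([cols_c * t.pixel_size[1],
                               rows_c * t.pixel_size[0]])
        if len(pts) > 3:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts).vertices]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        crest_diameter = float(np.sqrt(d2.max()))
        crest_radius = crest_diameter / 2

    # Lumen: deepest smoothed height inside the crest circle.
    yy = (np.arange(sub.shape[0])[:, None] - cy_px) * t.pixel_size[0]
    xx = (np.arange(sub.shape[1])[None, :] - cx_px) * t.pixel_size[1]
    interior = np.hypot(yy, xx) <= max(crest_radius - min(t.pixel_size),
                                       min(t.pixel_size))
    lumen_min = float(smoothed[interior].min()) if interior.any() \
        else float(smoothed.min())

    center_nm = ((c0 + cx_px) * t.pixel_size[1],
                 (r0 + cy_px) * t.pixel_size[0])
    return ParticleRecord(
        particle_id=particle_id, roi=roi, center=center_nm,
        shape_class=shape_class, max_height=max_height,
        crest_diameter=crest_diameter, lumen_min=lumen_min,
        pore_state=classify_pore_state(lumen_min, pore_threshold))


# ---------------------------------------------------------------------------
# Distribution fits and derived quantities
# ---------------------------------------------------------------------------

def fit_gaussian(values, method: str = "ml", bins: int | str = "auto"
                 ) -> GaussianFit:
    """Fit a normal distribution to measured values.

    ``method='ml'`` (default) uses the sample mean and SD (the maximum-
    likelihood fit up to the ddof convention); ``method='histogram'``
    least-squares fits a Gaussian curve to the histogram, mirroring how
    distribution figures are usually annotated.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("constant input: sd = 0, no Gaussian fit")
    if method == "ml":
        mean, sd = float(v.mean()), float(v.std(ddof=1))
    elif method == "histogram":
        from scipy.optimize import curve_fit
        counts, edges = np.histogram(v, bins=bins, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])

        def gauss(x, a, mu, sigma):
            return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        p0 = (counts.max(), v.mean(), v.std(ddof=1))
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        mean, sd = float(popt[1]), float(abs(popt[2]))
    else:
        raise ValueError("method must be 'ml' or 'histogram'")
    counts, edges = np.histogram(v, bins=bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    pdf = np.exp(-0.5 * ((centers - mean) / sd) ** 2) / (sd * math.sqrt(2
                                                                        * math.pi))
    rmse = float(np.sqrt(np.mean((counts - pdf) ** 2)))
    return GaussianFit(mean=mean, sd=sd, n=int(v.size), fit_rmse=rmse)


def subunit_spacing(crest_diameter: float, n_subunits: int,
                    convention: str = "circumferential") -> float:
    """Per-subunit spacing of a ring of N subunits on a crest of diameter D.

    ``circumferential`` (default) is the arc length pi*D/N between adjacent
    subunit centres; ``chord`` the straight-line distance D*sin(pi/N);
    ``literal`` the plain ratio D/N (the figure-caption wording, kept for
    comparability even though it is not a geometric spacing).
    """
    if n_subunits < 3:
        raise ValueError("n_subunits must be >= 3")
    if crest_diameter <= 0:
        raise ValueError("crest_diameter must be positive")
    if convention == "circumferential":
        return math.pi * crest_diameter / n_subunits
    if convention == "literal":
        return crest_diameter / n_subunits
    if convention == "chord":
        return crest_diameter * math.sin(math.pi / n_subunits)
    raise ValueError("convention must be circumferential, literal or chord")


# ---------------------------------------------------------------------------
# Time-lapse tracking
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One particle followed through a time-lapse series."""

    particle_id: int
    frames: list[int] = field(default_factory=list)
    centers: list[tuple[float, float]] = field(default_factory=list)
    mobility_class: str = "immobile"

    @property
    def appearance(self) -> int:
        return self.frames[0]

    @property
    def disappearance(self) -> int:
        return self.frames[-1]

    @property
    def max_displacement(self) -> float:
        x0, y0 = self.centers[0]
        return max(math.hypot(x - x0, y - y0) for x, y in self.centers)


def track_particles(frames, link_radius: float,
                    mobility_threshold: float | None = None) -> list[Track]:
    """Link per-frame particle records into tracks (greedy nearest neighbour).

    ``frames`` is a time-ordered list of ``(time_index, [ParticleRecord])``.
    Within each frame, candidate links inside ``link_radius`` are accepted
    in order of increasing distance.  A track is ``mobile`` if it moves more
    than ``mobility_threshold`` (default: its mean crest diameter) or if it
    appears after the first frame / disappears before the last.
    """
    tracks: list[Track] = []
    diam: dict[int, list[float]] = {}
    active: dict[int, tuple[float, float]] = {}
    frame_ids = [f for f, _ in frames]
    next_id = 0
    for f, records in frames:
        candidates = []
        for tid, (px, py) in active.items():
            for j, rec in enumerate(records):
                d = math.hypot(rec.center[0] - px, rec.center[1] - py)
                if d <= link_radius:
                    candidates.append((d, tid, j))
        used_t, used_j, links = set(), set(), {}
        for d, tid, j in sorted(candidates):
            if tid not in used_t and j not in used_j:
                links[j] = tid
                used_t.add(tid)
                used_j.add(j)
        new_active = {}
        for j, rec in enumerate(records):
            tid = links.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
                tracks.append(Track(particle_id=tid))
                diam[tid] = []
            tracks[tid].frames.append(f)
            tracks[tid].centers.append(rec.center)
            if np.isfinite(rec.crest_diameter):
                diam[tid].append(rec.crest_diameter)
            new_active[tid] = rec.center
        active = new_active
    for tr in tracks:
        thr = mobility_threshold
        if thr is None:
            thr = float(np.mean(diam[tr.particle_id])) \
                if diam[tr.particle_id] else link_radius
        transient = (tr.appearance != frame_ids[0]
                     or tr.disappearance != frame_ids[-1])
        tr.mobility_class = "mobile" if (tr.max_displacement > thr
                                         or transient) else "immobile"
    return tracks


def tally_outcomes(labels) -> pd.DataFrame:
    """Tally categorical simulation outcomes into counts and percentages.

    Returns a DataFrame with columns ``category``, ``count``, ``percent``
    (percent to one decimal; the percentages sum to 100 up to rounding).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no outcome labels given")
    cats = sorted(set(labels))
    counts = [labels.count(c) for c in cats]
    total = len(labels)
    return pd.DataFrame({
        "category": cats,
        "count": counts,
        "percent": [round(100.0 * c / total, 1) for c in counts],
    })


def particle_table(records) -> pd.DataFrame:
    """Particle records as a DataFrame (the CSV export schema)."""
    return pd.DataFrame([{
        "particle_id": r.particle_id,
        "shape": r.shape_class,
        "max_height_nm": r.max_height,
        "crest_diameter_nm": r.crest_diameter,
        "lumen_min_nm": r.lumen_min,
        "pore_state": r.pore_state,
        "stoichiometry": r.stoichiometry,
        "center_x_nm": r.center[0],
        "center_y_nm": r.center[1],
        "accepted": r.accepted,
    } for r in records])


def write_profile(distance_nm, height_nm, path) -> None:
    """Write a height profile as two-column CSV (distance_nm, height_nm)."""
    pd.DataFrame({"distance_nm": distance_nm,
                  "height_nm": height_nm}).to_csv(path, index=False)
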