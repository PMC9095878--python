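"""Topograph preprocessing: channel averaging, leveling, drift unwarping
and pixel-size calibration.

Raw scan-probe height maps carry an arbitrary tilt and offset, trace and
retrace channels with independent noise, and a slow-scan-axis drift that
stretches features along y.  The pipeline here reduces a raw pair of
channels to a leveled topograph with the membrane at 0 nm and an isotropic
pixel size: pixel-wise trace/retrace averaging, plane removal with the
membrane histogram mode pinned to zero, cubic-spline y resampling (with the
stretch either known or estimated from particle circularity), and a final
linear rescaling of measured diameters against an atomic model of a ring
oligomer of known stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline

from .topograph import Topograph

__all__ = [
    "CalibrationResult", "average_trace_retrace", "level_and_zero",
    "unwarp_y", "estimate_y_scale", "calibrate_pixel_size",
]

#: Histogram bin width used to locate the membrane mode, nm.
MEMBRANE_MODE_BIN_NM = 0.05
#: Residual band around the mode treated as membrane when re-fitting, nm.
MEMBRANE_BAND_NM = 0.5
#: Valid range of the estimated y stretch; outside it the pure-stretch
#: drift model is considered violated.
Y_SCALE_RANGE = (0.5, 2.0)


def average_trace_retrace(trace: Topograph, retrace: Topograph) -> Topograph:
    """Pixel-wise mean of the two scan directions."""
    if trace.shape != retrace.shape:
        raise ValueError("trace and retrace shapes differ")
    if not np.allclose(trace.pixel_size, retrace.pixel_size):
        raise ValueError("trace and retrace pixel sizes differ")
    mean = 0.5 * (trace.heights + retrace.heights)
    return trace.with_heights(mean, "average_trace_retrace",
                              channel="averaged")


def _plane_fit(heights: np.ndarray, mask: np.ndarray | None = None
               ) -> np.ndarray:
    rows, cols = heights.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    if mask is None:
        mask = np.ones_like(heights, dtype=bool)
    a = np.column_stack([yy[mask], xx[mask], np.ones(mask.sum())])
    coef, *_ = np.linalg.lstsq(a, heights[mask], rcond=None)
    return coef[0] * yy + coef[1] * xx + coef[2]


def _membrane_mode(residual: np.ndarray) -> float:
    """Mode of the height histogram, refined to the mean of the mode bin.

    With two exactly equally occupied modes the lower one is chosen and a
    warning issued (ambiguous baseline).
    """
    flat = residual.ravel()
    lo, hi = flat.min(), flat.max()
    nbins = max(1, int(np.ceil((hi - lo) / MEMBRANE_MODE_BIN_NM)))
    counts, edges = np.histogram(flat, bins=nbins)
    top = np.flatnonzero(counts == counts.max())
    if len(top) > 1 and top[-1] - top[0] > 1:
        warnings.warn("ambiguous membrane baseline (two equal height modes); "
                      "choosing the lower one", stacklevel=3)
    i = top[0]
    in_bin = flat[(flat >= edges[i]) & (flat <= edges[i + 1])]
    return float(in_bin.mean()) if in_bin.size else 0.5 * (edges[i]
                                                           + edges[i + 1])


def level_and_zero(t: Topograph, n_iter: int = 2) -> Topograph:
    """Remove the best-fit plane and pin the membrane mode to 0 nm.

    The membrane is assumed to occupy the plurality of pixels; after an
    initial whole-image plane fit, the plane is re-fit on pixels within
    +/-0.5 nm of the histogram mode so particles do not bias the baseline.
    Idempotent, and invariant to any added plane.
    """
    residual = t.heights - _plane_fit(t.heights)
    residual -= _membrane_mode(residual)
    for _ in range(n_iter):
        mask = np.abs(residual) < MEMBRANE_BAND_NM
        if mask.sum() < 16:
            break
        residual = t.heights - _plane_fit(t.heights, mask)
        residual -= _membrane_mode(residual)
    return t.with_heights(residual, "level_and_zero")


def estimate_y_scale(t: Topograph, height_threshold: float = 1.0,
                     min_area_px: int = 30) -> float:
    """Estimate the y-unwarp factor from particle circularity.

    For drift that is a pure y stretch, circular particles become ellipses
    whose x/y second-moment ratio equals the stretch factor's inverse; the
    estimate is the median over detected particles of
    ``sqrt(var_x / var_y)`` in physical units.  Requires a leveled
    topograph with particles protruding above ``height_threshold``.
    """
    labels, n = ndi.label(t.heights > height_threshold)
    if n == 0:
        raise ValueError("no particles found to estimate the y scale from")
    ratios = []
    for idx in ndi.find_objects(labels):
        blob = labels[idx] > 0
        if blob.sum() < min_area_px:
            continue
        yy, xx = np.nonzero(blob)
        y_nm = yy * t.pixel_size[0]
        x_nm = xx * t.pixel_size[1]
        vy, vx = np.var(y_nm), np.var(x_nm)
        if vy > 0 and vx > 0:
            ratios.append(np.sqrt(vx / vy))
    if not ratios:
        raise ValueError("no particle large enough to estimate the y scale")
    scale = float(np.median(ratios))
    if not Y_SCALE_RANGE[0] <= scale <= Y_SCALE_RANGE[1]:
        raise ValueError(
            f"estimated y scale {scale:.3f} outside {Y_SCALE_RANGE}; "
            "the pure y-stretch drift model does not hold")
    return scale


def unwarp_y(t: Topograph, scale: float | str = "auto") -> Topograph:
    """Resample the slow (y) axis so circular objects become circular.

    ``scale`` is the stretch applied during unwarping: output row ``j``
    samples input row ``j / scale``, so a scene whose features were
    stretched by drift factor ``s`` is corrected with ``scale = 1/s``.
    ``scale='auto'`` estimates it with :func:`estimate_y_scale`.  The number
    of rows changes accordingly; the pixel size is unchanged.
    """
    if isinstance(scale, str):
        if scale != "auto":
            raise ValueError("scale must be a float or 'auto'")
        scale = estimate_y_scale(t)
    if not Y_SCALE_RANGE[0] <= scale <= Y_SCALE_RANGE[1]:
        raise ValueError(f"y scale {scale} outside {Y_SCALE_RANGE}")
    rows = t.shape[0]
    if scale == 1.0:
        return t.with_heights(t.heights.copy(), "unwarp_y scale=1")
    n_out = int(np.floor((rows - 1) * scale)) + 1
    src = np.arange(n_out) / scale
    spline = CubicSpline(np.arange(rows), t.heights, axis=0)
    return t.with_heights(spline(src), f"unwarp_y scale={scale:.5f}")


@dataclass
class CalibrationResult:
    """Outcome of pixel-size calibration against an atomic model."""

    scale_factor: float          # multiply measured lengths by this
    model_diameter: float        # nm, reference ring diameter
    matched_stoichiometry: int
    residual: float              # nm, SD of the calibrated reference class

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def calibrate_pixel_size(diameters_by_n, model: tuple[int, float]
                         ) -> CalibrationResult:
    """Calibrate measured diameters against a model ring of known size.

    ``diameters_by_n`` is an iterable of ``(stoichiometry, measured
    diameter)`` pairs (or a DataFrame with columns ``N`` and
    ``diameter_nm``); the diameter distribution of ring oligomers shows
    discrete stoichiometry classes, so the mean measured diameter of the
    class matching the atomic model fixes the true pixel size.
    """
    n0, model_diameter = int(model[0]), float(model[1])
    if hasattr(diameters_by_n, "columns"):
        pairs = list(zip(diameters_by_n["N"], diameters_by_n["diameter_nm"]))
    else:
        pairs = [(int(n), float(d)) for n, d in diameters_by_n]
    ref = np.array([d for n, d in pairs if n == n0], dtype=float)
    if ref.size == 0:
        raise ValueError(f"no measured ring with stoichiometry {n0}")
    scale = model_diameter / ref.mean()
    residual = float(np.std(ref * scale, ddof=1)) if ref.size > 1 else 0.0
    return CalibrationResult(scale_factor=float(scale),
                             model_diameter=model_diameter,
                             matched_stoichiometry=n0, residual=residual)
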