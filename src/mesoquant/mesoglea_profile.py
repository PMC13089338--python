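"""Polyline straightening and FWHM-based mesoglea thickness.

The mesoglea is traced with a polyline ROI along the body column; the
image is resampled on the polyline's arc-length/normal frame so the curved
band becomes a horizontal map over (axial position ``s`` in [0, 1], signed
transverse offset ``d`` in micrometres).  ``d = 0`` is the polyline, the
positive side is the endoderm and the negative side the ectoderm — the
caller orients the polyline so that the endoderm lies left of the travel
direction.  The local band thickness is the full width at half maximum of
the transverse intensity peak, and the signal within that window is the
local Col IV amount; column summaries are means and standard deviations
over the axial extent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import CalibratedImage, PolylineROI

__all__ = [
    "StraightenedMap",
    "FWHMResult",
    "ThicknessProfile",
    "straighten",
    "transverse_profile",
    "fwhm",
    "thickness_along_column",
    "ec_ic_ratio",
    "axial_intensity_profile",
]


@dataclass(frozen=True)
class StraightenedMap:
    """Image resampled into (axial s, transverse d) band coordinates.

    ``grid[i, j]`` is the intensity at ``(d[i], s[j])``; samples falling
    outside the source image are NaN (excluded, never zero-filled — zeros
    would bias FWHM baselines).
    """

    grid: np.ndarray  # (n_d, n_s), NaN = missing
    s: np.ndarray  # normalized axial positions, strictly increasing in [0, 1]
    d: np.ndarray  # signed transverse offsets, um, symmetric about 0
    half_width: float
    axial_step: float
    transverse_step: float

    @property
    def axial_samples(self) -> int:
        return self.grid.shape[1]

    @property
    def transverse_samples(self) -> int:
        return self.grid.shape[0]


@dataclass(frozen=True)
class FWHMResult:
    width: float  # um
    center: float  # um, midpoint of the half-maximum crossings
    half_level: float  # absolute intensity at the crossings
    baseline: float
    peak: float  # baseline-subtracted peak height


@dataclass
class ThicknessProfile:
    """Per-axial-bin thickness/amount records with column summaries.

    ``amount_sum`` integrates the baseline-subtracted signal over the FWHM
    window (intensity x um); ``amount_mean`` is its per-sample mean —
    both are reported since either reading of "signal within" is defensible.
    Bins where no peak is measurable are excluded from the summaries and
    counted in ``n_undefined``.
    """

    s: np.ndarray
    thickness: np.ndarray
    amount_sum: np.ndarray
    amount_mean: np.ndarray
    center_offset: np.ndarray
    mean_thickness: float
    sd_thickness: float
    mean_amount: float
    sd_amount: float
    n_defined: int
    n_undefined: int


# ---------------------------------------------------------------------------


def _resample_polyline(roi: PolylineROI, step: float):
    """Arc-length resampling with unit tangents and left-of-travel normals."""
    pts = roi.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(round(total / step)), 1)
    s_arc = np.linspace(0.0, total, n + 1)
    x = np.interp(s_arc, cum, pts[:, 0])
    y = np.interp(s_arc, cum, pts[:, 1])
    tx = np.gradient(x, s_arc)
    ty = np.gradient(y, s_arc)
    norm = np.hypot(tx, ty)
    tx, ty = tx / norm, ty / norm
    # left of travel: rotate tangent by +90 deg in the (x, y) basis
    nx, ny = -ty, tx
    return s_arc, x, y, nx, ny


def straighten(
    image: CalibratedImage,
    roi: PolylineROI,
    half_width: float,
    axial_step: float | None = None,
    transverse_step: float | None = None,
) -> StraightenedMap:
    """Resample the image along the polyline and its normals.

    Sampling points are ``p(s) + d * n(s)`` with ``p`` the arc-length
    parameterized polyline and ``n`` its left-of-travel unit normal;
    bilinear interpolation, out-of-image samples NaN.  Both steps default
    to the pixel size.  ``s`` is rescaled to [0, 1].
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    ps = image.pixel_size
    axial_step = ps if axial_step is None else axial_step
    transverse_step = ps if transverse_step is None else transverse_step
    s_arc, x, y, nx, ny = _resample_polyline(roi, axial_step)
    n_d = int(round(half_width / transverse_step))
    d = np.arange(-n_d, n_d + 1) * transverse_step

    sample_x = x[None, :] + d[:, None] * nx[None, :]
    sample_y = y[None, :] + d[:, None] * ny[None, :]
    rows = sample_y / ps
    cols = sample_x / ps
    if np.all(
        (rows < -0.5)
        | (rows > image.shape[0] - 0.5)
        | (cols < -0.5)
        | (cols > image.shape[1] - 0.5)
    ):
        raise ValueError("polyline (with half_width margin) lies outside the image")
    grid = ndimage.map_coordinates(
        image.pixels,
        np.stack([rows.ravel(), cols.ravel()]),
        order=1,
        mode="constant",
        cval=np.nan,
    ).reshape(sample_x.shape)
    s_norm = s_arc / s_arc[-1] if s_arc[-1] > 0 else s_arc
    return StraightenedMap(
        grid=grid,
        s=s_norm,
        d=d,
        half_width=half_width,
        axial_step=axial_step,
        transverse_step=transverse_step,
    )


def transverse_profile(
    smap: StraightenedMap, s_range: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity versus transverse offset d, averaged over s.

    Missing (NaN) samples are ignored; ``s_range`` restricts the average to
    a normalized axial interval.
    """
    if s_range is None:
        sel = np.ones_like(smap.s, dtype=bool)
    else:
        lo, hi = s_range
        sel = (smap.s >= lo) & (smap.s <= hi)
    if not sel.any():
        raise ValueError("empty s_range")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        prof = np.nanmean(smap.grid[:, sel], axis=1)
    return smap.d.copy(), prof


def fwhm(
    d: np.ndarray, intensity: np.ndarray, baseline_fraction: float = 0.10
) -> FWHMResult:
    """Full width at half maximum of an interior intensity peak.

    The baseline is the mean of the outer ``baseline_fraction`` of samples
    on each side (robust to tissue shoulders); the peak is the maximum
    after baseline subtraction; the half-maximum crossings nearest the peak
    are located by linear interpolation on each flank.  The construction is
    exactly invariant to affine intensity transforms.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(intensity, dtype=float)
    keep = np.isfinite(y)
    d, y = d[keep], y[keep]
    n = len(y)
    if n < 5:
        raise ValueError("profile too short for FWHM estimation")
    k = max(1, int(round(baseline_fraction * n)))
    baseline = float(np.concatenate([y[:k], y[-k:]]).mean())
    ysub = y - baseline
    ipk = int(np.argmax(ysub))
    peak = float(ysub[ipk])
    if peak <= 0:
        raise ValueError("no peak above the edge baseline")
    if ipk == 0 or ipk == n - 1:
        raise ValueError("peak at the profile boundary; flank not bracketed")
    half = peak / 2.0

    def cross(idx_range) -> float:
        for i in idx_range:
            step = 1 if i < ipk else -1  # direction back toward the peak
            if ysub[i] < half <= ysub[i + step]:
                f = (half - ysub[i]) / (ysub[i + step] - ysub[i])
                return float(d[i] + f * (d[i + step] - d[i]))
        raise ValueError("half-maximum flank not bracketed within the profile")

    left = cross(range(ipk - 1, -1, -1))
    right = cross(range(ipk + 1, n))
    return FWHMResult(
        width=right - left,
        center=(left + right) / 2.0,
        half_level=baseline + half,
        baseline=baseline,
        peak=peak,
    )


def thickness_along_column(
    smap: StraightenedMap, axial_bin: int = 5, baseline_fraction: float = 0.10
) -> ThicknessProfile:
    """Apply the FWHM thickness estimator along the straightened column.

    Axial samples are grouped in bins of ``axial_bin`` (default 5, which
    stabilizes noisy flank crossings); each bin's transverse profile gives
    one (thickness, amount, center offset) record.  Bins without a
    measurable peak are excluded and counted.
    """
    if axial_bin < 1:
        raise ValueError("axial_bin must be >= 1")
    n_s = smap.axial_samples
    s_mid, th, amt_s, amt_m, cen = [], [], [], [], []
    n_undef = 0
    for start in range(0, n_s, axial_bin):
        stop = min(start + axial_bin, n_s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof = np.nanmean(smap.grid[:, start:stop], axis=1)
        try:
            res = fwhm(smap.d, prof, baseline_fraction)
        except ValueError:
            n_undef += 1
            continue
        window = np.abs(smap.d - res.center) <= res.width / 2.0
        vals = prof[window] - res.baseline
        vals = vals[np.isfinite(vals)]
        s_mid.append(float(smap.s[start : stop].mean()))
        th.append(res.width)
        amt_s.append(float(vals.sum()) * smap.transverse_step)
        amt_m.append(float(vals.mean()) if len(vals) else math.nan)
        cen.append(res.center)
    if not th:
        raise ValueError("no axial position yielded a measurable band")
    th_a = np.asarray(th)
    amt_a = np.asarray(amt_s)
    ddof = 1 if len(th) > 1 else 0
    return ThicknessProfile(
        s=np.asarray(s_mid),
        thickness=th_a,
        amount_sum=amt_a,
        amount_mean=np.asarray(amt_m),
        center_offset=np.asarray(cen),
        mean_thickness=float(th_a.mean()),
        sd_thickness=float(th_a.std(ddof=ddof)),
        mean_amount=float(amt_a.mean()),
        sd_amount=float(amt_a.std(ddof=ddof)),
        n_defined=len(th),
        n_undefined=n_undef,
    )


def ec_ic_ratio(
    smap: StraightenedMap,
    endoderm_band: tuple[float, float],
    mesoglea_window: FWHMResult | None = None,
) -> float:
    """Extracellular (mesoglea) to intracellular (endoderm) intensity ratio.

    Numerator: mean baseline-subtracted intensity within the FWHM window of
    the column-average transverse profile (``mesoglea_window`` overrides
    the internally fitted one).  Denominator: mean baseline-subtracted
    intensity within ``endoderm_band = (d_lo, d_hi)`` on the positive-d
    (endoderm) side, disjoint from the window.  Scale-invariant by
    construction.
    """
    d, prof = transverse_profile(smap)
    res = mesoglea_window if mesoglea_window is not None else fwhm(d, prof)
    lo, hi = endoderm_band
    if lo >= hi or lo <= 0:
        raise ValueError("endoderm_band must be (d_lo, d_hi) with 0 < d_lo < d_hi")
    if lo < res.center + res.width / 2.0:
        raise ValueError("endoderm_band overlaps the mesoglea FWHM window")
    win = np.abs(d - res.center) <= res.width / 2.0
    band = (d >= lo) & (d <= hi)
    if not band.any():
        raise ValueError("endoderm_band contains no samples")
    num = float(np.nanmean(prof[win])) - res.baseline
    den = float(np.nanmean(prof[band])) - res.baseline
    if den <= 0:
        raise ValueError("non-positive endoderm signal after baseline subtraction")
    return num / den


def axial_intensity_profile(
    image: CalibratedImage,
    axis_roi: PolylineROI,
    averaging_width: float = 0.0,
    origin: str = "aboral",
    step: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity along the oral-aboral axis, position normalized to [0, 1].

    The polyline is assumed drawn starting at the oral pole.  With
    ``origin="aboral"`` (the default convention here) position 0 denotes
    the aboral pole, so positions run against the polyline direction; with
    ``origin="oral"`` position 0 is the polyline start.  ``averaging_width``
    averages perpendicular to the line (0 = single-line sample).
    """
    if origin not in ("oral", "aboral"):
        raise ValueError("origin must be 'oral' or 'aboral'")
    half = max(averaging_width / 2.0, image.pixel_size / 4.0)
    smap = straighten(image, axis_roi, half_width=half, transverse_step=half)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if averaging_width > 0:
            prof = np.nanmean(smap.grid, axis=0)
        else:
            prof = smap.grid[smap.grid.shape[0] // 2]
    if np.all(np.isnan(prof)):
        raise ValueError("polyline lies outside the image")
    pos = smap.s.copy()
    if origin == "aboral":
        pos = (1.0 - pos)[::-1]
        prof = prof[::-1]
    return pos, prof
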