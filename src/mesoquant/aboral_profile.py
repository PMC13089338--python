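"""Intensity profiling at the aboral pole.

The aboral valve is marked by a localized Col IV depletion zone in the
mesoglea.  Profiles are measured along a line ROI laid along the aboral
mesoglea, intensity averaged across a configurable line width, and the
position axis translated so 0 denotes the pore.  The depletion zone is
scored as the full width at half depth of the dip relative to its flanking
plateaus — the mirror image of the FWHM thickness convention, and equally
invariant to intensity gain and offset.  Multi-animal summaries are
per-position mean +/- SD bands after resampling onto a common grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import CalibratedImage, PolylineROI
from .mesoglea_profile import straighten

__all__ = [
    "AboralProfile",
    "ProfileEnsemble",
    "extract_aboral_profile",
    "perk_profile",
    "depletion_zone_width",
    "ensemble_profiles",
    "roi_mean_intensity",
]


@dataclass(frozen=True)
class AboralProfile:
    """A pore-centred line profile: positions in um, 0 at the pore."""

    positions: np.ndarray
    intensity: np.ndarray
    channel: str
    roi_length: float
    line_width: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise ValueError("positions and intensity must be matching 1D arrays")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class ProfileEnsemble:
    """Aligned profiles from n animals with per-position mean and SD."""

    positions: np.ndarray
    members: np.ndarray  # (n, n_positions)
    mean: np.ndarray
    sd: np.ndarray  # ddof = 1; 0 when n = 1
    channel: str

    @property
    def n(self) -> int:
        return self.members.shape[0]


def extract_aboral_profile(
    image: CalibratedImage,
    line: PolylineROI,
    pore_position: float,
    roi_length: float = 100.0,
    line_width: float = 1.0,
    step: float | None = None,
    channel: str | None = None,
) -> AboralProfile:
    """Measure a pore-centred intensity profile along a line ROI.

    ``pore_position`` is the pore's arc position (um) along the line; the
    returned positions are translated so the pore sits at 0 and clipped to
    ``roi_length`` centred on it when the line is longer.  Intensity is
    averaged across ``line_width`` perpendicular to the line.
    """
    total = line.arc_length
    if not (0.0 <= pore_position <= total):
        raise ValueError("pore_position lies outside the line")
    if total < roi_length / 2.0:
        raise ValueError(f"line ({total:.1f} um) shorter than half the ROI length")
    step = image.pixel_size if step is None else step
    half = max(line_width / 2.0, image.pixel_size / 4.0)
    smap = straighten(
        image,
        line,
        half_width=half,
        axial_step=step,
        transverse_step=min(half, image.pixel_size),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof = np.nanmean(smap.grid, axis=0)
    arc = smap.s * total
    pos = arc - pore_position
    keep = np.abs(pos) <= roi_length / 2.0 + 1e-9
    keep &= np.isfinite(prof)
    if keep.sum() < 3:
        raise ValueError("line exits the image around the pore")
    return AboralProfile(
        positions=pos[keep],
        intensity=prof[keep],
        channel=channel or image.channel_name,
        roi_length=roi_length,
        line_width=line_width,
    )


def perk_profile(
    image: CalibratedImage, line: PolylineROI, step: float | None = None
) -> AboralProfile:
    """pErk line profile at the aboral pore: 0 um outside, 50 um into the
    body cavity, averaged across a 5-um-wide line.

    The polyline is drawn from outside the animal inward; positions follow
    its arc length over [0, 50] um.
    """
    if line.arc_length < 50.0:
        raise ValueError("pErk line must be at least 50 um long")
    prof = extract_aboral_profile(
        image, line, pore_position=0.0, roi_length=100.0, line_width=5.0, step=step
    )
    keep = (prof.positions >= -1e-9) & (prof.positions <= 50.0 + 1e-9)
    return AboralProfile(
        positions=prof.positions[keep],
        intensity=prof.intensity[keep],
        channel=prof.channel,
        roi_length=50.0,
        line_width=5.0,
    )


def depletion_zone_width(
    profile: AboralProfile,
    flank_fraction: float = 0.20,
    noise_floor: float = 0.05,
) -> tuple[float, float]:
    """Full width at half depth of the Col IV depletion dip at the pore.

    Flank level = mean of the outer ``flank_fraction`` of samples on each
    side; depth = 1 - min/flank; the width spans the two crossings of
    ``flank * (1 - depth / 2)`` nearest the minimum, linearly interpolated.
    Dips shallower than ``noise_floor`` raise a no-dip error.  Invariant to
    intensity gain, by construction.
    """
    pos, y = profile.positions, profile.intensity
    n = len(y)
    if n < 10:
        raise ValueError("profile too short to score a depletion zone")
    k = max(1, int(round(flank_fraction * n)))
    flank = float(np.concatenate([y[:k], y[-k:]]).mean())
    if flank <= 0:
        raise ValueError("non-positive flank level")
    imin = int(np.argmin(y))
    depth = 1.0 - float(y[imin]) / flank
    if depth <= noise_floor:
        raise ValueError(f"no depletion dip (depth {depth:.3f} <= floor {noise_floor})")
    if imin < k or imin >= n - k:
        raise ValueError("dip minimum inside a flank window; missing flank")
    level = flank * (1.0 - depth / 2.0)

    def cross(idx_range) -> float:
        for i in idx_range:
            inner = i + (1 if i < imin else -1)
            if y[i] > level >= y[inner]:
                f = (y[i] - level) / (y[i] - y[inner])
                return float(pos[i] + f * (pos[inner] - pos[i]))
        raise ValueError("half-depth crossing not bracketed; missing flank")

    left = cross(range(imin - 1, -1, -1))
    right = cross(range(imin + 1, n))
    return right - left, depth


def ensemble_profiles(profiles: list[AboralProfile]) -> ProfileEnsemble:
    """Combine profiles from several animals into a mean +/- SD band.

    Profiles are resampled by linear interpolation onto the finest common
    position grid over the overlap of their ranges; the SD uses ddof = 1
    and is 0 for a single member.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    channels = {p.channel for p in profiles}
    if len(channels) > 1:
        raise ValueError(f"channel mismatch: {sorted(channels)}")
    lo = max(p.positions[0] for p in profiles)
    hi = min(p.positions[-1] for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have no overlapping position range")
    step = min(float(np.min(np.diff(p.positions))) for p in profiles)
    grid = np.arange(lo, hi + step / 2.0, step)
    members = np.vstack(
        [np.interp(grid, p.positions, p.intensity) for p in profiles]
    )
    mean = members.mean(axis=0)
    sd = (
        members.std(axis=0, ddof=1)
        if members.shape[0] > 1
        else np.zeros_like(mean)
    )
    return ProfileEnsemble(
        positions=grid, members=members, mean=mean, sd=sd, channel=channels.pop()
    )


def roi_mean_intensity(
    image: CalibratedImage,
    roi_centers: list[tuple[float, float]],
    roi_side: float,
) -> list[float]:
    """Mean intensity over equal-sized square ROIs ((x, y) centres, um).

    Intended for maximum-intensity projections supplied by the caller —
    this operation does not project.  ROIs must lie fully inside the image.
    """
    if roi_side <= 0:
        raise ValueError("roi_side must be positive")
    ps = image.pixel_size
    h, w = image.shape
    out = []
    for cx, cy in roi_centers:
        c0 = (cx - roi_side / 2.0) / ps
        c1 = (cx + roi_side / 2.0) / ps
        r0 = (cy - roi_side / 2.0) / ps
        r1 = (cy + roi_side / 2.0) / ps
        if c0 < -0.5 or r0 < -0.5 or c1 > w - 0.5 or r1 > h - 0.5:
            raise ValueError(f"ROI at ({cx}, {cy}) exceeds the image bounds")
        rows = slice(int(np.ceil(r0 - 0.5 + 1e-9)), int(np.floor(r1 + 0.5 - 1e-9)) + 1)
        cols = slice(int(np.ceil(c0 - 0.5 + 1e-9)), int(np.floor(c1 + 0.5 - 1e-9)) + 1)
        out.append(float(image.pixels[rows, cols].mean()))
    return out
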