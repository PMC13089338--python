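"""Synthetic fluorescence scenes with known ground truth.

Every analysis stage in this package is validated by parameter recovery on
scenes produced here: an elliptical body column whose ectoderm and endoderm
are separated by a thin bright mesoglea band, an aboral band carrying a
localized Col IV depletion zone, stadium-shaped photoconverted patches, and
volume/aspect-ratio trajectories with optional abrupt leakage drops.

Geometry of the body scene
--------------------------
The body column is an ellipse (semi-axes ``body_length/2`` by
``body_width/2``) at ``body_angle``.  The mesoglea midline is the inner
parallel curve of the body outline at a constant ectoderm thickness, which
coincides with the level set of the Euclidean distance-to-boundary field.
The band's transverse intensity profile is Gaussian in that distance field
with ``sigma = T / (2 * sqrt(2 * ln 2))`` so its full width at half maximum
equals the nominal thickness ``T`` by construction; because the distance
field has unit gradient, the physical FWHM is preserved everywhere along
the column.  The endoderm plateau is ``tissue_intensity * endoderm_excess``
and the ectoderm plateau ``tissue_intensity``, giving the
extracellular/intracellular intensity ratio a closed-form truth.

Noise is additive i.i.d. Gaussian on images (clipped at zero) and
multiplicative log-normal on volume traces; identical ``(config, seed)``
always yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, special

from .core_io import CalibratedImage, MaskImage, PolylineROI

__all__ = [
    "SceneConfig",
    "TrajectoryConfig",
    "SceneTruth",
    "TrajectoryTruth",
    "make_body_scene",
    "make_aboral_scene",
    "make_patch_scene",
    "make_trajectory",
    "fwhm_to_sigma",
]

#: mean of a unit Gaussian over its FWHM window (closed form)
_FWHM_MEAN_FACTOR = math.sqrt(math.pi / (4 * math.log(2))) * special.erf(
    math.sqrt(math.log(2))
)


def fwhm_to_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half maximum."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class SceneConfig(BaseModel):
    """Generative parameters of a single synthetic scene.

    Lengths are micrometres, intensities arbitrary units.  The defaults
    describe a desk-scale body column: a 60 x 30 um ellipse imaged at
    0.1 um/px with a 2-um mesoglea band, matching the band thickness the
    method is meant to recover, and a 5-um aboral depletion zone.
    """

    pixel_size: float = Field(0.1, gt=0)
    body_length: float = Field(60.0, gt=0)
    body_width: float = Field(30.0, gt=0)
    body_angle: float = 0.0  # degrees, CCW in (x, y)
    ectoderm_thickness: float = Field(8.0, gt=0)
    mesoglea_thickness: float = Field(2.0, gt=0)  # band FWHM, um
    mesoglea_peak: float = Field(1000.0, gt=0)
    tissue_intensity: float = Field(100.0, ge=0)
    endoderm_excess: float = Field(1.5, ge=1)
    depletion_width: float = Field(5.0, gt=0)  # full width at half depth, um
    depletion_depth: float = Field(0.6, ge=0, le=1)
    patch_length: float = Field(100.0, gt=0)
    patch_width: float = Field(10.0, gt=0)
    patch_angle: float = 0.0
    noise_sigma: float = Field(0.0, ge=0)
    margin: float = Field(5.0, gt=0)
    scene_shape_um: Optional[tuple[float, float]] = None  # (height, width); None = auto
    aboral_scene_length: float = Field(120.0, gt=0)
    aboral_scene_height: float = Field(30.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneConfig":
        if self.body_length < self.body_width:
            raise ValueError("body_length must be >= body_width")
        if self.patch_length < self.patch_width:
            raise ValueError("patch_length must be >= patch_width")
        if self.body_width / 2 <= self.ectoderm_thickness:
            raise ValueError("ectoderm_thickness leaves no room for the endoderm")
        return self


class TrajectoryConfig(BaseModel):
    """Generative parameters of a volume/aspect-ratio time series."""

    n_frames: int = Field(100, ge=2)
    dt: float = Field(2.0, gt=0)  # minutes
    ar_start: float = Field(1.0, gt=0)
    ar_end: float = Field(8.0, gt=0)
    volume_start: float = Field(1.0e6, gt=0)  # um^3
    growth_rate: float = Field(0.005, ge=0)  # per frame, multiplicative
    leakage_frame: Optional[int] = None
    leakage_fraction: float = Field(0.15, gt=0, lt=1)
    noise_cv: float = Field(0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrajectoryConfig":
        if self.leakage_frame is not None and not (
            0 < self.leakage_frame < self.n_frames
        ):
            raise ValueError("leakage_frame must lie strictly inside the trace")
        return self


@dataclass
class SceneTruth:
    """Ground truth implied by a :class:`SceneConfig`, for recovery tests."""

    config: SceneConfig
    aspect_ratio: float | None = None
    volume: float | None = None  # solid of revolution about the long axis
    thickness: float | None = None  # band FWHM, um
    ec_ic_ratio: float | None = None
    midline: PolylineROI | None = None  # oriented: endoderm on positive d
    body_mask: np.ndarray | None = None
    pore_position: float | None = None  # arc position along `line`, um
    line: PolylineROI | None = None
    depletion_width: float | None = None
    depletion_depth: float | None = None
    patch_area: float | None = None  # analytic stadium area, um^2
    patch_skeleton_length: float | None = None  # analytic medial axis, um
    patch_ar: float | None = None


@dataclass
class TrajectoryTruth:
    config: TrajectoryConfig
    clean_volume: np.ndarray = field(default_factory=lambda: np.empty(0))
    leakage_frame: int | None = None
    leakage_fraction: float | None = None
    ar_at_leakage: float | None = None


# ---------------------------------------------------------------------------


def _grid(config: SceneConfig, height_um: float, width_um: float):
    if config.scene_shape_um is not None:
        req_h, req_w = config.scene_shape_um
        if req_h < height_um or req_w < width_um:
            raise ValueError(
                f"scene content ({height_um:.1f} x {width_um:.1f} um) does not fit "
                f"the requested {req_h:.1f} x {req_w:.1f} um grid"
            )
        height_um, width_um = req_h, req_w
    ps = config.pixel_size
    n_rows = int(round(height_um / ps))
    n_cols = int(round(width_um / ps))
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    return rows * ps, cols * ps, (n_rows, n_cols)  # y, x in um


def _add_noise(pixels: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma > 0:
        pixels = pixels + rng.normal(0.0, sigma, size=pixels.shape)
    return np.clip(pixels, 0.0, None)


def make_body_scene(
    config: SceneConfig,
) -> tuple[dict[str, CalibratedImage], MaskImage, SceneTruth]:
    """Render an elliptical body column with a mesoglea band.

    Returns the ColIV channel, the true body mask and a :class:`SceneTruth`
    whose midline polyline runs along one flank of the column, oriented so
    the endoderm lies on the positive transverse side.
    """
    a = config.body_length / 2.0
    b = config.body_width / 2.0
    ang = math.radians(config.body_angle)
    # bounding half-extents of the rotated ellipse
    ex = math.hypot(a * math.cos(ang), b * math.sin(ang))
    ey = math.hypot(a * math.sin(ang), b * math.cos(ang))
    y, x, shape = _grid(config, 2 * (ey + config.margin), 2 * (ex + config.margin))
    cy = (shape[0] - 1) * config.pixel_size / 2.0
    cx = (shape[1] - 1) * config.pixel_size / 2.0

    # body-frame coordinates
    dx, dy = x - cx, y - cy
    xb = dx * math.cos(ang) + dy * math.sin(ang)
    yb = -dx * math.sin(ang) + dy * math.cos(ang)
    body = (xb / a) ** 2 + (yb / b) ** 2 <= 1.0

    d_in = ndimage.distance_transform_edt(body, sampling=config.pixel_size)
    m = config.ectoderm_thickness
    sigma = fwhm_to_sigma(config.mesoglea_thickness)
    ridge = config.mesoglea_peak * np.exp(-((d_in - m) ** 2) / (2 * sigma**2)) * body
    tissue = np.where(
        d_in > m,
        config.tissue_intensity * config.endoderm_excess,
        np.where(body, config.tissue_intensity, 0.0),
    )
    rng = np.random.default_rng(config.seed)
    pixels = _add_noise(tissue + ridge, config.noise_sigma, rng)

    image = CalibratedImage(pixels, config.pixel_size, "ColIV")
    mask = MaskImage(body, config.pixel_size)
    truth = SceneTruth(
        config=config,
        aspect_ratio=config.body_length / config.body_width,
        volume=4.0 / 3.0 * math.pi * a * b**2,
        thickness=config.mesoglea_thickness,
        ec_ic_ratio=_ec_ic_truth(config),
        midline=_midline_flank(config, (cx, cy)),
        body_mask=body,
    )
    return {"ColIV": image}, mask, truth


def _ec_ic_truth(config: SceneConfig) -> float | None:
    """Closed-form extracellular/intracellular ratio of the body scene.

    With plateaus T_e (ectoderm) and T_n (endoderm) flanking a Gaussian peak
    of amplitude P, the edge baseline is (T_e + T_n) / 2, the tissue step
    averages out over the symmetric FWHM window, and the mean of the peak
    over its own FWHM is P * sqrt(pi / (4 ln 2)) * erf(sqrt(ln 2)).
    Undefined (None) when endoderm and ectoderm plateaus coincide.
    """
    t_e = config.tissue_intensity
    t_n = t_e * config.endoderm_excess
    denom = t_n - (t_e + t_n) / 2.0
    if denom <= 0:
        return None
    return _FWHM_MEAN_FACTOR * config.mesoglea_peak / denom


def _midline_flank(
    config: SceneConfig, center: tuple[float, float], theta_deg=(50.0, 130.0), n=181
) -> PolylineROI:
    """Arc of the mesoglea midline along one long flank of the body column.

    The midline is the inner parallel curve of the body ellipse at the
    ectoderm thickness; the flank arc avoids the high-curvature poles where
    the parallel curve degenerates.  Orientation: endoderm to the left of
    travel (positive transverse offset after straightening).
    """
    a = config.body_length / 2.0
    b = config.body_width / 2.0
    m = config.ectoderm_thickness
    ang = math.radians(config.body_angle)
    th = np.radians(np.linspace(theta_deg[0], theta_deg[1], n))
    norm = np.hypot(b * np.cos(th), a * np.sin(th))
    xb = a * np.cos(th) - m * b * np.cos(th) / norm
    yb = b * np.sin(th) - m * a * np.sin(th) / norm
    xr = xb * math.cos(ang) - yb * math.sin(ang) + center[0]
    yr = xb * math.sin(ang) + yb * math.cos(ang) + center[1]
    return PolylineROI(np.column_stack([xr, yr]))


def make_aboral_scene(
    config: SceneConfig,
) -> tuple[CalibratedImage, CalibratedImage, SceneTruth]:
    """Render the aboral pole as a straight mesoglea band with a pore.

    The ColIV channel is attenuated multiplicatively around the pore by a
    Gaussian dip of depth ``depletion_depth`` whose full width at half
    depth equals ``depletion_width``; the Laminin channel carries a
    co-located band thickening instead of a dip.  The truth records the
    profile line along the band and the pore's arc position on it.
    """
    if config.depletion_width >= config.aboral_scene_length / 2:
        raise ValueError("depletion_width too wide for the aboral scene")
    y, x, shape = _grid(config, config.aboral_scene_height, config.aboral_scene_length)
    ps = config.pixel_size
    # pore and band midline sit exactly on pixel centres
    y0 = ((shape[0] - 1) // 2) * ps
    x0 = ((shape[1] - 1) // 2) * ps

    sigma_t = fwhm_to_sigma(config.mesoglea_thickness)
    sigma_d = fwhm_to_sigma(config.depletion_width)
    dip = np.exp(-((x - x0) ** 2) / (2 * sigma_d**2))

    tissue = np.where(
        y > y0, config.tissue_intensity * config.endoderm_excess, config.tissue_intensity
    )
    band = config.mesoglea_peak * np.exp(-((y - y0) ** 2) / (2 * sigma_t**2))
    colv = (tissue + band) * (1.0 - config.depletion_depth * dip)

    # laminin: same band, locally thickened by up to 50% at the pore
    sig_lam = sigma_t * (1.0 + 0.5 * dip)
    lam = tissue + config.mesoglea_peak * np.exp(-((y - y0) ** 2) / (2 * sig_lam**2))

    rng = np.random.default_rng(config.seed)
    colv = _add_noise(colv, config.noise_sigma, rng)
    lam = _add_noise(lam, config.noise_sigma, rng)

    line = PolylineROI(np.array([[0.0, y0], [(shape[1] - 1) * ps, y0]]))
    truth = SceneTruth(
        config=config,
        thickness=config.mesoglea_thickness,
        pore_position=x0,
        line=line,
        depletion_width=config.depletion_width,
        depletion_depth=config.depletion_depth,
    )
    return (
        CalibratedImage(colv, ps, "ColIV"),
        CalibratedImage(lam, ps, "Laminin"),
        truth,
    )


def make_patch_scene(config: SceneConfig) -> tuple[MaskImage, SceneTruth]:
    """Render a stadium-shaped photoconverted patch mask.

    A stadium of overall length L and width W is the set of points within
    W/2 of a segment of length L - W; its medial axis is that segment, so
    the analytic skeleton length is L - W and the analytic elongation score
    is (L - W)^2 / area.
    """
    L, W = config.patch_length, config.patch_width
    ang = math.radians(config.patch_angle)
    half_seg = (L - W) / 2.0
    ux, uy = math.cos(ang), math.sin(ang)
    ex = abs(ux) * half_seg + W / 2.0
    ey = abs(uy) * half_seg + W / 2.0
    y, x, shape = _grid(config, 2 * (ey + config.margin), 2 * (ex + config.margin))
    ps = config.pixel_size
    cy = (shape[0] - 1) * ps / 2.0
    cx = (shape[1] - 1) * ps / 2.0

    # distance from each pixel centre to the core segment
    t = np.clip((x - cx) * ux + (y - cy) * uy, -half_seg, half_seg)
    dist = np.hypot(x - cx - t * ux, y - cy - t * uy)
    mask = dist <= W / 2.0

    area = L * W - (4.0 - math.pi) * (W / 2.0) ** 2
    skel = L - W
    truth = SceneTruth(
        config=config,
        patch_area=area,
        patch_skeleton_length=skel,
        patch_ar=(skel**2 / area) if skel > 0 else 0.0,
    )
    return MaskImage(mask, ps), truth


def make_trajectory(config: TrajectoryConfig) -> tuple[pd.DataFrame, TrajectoryTruth]:
    """Simulate a morphospace trajectory with an optional leakage drop.

    The aspect ratio interpolates linearly from ``ar_start`` to ``ar_end``;
    the volume grows multiplicatively at ``growth_rate`` per frame and, if
    ``leakage_frame`` is set, drops by ``leakage_fraction`` at that frame
    and stays reduced.  Noise is multiplicative log-normal with coefficient
    of variation ``noise_cv`` (unit mean).
    """
    k = np.arange(config.n_frames)
    ar = np.linspace(config.ar_start, config.ar_end, config.n_frames)
    volume = config.volume_start * (1.0 + config.growth_rate) ** k
    if config.leakage_frame is not None:
        volume = volume * np.where(
            k >= config.leakage_frame, 1.0 - config.leakage_fraction, 1.0
        )
    clean = volume.copy()
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        s = math.sqrt(math.log(1.0 + config.noise_cv**2))
        volume = volume * np.exp(rng.normal(0.0, s, size=volume.shape) - s**2 / 2.0)
    df = pd.DataFrame(
        {"frame": k, "time": k * config.dt, "volume": volume, "aspect_ratio": ar}
    )
    truth = TrajectoryTruth(
        config=config,
        clean_volume=clean,
        leakage_frame=config.leakage_frame,
        leakage_fraction=(
            config.leakage_fraction if config.leakage_frame is not None else None
        ),
        ar_at_leakage=(
            float(ar[config.leakage_frame]) if config.leakage_frame is not None else None
        ),
    )
    return df, truth
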