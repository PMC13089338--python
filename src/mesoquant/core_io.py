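"""Calibrated image / ROI / table I-O.

All downstream analysis consumes physical units (micrometres); the only
place pixel indices appear is at the interpolation layer.  Coordinate
convention: 0-based pixel indices, pixel centres at integer coordinates,
physical ``(x, y) = (col, row) * pixel_size``.  Only isotropic 2D
calibration is supported; anisotropic input is rejected rather than
silently averaged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedImage",
    "MaskImage",
    "PolylineROI",
    "CalibrationError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_roi",
    "write_roi",
    "write_table",
    "read_table",
]


class CalibrationError(ValueError):
    """Raised when the physical pixel size cannot be established."""


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D intensity grid with an isotropic physical calibration.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size
        Micrometres per pixel, identical along both axes.
    channel_name
        Free-text channel label, e.g. ``"ColIV"``, ``"Laminin"``, ``"pErk"``.
    """

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"expected a 2D grid of at least 2x2 pixels, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if not (self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (height, width) of the grid in micrometres."""
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


@dataclass(frozen=True)
class MaskImage:
    """A binary grid with the same calibration contract as CalibratedImage."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"expected a 2D mask of at least 2x2 pixels, got shape {px.shape}")
        if not (self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2


@dataclass(frozen=True)
class PolylineROI:
    """An ordered, open polyline in physical (x, y) micrometre coordinates."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("polyline needs an (n >= 2, 2) array of (x, y) points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("polyline has coincident consecutive points")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        """Total length in micrometres."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def reversed(self) -> "PolylineROI":
        return PolylineROI(self.points[::-1].copy(), self.closed)


# ---------------------------------------------------------------------------
# TIFF images


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Extract isotropic um/px from TIFF resolution tags (plain or OME)."""
    page = tf.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return None
    unit_tag = tags.get("ResolutionUnit")
    unit = unit_tag.value if unit_tag is not None else 2
    unit = getattr(unit, "value", unit)  # enum -> int
    # pixels per unit -> um per pixel
    to_um = {1: 1.0, 2: 25400.0, 3: 10000.0}.get(int(unit))
    if to_um is None:
        return None

    def as_float(v):
        if isinstance(v, tuple):
            num, den = v
            if den == 0 or num == 0:
                return None
            return num / den
        return float(v) if v else None

    px_per_unit_x = as_float(xres.value)
    px_per_unit_y = as_float(yres.value)
    if not px_per_unit_x or not px_per_unit_y:
        return None
    # writers emit a placeholder 1:1 resolution with no unit; that is not
    # a calibration
    if int(unit) == 1 and px_per_unit_x == 1.0 and px_per_unit_y == 1.0:
        return None
    # RESUNIT.NONE (1): interpret resolution as px/um directly
    sx = (1.0 if to_um == 1.0 else to_um) / px_per_unit_x
    sy = (1.0 if to_um == 1.0 else to_um) / px_per_unit_y
    if not np.isclose(sx, sy, rtol=1e-3):
        raise CalibrationError(
            f"anisotropic calibration ({sx:g} x {sy:g} um/px) is not supported"
        )
    return sx


def read_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_name: str = "",
) -> CalibratedImage | list[CalibratedImage]:
    """Read a single-plane or stacked TIFF as calibrated image(s).

    The pixel size is taken from the TIFF resolution metadata unless
    ``pixel_size_override`` is given; if neither source provides a
    calibration a :class:`CalibrationError` is raised.  A multi-plane stack
    yields a list of images sharing one calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_px = _pixel_size_from_tiff(tf)
    pixel_size = pixel_size_override if pixel_size_override is not None else meta_px
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no resolution metadata and no pixel_size_override given"
        )
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        return CalibratedImage(data, pixel_size, channel_name)
    if data.ndim == 3:
        return [CalibratedImage(pl, pixel_size, channel_name) for pl in data]
    raise ValueError(f"{path}: unsupported TIFF dimensionality {data.ndim}")


def write_image(image: CalibratedImage | MaskImage, path: str | Path) -> None:
    """Write a TIFF carrying the calibration in its resolution tags."""
    px_per_cm = 10000.0 / image.pixel_size
    data = image.pixels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(
        Path(path),
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_mask(path: str | Path, pixel_size_override: float | None = None) -> MaskImage:
    img = read_image(path, pixel_size_override)
    if isinstance(img, list):
        raise ValueError(f"{path}: expected a single-plane mask, got a stack")
    return MaskImage(img.pixels > 0, img.pixel_size)


write_mask = write_image


# ---------------------------------------------------------------------------
# ROIs


def read_roi(path: str | Path) -> PolylineROI:
    """Read a polyline ROI from JSON (``[[x, y], ...]``) or CSV (x,y rows).

    Coordinates are physical micrometres.  Files with fewer than two points
    or zero total arc length are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            payload = payload.get("points", payload)
        pts = np.asarray(payload, dtype=float)
    else:
        df = pd.read_csv(path, header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns of coordinates")
        if isinstance(df.iloc[0, 0], str):  # header row present
            df = df.iloc[1:]
        pts = df.iloc[:, :2].to_numpy(dtype=float)
    return PolylineROI(pts)


def write_roi(roi: PolylineROI, path: str | Path) -> None:
    Path(path).write_text(json.dumps(roi.points.tolist()))


# ---------------------------------------------------------------------------
# Tables


def write_table(
    rows: Iterable, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write homogeneous records as CSV: header, deterministic column order,
    UTF-8, '.' decimal separator.  Accepts dataclasses, dicts or a DataFrame;
    ``columns`` supplies the header for an empty record list.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        records = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                records.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            elif isinstance(r, dict):
                records.append(r)
            else:
                raise TypeError(f"cannot tabulate record of type {type(r).__name__}")
        cols = list(records[0].keys()) if records else list(columns or [])
        for rec in records[1:]:
            if list(rec.keys()) != cols:
                raise ValueError("heterogeneous records cannot be tabulated")
        df = pd.DataFrame.from_records(records, columns=cols)
    df.to_csv(Path(path), index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), encoding="utf-8")
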