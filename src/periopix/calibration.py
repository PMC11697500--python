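"""Fiducial sticker detection and pixel-to-millimetre calibration.

A green adhesive dot of known physical diameter (24 mm by default) placed on
the forehead calibrates every image: once its circular outline is fitted in
pixels, mm_per_px = diameter_mm / (2 * radius_px). Detection is a plain
colour-and-shape pipeline — HSV green thresholding, connected components,
an area and circularity gate, then a least-squares circle fit to the
sub-pixel component boundary. The calibration assumes the sticker and the
eyes are coplanar with the sensor (parallax at a ~1 m standoff is ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import find_contours, regionprops

from .errors import CalibrationNotFoundError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_DIAMETER_MM = 24.0


@dataclass
class CalibConfig:
    """Green-detection parameters; hue/sat/val on the [0, 1] HSV scale."""

    hue_min: float = 0.20
    hue_max: float = 0.47
    sat_min: float = 0.30
    val_min: float = 0.15
    min_area_px: int = 200
    min_circularity: float = 0.8  # 4*pi*A / P^2
    degraded_residual_frac: float = 0.1  # residual > frac * radius -> warn


@dataclass
class FittedCircle:
    center_x: float
    center_y: float
    radius_px: float
    residual_px: float  # RMS distance of boundary points from the circle
    degraded: bool = False


@dataclass
class CalibrationScale:
    """mm-per-pixel conversion factor derived from the fitted fiducial."""

    mm_per_px: float
    circle: FittedCircle
    diameter_mm: float = DEFAULT_DIAMETER_MM

    @property
    def fit_residual(self) -> float:
        return self.circle.residual_px


def _fit_circle(points: np.ndarray) -> tuple[float, float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (cx, cy, r, rms)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(c + cx * cx + cy * cy))
    dist = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return float(cx), float(cy), r, rms


def detect_sticker(image: np.ndarray, config: CalibConfig | None = None) -> FittedCircle:
    """Locate the green fiducial dot and fit a circle to its boundary.

    Raises :class:`CalibrationNotFoundError` when no connected green
    component passes the area and circularity gates. A fit whose RMS
    boundary residual exceeds ``degraded_residual_frac * radius`` is
    returned with ``degraded=True`` and logged as a warning.
    """
    cfg = config or CalibConfig()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected an RGB image; got shape {img.shape}")
    rgb = img.astype(float) / 255.0 if img.dtype == np.uint8 else img.astype(float)
    hsv = rgb2hsv(rgb)
    mask = (
        (hsv[..., 0] >= cfg.hue_min)
        & (hsv[..., 0] <= cfg.hue_max)
        & (hsv[..., 1] >= cfg.sat_min)
        & (hsv[..., 2] >= cfg.val_min)
    )
    labels, n = ndimage.label(mask)
    if n == 0:
        raise CalibrationNotFoundError("no green pixels found")

    best = None
    for prop in regionprops(labels):
        if prop.area < cfg.min_area_px:
            continue
        perim = prop.perimeter
        if perim <= 0:
            continue
        circularity = 4.0 * np.pi * prop.area / (perim * perim)
        if circularity < cfg.min_circularity:
            continue
        if best is None or prop.area > best.area:
            best = prop
    if best is None:
        raise CalibrationNotFoundError(
            "no green component passed the area/circularity gates"
        )

    component = labels == best.label
    contours = find_contours(component.astype(float), 0.5)
    boundary = np.vstack(contours)[:, ::-1]  # (row, col) -> (x, y)
    cx, cy, r, rms = _fit_circle(boundary)
    degraded = rms > cfg.degraded_residual_frac * r
    if degraded:
        log.warning(
            "degraded fiducial fit: residual %.2f px on radius %.1f px", rms, r
        )
    return FittedCircle(cx, cy, r, rms, degraded=degraded)


def scale_from_circle(
    circle: FittedCircle, diameter_mm: float = DEFAULT_DIAMETER_MM
) -> CalibrationScale:
    """Convert a fitted fiducial circle to a mm-per-pixel scale."""
    if circle.radius_px <= 0:
        raise ValidationError(f"radius must be > 0; got {circle.radius_px}")
    if diameter_mm <= 0:
        raise ValidationError(f"diameter_mm must be > 0; got {diameter_mm}")
    return CalibrationScale(
        mm_per_px=diameter_mm / (2.0 * circle.radius_px),
        circle=circle,
        diameter_mm=diameter_mm,
    )
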