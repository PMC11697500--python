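"""The seven clinical periocular measurements.

Given ten landmarks and a pixel-to-millimetre scale, compute:

- MRD1 (marginal reflex distance 1): signed vertical distance from the
  pupillary centre up to the upper-lid margin midpoint, per eye. Negative
  when the lid droops below the pupil centre (severe ptosis).
- MRD2: signed vertical distance from the pupillary centre down to the
  lower-lid margin midpoint, per eye.
- PFH (palpebral fissure height): MRD1 + MRD2, by construction.
- HPA (horizontal palpebral aperture): medial-to-lateral canthal distance
  within each eye.
- IICD / OICD: inner / outer intercanthal distance (between the two medial /
  lateral canthi).
- IPD: interpupillary distance.

The vertical measures use the signed y-component because the clinical
definition is a vertical distance along the pupil's vertical midline; they
are therefore not invariant under head roll. The horizontal measures default
to the full Euclidean inter-landmark distance, which is roll-invariant and
coincides with the x-component for a level head; ``horizontal="x"`` switches
to the strict x-component convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import landmarks as lm
from .errors import ValidationError
from .landmarks import LandmarkSet

#: Measurements reported once per eye (pooled bilaterally in agreement stats).
BILATERAL_METRICS = ("mrd1", "mrd2", "pfh", "hpa")
#: Measurements reported once per face.
CENTRAL_METRICS = ("ipd", "iicd", "oicd")

#: Column order used in measurement CSV files.
RECORD_FIELDS = (
    "mrd1_right",
    "mrd1_left",
    "mrd2_right",
    "mrd2_left",
    "pfh_right",
    "pfh_left",
    "hpa_right",
    "hpa_left",
    "ipd",
    "iicd",
    "oicd",
    "mm_per_px",
)


@dataclass
class MeasurementRecord:
    """The seven periocular metrics in millimetres (four per-eye, three per-face)."""

    mrd1_right: float
    mrd1_left: float
    mrd2_right: float
    mrd2_left: float
    pfh_right: float
    pfh_left: float
    hpa_right: float
    hpa_left: float
    ipd: float
    iicd: float
    oicd: float
    mm_per_px: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def value(self, metric: str, side: str | None = None) -> float:
        key = metric if side is None else f"{metric}_{side}"
        return getattr(self, key)


def _mm_per_px(scale) -> float:
    """Accept a CalibrationScale, a SceneParams-like object, or a bare float."""
    for attr in ("mm_per_px", "mm_per_px_true"):
        if hasattr(scale, attr):
            scale = getattr(scale, attr)
            break
    s = float(scale)
    if not s > 0:
        raise ValidationError(f"mm_per_px must be > 0; got {s}")
    return s


def compute_measurements(
    landmarks: LandmarkSet,
    scale,
    horizontal: str = "euclidean",
) -> MeasurementRecord:
    """Compute all seven metrics from one landmark set.

    ``scale`` may be a :class:`~periopix.calibration.CalibrationScale`, an
    object exposing ``mm_per_px``/``mm_per_px_true``, or a float in mm/px.
    """
    s = _mm_per_px(scale)
    if horizontal not in ("euclidean", "x"):
        raise ValidationError(f"unknown horizontal mode {horizontal!r}")
    p = landmarks.points

    def dist(i: int, j: int) -> float:
        if horizontal == "euclidean":
            return float(np.linalg.norm(p[i] - p[j])) * s
        return abs(float(p[i, 0] - p[j, 0])) * s

    mrd1_r = float(p[lm.R_PUPIL, 1] - p[lm.R_UPPER, 1]) * s
    mrd1_l = float(p[lm.L_PUPIL, 1] - p[lm.L_UPPER, 1]) * s
    mrd2_r = float(p[lm.R_LOWER, 1] - p[lm.R_PUPIL, 1]) * s
    mrd2_l = float(p[lm.L_LOWER, 1] - p[lm.L_PUPIL, 1]) * s
    return MeasurementRecord(
        mrd1_right=mrd1_r,
        mrd1_left=mrd1_l,
        mrd2_right=mrd2_r,
        mrd2_left=mrd2_l,
        pfh_right=mrd1_r + mrd2_r,
        pfh_left=mrd1_l + mrd2_l,
        hpa_right=dist(lm.R_MEDIAL, lm.R_LATERAL),
        hpa_left=dist(lm.L_MEDIAL, lm.L_LATERAL),
        ipd=dist(lm.R_PUPIL, lm.L_PUPIL),
        iicd=dist(lm.R_MEDIAL, lm.L_MEDIAL),
        oicd=dist(lm.R_LATERAL, lm.L_LATERAL),
        mm_per_px=s,
    )


@dataclass
class MeasurementReport:
    """A MeasurementRecord plus the audit trail that produced it."""

    record: MeasurementRecord
    landmarks: LandmarkSet
    scale: object  # CalibrationScale


def measure_image(
    image: np.ndarray,
    model,
    sticker_diameter_mm: float = 24.0,
) -> MeasurementReport:
    """Full single-image pipeline: calibrate, detect landmarks, measure.

    Runs fiducial sticker detection, converts the fitted circle to a
    mm-per-pixel scale, predicts the ten landmarks with the trained model,
    and computes the measurement record. Calibration and decoding errors
    propagate unchanged.
    """
    from .calibration import detect_sticker, scale_from_circle
    from .detector import predict

    circle = detect_sticker(image)
    scale = scale_from_circle(circle, diameter_mm=sticker_diameter_mm)
    landmarks = predict(model, image)
    record = compute_measurements(landmarks, scale)
    return MeasurementReport(record=record, landmarks=landmarks, scale=scale)
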