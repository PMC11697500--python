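"""File formats: annotation JSON, measurement CSV, dataset manifests.

Annotations are JSON with one named entry per canonical landmark so files
stay human-diffable; measurements and manifests are flat CSV tables.
Writing is canonical (sorted keys, fixed ordering, fixed float formatting)
so identical content always produces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import SchemaError, ValidationError
from .landmarks import LANDMARK_NAMES, LandmarkSet
from .measure import RECORD_FIELDS, MeasurementRecord

SCHEMA_VERSION = 1


@dataclass
class AnnotationFile:
    """One face's landmark annotation, bound to an image file."""

    image_name: str
    image_size: tuple[int, int]  # (width, height)
    landmarks: LandmarkSet
    sticker_circle: tuple[float, float, float] | None = None  # (cx, cy, r)
    rater: str | None = None
    schema_version: int = SCHEMA_VERSION


def write_annotations(ann: AnnotationFile, path: str | Path) -> None:
    payload = {
        "schema_version": ann.schema_version,
        "image": ann.image_name,
        "image_size": [int(ann.image_size[0]), int(ann.image_size[1])],
        "landmarks": [
            {"name": name, "x": float(x), "y": float(y)}
            for name, (x, y) in zip(LANDMARK_NAMES, ann.landmarks.points)
        ],
    }
    if ann.sticker_circle is not None:
        cx, cy, r = ann.sticker_circle
        payload["sticker_circle"] = {
            "center_x": float(cx),
            "center_y": float(cy),
            "radius_px": float(r),
        }
    if ann.rater is not None:
        payload["rater"] = ann.rater
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def read_annotations(path: str | Path) -> AnnotationFile:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("schema_version", "image", "image_size", "landmarks"):
        if key not in payload:
            raise SchemaError(f"{path}: missing field {key!r}", key=key)
    w, h = payload["image_size"]
    entries = payload["landmarks"]
    seen: dict[str, tuple[float, float]] = {}
    for entry in entries:
        for key in ("name", "x", "y"):
            if key not in entry:
                raise SchemaError(f"{path}: landmark entry missing {key!r}", key=key)
        name = entry["name"]
        if name not in LANDMARK_NAMES:
            raise SchemaError(f"{path}: unknown landmark name {name!r}", key=name)
        if name in seen:
            raise SchemaError(f"{path}: duplicate landmark {name!r}", key=name)
        x, y = float(entry["x"]), float(entry["y"])
        if not (0.0 <= x < w and 0.0 <= y < h):
            raise SchemaError(
                f"{path}: landmark {name!r} at ({x}, {y}) outside image ({w}x{h})",
                key=name,
            )
        seen[name] = (x, y)
    missing = [n for n in LANDMARK_NAMES if n not in seen]
    if missing:
        raise SchemaError(f"{path}: missing landmarks {missing}", key=missing[0])
    sticker = None
    if "sticker_circle" in payload:
        sc = payload["sticker_circle"]
        sticker = (sc["center_x"], sc["center_y"], sc["radius_px"])
    return AnnotationFile(
        image_name=payload["image"],
        image_size=(int(w), int(h)),
        landmarks=LandmarkSet.from_dict(seen),
        sticker_circle=sticker,
        rater=payload.get("rater"),
        schema_version=int(payload["schema_version"]),
    )


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image).save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)).convert("RGB"))


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def records_to_frame(
    names: list[str], records: list[MeasurementRecord]
) -> pd.DataFrame:
    """Flatten records into a table with mm values rounded to 2 decimals."""
    rows = []
    for name, rec in zip(names, records):
        row = {"image": name}
        for field in RECORD_FIELDS:
            v = getattr(rec, field)
            row[field] = round(v, 6) if field == "mm_per_px" else round(v, 2)
        rows.append(row)
    return pd.DataFrame(rows, columns=["image"] + list(RECORD_FIELDS))


def write_measurements(
    names: list[str], records: list[MeasurementRecord], path: str | Path
) -> None:
    records_to_frame(names, records).to_csv(path, index=False)


def read_measurements(path: str | Path) -> tuple[list[str], list[MeasurementRecord]]:
    df = pd.read_csv(path)
    missing = [c for c in ("image",) + RECORD_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}", key=missing[0])
    records = [
        MeasurementRecord(**{f: float(row[f]) for f in RECORD_FIELDS})
        for _, row in df.iterrows()
    ]
    return df["image"].astype(str).tolist(), records


# ---------------------------------------------------------------------------
# synthetic dataset directories
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"
RUN_INFO_NAME = "run.json"


def write_dataset(samples, out_dir: str | Path, seed: int, ranges=None) -> Path:
    """Write a simulated dataset: PNGs, truth annotations, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(samples):
        stem = f"scene_{i:04d}"
        write_image(sample.image, out / f"{stem}.png")
        h, w = sample.image.shape[:2]
        write_annotations(
            AnnotationFile(
                image_name=f"{stem}.png",
                image_size=(w, h),
                landmarks=sample.landmarks_true,
                sticker_circle=sample.sticker_circle_true,
                rater="truth",
            ),
            out / f"{stem}.json",
        )
        p = sample.params
        rows.append(
            {
                "sample_id": stem,
                "mrd1_right": p.mrd1_right,
                "mrd1_left": p.mrd1_left,
                "mrd2_right": p.mrd2_right,
                "mrd2_left": p.mrd2_left,
                "hpa_right": p.hpa_right,
                "hpa_left": p.hpa_left,
                "ipd": p.ipd,
                "iicd": p.iicd,
                "oicd": p.oicd,
                "mm_per_px_true": p.mm_per_px_true,
                "head_roll_deg": p.head_roll_deg,
                "noise_sd": p.noise_sd,
            }
        )
    pd.DataFrame(rows).to_csv(out / MANIFEST_NAME, index=False, float_format="%.6f")
    (out / RUN_INFO_NAME).write_text(
        json.dumps(
            {"seed": seed, "n": len(samples), "ranges": ranges or {}},
            sort_keys=True,
            indent=2,
        )
        + "\n"
    )
    return out


def load_dataset(data_dir: str | Path) -> list[tuple[np.ndarray, LandmarkSet]]:
    """Load (image, landmarks) pairs from a simulated/annotated directory."""
    data = Path(data_dir)
    manifest = data / MANIFEST_NAME
    if manifest.exists():
        stems = pd.read_csv(manifest)["sample_id"].astype(str).tolist()
    else:
        stems = sorted(p.stem for p in data.glob("*.json") if p.name != RUN_INFO_NAME)
    if not stems:
        raise ValidationError(f"no annotated samples found in {data}")
    pairs = []
    for stem in stems:
        ann = read_annotations(data / f"{stem}.json")
        pairs.append((read_image(data / ann.image_name), ann.landmarks))
    return pairs
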