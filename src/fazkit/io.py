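"""Reading and writing angiograms, masks, metadata sidecars, annotations
and measurement tables.

Images travel as plain single-frame grayscale TIFF or PNG; per-scan
acquisition metadata (subject, eye, visit, plexus, axial length, scan
quality) travels in a CSV sidecar keyed by file name; training annotations
for the pixel classifier are JSON polylines.  Everything round-trips
losslessly so batch runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "ScanMetadata",
    "AngiogramImage",
    "BinaryMask",
    "TrainingAnnotation",
    "MeasurementTable",
    "read_angiogram",
    "read_image_array",
    "filter_quality",
    "write_mask",
    "read_mask",
    "write_measurements",
    "read_measurements",
    "read_annotations",
    "write_annotations",
    "read_metadata_csv",
    "write_metadata_csv",
]

EYES = ("OD", "OS")
PLEXUSES = ("SVP", "IVP", "DVP")
VISITS = (1, 2, 3, 4)
METHODS = ("script", "ml")
ANNOTATION_LABELS = ("vascular", "avascular")

#: Scans with quality index at or below this are excluded from analysis.
QUALITY_INDEX_CUTOFF = 15


@dataclass(frozen=True)
class ScanMetadata:
    """Acquisition metadata for one en-face angiogram.

    ``visit`` runs 1–4 (baseline plus three follow-ups); ``plexus`` names
    the depth slab (superficial / intermediate / deep vascular plexus);
    ``axial_length_mm`` drives the magnification correction and
    ``quality_index`` the device's scan-quality score used for exclusion.
    """

    subject_id: str
    eye: str
    visit: int
    plexus: str
    axial_length_mm: float
    quality_index: int

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"invalid field 'eye': {self.eye!r} (expected one of {EYES})")
        if self.visit not in VISITS:
            raise ValueError(f"invalid field 'visit': {self.visit!r} (expected 1-4)")
        if self.plexus not in PLEXUSES:
            raise ValueError(
                f"invalid field 'plexus': {self.plexus!r} (expected one of {PLEXUSES})"
            )
        if not (15.0 < self.axial_length_mm < 40.0):
            raise ValueError(
                f"invalid field 'axial_length_mm': {self.axial_length_mm!r} "
                "(expected in (15, 40) mm)"
            )
        if self.quality_index < 0:
            raise ValueError(
                f"invalid field 'quality_index': {self.quality_index!r} (expected >= 0)"
            )


@dataclass
class AngiogramImage:
    """8-bit en-face angiogram raster plus its acquisition metadata."""

    pixels: np.ndarray
    metadata: ScanMetadata

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("angiogram pixels must be a 2-D grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("angiogram pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Foreground/background raster; foreground is 255, background 0.

    ``origin`` is the (x, y) offset of the mask's pixel (0, 0) in the
    coordinate frame of the source image it was derived from.
    """

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        bad = set(np.unique(self.pixels)) - {0, 255}
        if bad:
            raise ValueError(f"mask pixels must be 0 or 255; found values {sorted(bad)}")

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.pixels))

    def as_bool(self) -> np.ndarray:
        return self.pixels > 0

    @classmethod
    def from_bool(cls, fg: np.ndarray, origin: tuple[int, int] = (0, 0)) -> "BinaryMask":
        return cls(np.where(np.asarray(fg, dtype=bool), 255, 0).astype(np.uint8), origin)


@dataclass(frozen=True)
class TrainingAnnotation:
    """A labelled polyline drawn over a training image.

    Vertices are 0-based (x, y) pixel coordinates of the 512×512 cropped
    frame, x rightward, y downward.
    """

    polyline: tuple[tuple[float, float], ...]
    label: str
    source_image_id: str

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(
                f"invalid annotation label {self.label!r}; expected one of {ANNOTATION_LABELS}"
            )
        if len(self.polyline) < 2:
            raise ValueError("annotation polyline needs at least 2 vertices")


MEASUREMENT_COLUMNS = [
    "subject_id",
    "eye",
    "visit",
    "plexus",
    "method",
    "pixel_count",
    "area_mm2",
]


@dataclass
class MeasurementTable:
    """Long-format FAZ measurements: one row per scan per method.

    The tuple (subject_id, eye, visit, plexus, method) is a unique key.
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MEASUREMENT_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=MEASUREMENT_COLUMNS).copy()
        df["visit"] = df["visit"].astype(int)
        df["pixel_count"] = df["pixel_count"].astype(int)
        df["area_mm2"] = df["area_mm2"].astype(float)
        key = ["subject_id", "eye", "visit", "plexus", "method"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key, keep=False)]
            raise ValueError(f"duplicate measurement keys:\n{dup[key].drop_duplicates()}")
        if (df["area_mm2"] < 0).any() or (df["pixel_count"] < 0).any():
            raise ValueError("areas and pixel counts must be nonnegative")
        zero_mismatch = (df["area_mm2"] == 0) != (df["pixel_count"] == 0)
        if zero_mismatch.any():
            raise ValueError("area_mm2 must be 0 exactly when pixel_count is 0")
        bad_m = set(df["method"]) - set(METHODS)
        if bad_m:
            raise ValueError(f"unknown methods {sorted(bad_m)}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def append(self, **row) -> None:
        new = pd.concat([self.records, pd.DataFrame([row])], ignore_index=True)
        self.records = MeasurementTable(new).records


# ---------------------------------------------------------------------------
# images


def read_image_array(path: str | Path) -> np.ndarray:
    """Read a single-frame grayscale raster (TIFF or PNG) as an array.

    Multi-frame TIFFs are rejected: silently picking a frame would hide
    acquisition/export errors.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            with tifffile.TiffFile(path) as tf:
                n_frames = len(tf.pages)
                if n_frames != 1:
                    raise ValueError(
                        f"multi-frame TIFF ({n_frames} frames) is ambiguous: {path}"
                    )
                arr = tf.pages[0].asarray()
        else:
            with Image.open(path) as im:
                if getattr(im, "n_frames", 1) != 1:
                    raise ValueError(f"multi-frame image is ambiguous: {path}")
                arr = np.asarray(im)
    except ValueError:
        raise
    except Exception as exc:  # unreadable / truncated file
        raise IOError(f"could not read image {path}: {exc}") from exc
    return np.asarray(arr)


def read_angiogram(image_path: str | Path, metadata: ScanMetadata) -> AngiogramImage:
    """Read an exported angiogram and coerce it to 8-bit.

    16-bit inputs are min–max scaled over their occupied range; RGB inputs
    are converted to luminance (see :func:`fazkit.script_segmenter.to_8bit`).
    """
    from .script_segmenter import to_8bit

    arr = read_image_array(image_path)
    return AngiogramImage(pixels=to_8bit(arr), metadata=metadata)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-channel TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask.pixels)
    else:
        Image.fromarray(mask.pixels, mode="L").save(path)


def read_mask(path: str | Path) -> BinaryMask:
    arr = read_image_array(path)
    return BinaryMask(arr)


# ---------------------------------------------------------------------------
# quality filter


def filter_quality(
    records: Sequence, min_quality_exclusive: int = QUALITY_INDEX_CUTOFF
) -> tuple[list, list]:
    """Partition scan records into (kept, excluded) by quality index.

    A record is kept iff its quality index is *strictly above*
    ``min_quality_exclusive`` (default 15, i.e. quality ≤ 15 excluded).
    Records may be ``ScanMetadata`` or ``(ScanMetadata, payload)`` tuples;
    input order is preserved within each output list.
    """
    kept: list = []
    excluded: list = []
    for rec in records:
        meta = rec[0] if isinstance(rec, tuple) else rec
        (kept if meta.quality_index > min_quality_exclusive else excluded).append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# measurement tables


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a measurement table as RFC-4180 CSV at full float precision."""
    # default float formatting is shortest-round-trip, so areas survive exactly
    table.records.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements(path: str | Path) -> MeasurementTable:
    df = pd.read_csv(path, dtype={"subject_id": str, "eye": str, "plexus": str, "method": str},
                     float_precision="round_trip")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV {path} missing columns {sorted(missing)}")
    return MeasurementTable(df)


# ---------------------------------------------------------------------------
# metadata sidecar

METADATA_COLUMNS = [
    "file",
    "subject_id",
    "eye",
    "visit",
    "plexus",
    "axial_length_mm",
    "quality_index",
]


def read_metadata_csv(path: str | Path) -> dict[str, ScanMetadata]:
    """Read the per-scan metadata sidecar, keyed by image file name.

    Rows whose fields violate the metadata invariants (e.g. axial length
    outside (15, 40) mm) are rejected with an error naming the row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "eye": str, "plexus": str},
                     float_precision="round_trip")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV {path} missing columns {sorted(missing)}")
    out: dict[str, ScanMetadata] = {}
    for i, row in df.iterrows():
        try:
            meta = ScanMetadata(
                subject_id=str(row["subject_id"]),
                eye=str(row["eye"]),
                visit=int(row["visit"]),
                plexus=str(row["plexus"]),
                axial_length_mm=float(row["axial_length_mm"]),
                quality_index=int(row["quality_index"]),
            )
        except ValueError as exc:
            raise ValueError(f"metadata CSV {path}, row {i} ({row['file']}): {exc}") from exc
        out[str(row["file"])] = meta
    return out


def write_metadata_csv(entries: dict[str, ScanMetadata], path: str | Path) -> None:
    rows = [
        {
            "file": fname,
            "subject_id": m.subject_id,
            "eye": m.eye,
            "visit": m.visit,
            "plexus": m.plexus,
            "axial_length_mm": m.axial_length_mm,
            "quality_index": m.quality_index,
        }
        for fname, m in entries.items()
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[TrainingAnnotation]:
    """Read classifier training annotations from a JSON file.

    Expected format: a JSON array of objects
    ``{"image_id": str, "label": "vascular"|"avascular", "points": [[x, y], ...]}``.
    """
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed annotation JSON {path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(raw, list):
        raise ValueError(f"annotation JSON {path} must be a top-level array")
    out = []
    for i, item in enumerate(raw):
        try:
            out.append(
                TrainingAnnotation(
                    polyline=tuple((float(x), float(y)) for x, y in item["points"]),
                    label=item["label"],
                    source_image_id=str(item["image_id"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"annotation JSON {path}, entry {i}: missing/invalid field: {exc}") from exc
    return out


def write_annotations(annotations: Iterable[TrainingAnnotation], path: str | Path) -> None:
    payload = [
        {
            "image_id": a.source_image_id,
            "label": a.label,
            "points": [[x, y] for x, y in a.polyline],
        }
        for a in annotations
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
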