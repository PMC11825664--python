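"""Image, annotation, and report I/O plus canonical preprocessing.

Every downstream metric assumes images on a canonical square grid with
intensities in [0, 1]. This module owns that contract: it reads PNG and
NIfTI slices, normalizes each image to its 98th intensity percentile,
zero-pads to square, and resamples to the canonical resolution
(128 x 128 by default) with bilinear interpolation.

Conventions
-----------
* Pixels are indexed row-major as (y, x); boxes are 0-based, half-open
  (``x_max``/``y_max`` exclusive), so a box's pixel count is exactly
  ``(x_max - x_min) * (y_max - y_min)``.
* Binary masks are uint8 arrays holding strictly {0, 1}; 1 marks an
  anomalous pixel.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

from .errors import (
    ContractError,
    DataError,
    DegenerateInputError,
    FormatError,
    UsageError,
)

CANONICAL_SIZE = 128
NORMALIZATION_PERCENTILE = 98.0

_PNG_SUFFIXES = {".png"}
_NIFTI_SUFFIXES = {".nii", ".nii.gz"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageSample:
    """One 2-D grayscale image with an identifier.

    ``pixels`` is a float64 (H, W) array. Raw (just-loaded) samples may hold
    any finite non-negative range; after :func:`preprocess` intensities lie
    in [0, 1] on the canonical grid.
    """

    id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ContractError(
                f"image {self.id!r}: expected a non-empty 2-D array, "
                f"got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ContractError(f"image {self.id!r}: non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box, 0-based, half-open on both axes."""

    label: str
    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise DataError(f"box {self} has non-positive area")

    @property
    def area(self) -> int:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the box's pixels."""
        return slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)

    def validate_against(self, shape: tuple[int, int], image_id: str = "?") -> None:
        h, w = shape
        if self.x_min < 0 or self.y_min < 0 or self.x_max > w or self.y_max > h:
            raise DataError(
                f"box {self} for image {image_id!r} lies outside the "
                f"{h}x{w} grid"
            )


@dataclass
class AnnotationSet:
    """Per-image ground-truth annotations: binary masks and/or boxes."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    boxes: dict[str, list[Box]] = field(default_factory=dict)
    brain_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for store in (self.masks, self.brain_masks):
            for key, mask in store.items():
                store[key] = _check_binary(mask, key)

    def validate_against(self, shapes: Mapping[str, tuple[int, int]]) -> None:
        """Check masks and boxes against the per-image grids."""
        for image_id, mask in self.masks.items():
            if image_id in shapes and mask.shape != shapes[image_id]:
                raise DataError(
                    f"mask for {image_id!r} has shape {mask.shape}, "
                    f"image grid is {shapes[image_id]}"
                )
        for image_id, box_list in self.boxes.items():
            if image_id in shapes:
                for box in box_list:
                    box.validate_against(shapes[image_id], image_id)


@dataclass
class DatasetBundle:
    """The four evaluation sets and their pairings.

    * ``healthy_ref``       -- healthy reference set (the normative anchor)
    * ``unseen_healthy``    -- (input, restoration) pairs of held-out healthy
                               images; restoration may be None until a
                               restorer has been applied
    * ``pathological``      -- pathological inputs
    * ``restored_pathological`` -- their restorations, paired by id
    * ``annotations``       -- masks/boxes over the pathological ids
    """

    healthy_ref: list[ImageSample]
    unseen_healthy: list[tuple[ImageSample, ImageSample | None]]
    pathological: list[ImageSample]
    restored_pathological: list[ImageSample]
    annotations: AnnotationSet | None = None
    # Populated by the synthetic generator so an oracle restorer can rebuild
    # each phantom without its lesion; absent for bundles loaded from disk.
    phantom_specs: dict[str, object] | None = None

    def validate(self) -> None:
        p_ids = [s.id for s in self.pathological]
        rp_ids = [s.id for s in self.restored_pathological]
        if self.restored_pathological and sorted(p_ids) != sorted(rp_ids):
            raise DataError(
                "pathological and restored_pathological id sets differ: "
                f"{sorted(set(p_ids) ^ set(rp_ids))}"
            )
        for inp, rest in self.unseen_healthy:
            if rest is not None:
                if inp.id != rest.id:
                    raise DataError(
                        f"unseen-healthy pair ids differ: {inp.id!r} vs {rest.id!r}"
                    )
                if inp.shape != rest.shape:
                    raise DataError(
                        f"unseen-healthy pair {inp.id!r} shapes differ: "
                        f"{inp.shape} vs {rest.shape}"
                    )

    def pathological_pairs(self) -> list[tuple[ImageSample, ImageSample]]:
        by_id = {s.id: s for s in self.restored_pathological}
        missing = [s.id for s in self.pathological if s.id not in by_id]
        if missing:
            raise DataError(f"no restoration for pathological ids {missing}")
        return [(s, by_id[s.id]) for s in self.pathological]


@dataclass
class MetricReport:
    """Full evaluation output: headline metrics, detection tables,
    ceiling-Dice per stratum, and an echo of the configuration used."""

    rqi: float | None = None
    ahi: float | None = None
    caci: float | None = None
    fused: float | None = None
    fid_components: dict[str, float] = field(default_factory=dict)
    caci_excluded_empty_masks: int = 0
    per_class_detection: dict[str, dict[str, float]] = field(default_factory=dict)
    overall_detection: dict[str, float] = field(default_factory=dict)
    ceiling_dice: dict[str, dict[str, float]] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rqi": self.rqi,
            "ahi": self.ahi,
            "caci": self.caci,
            "fused": self.fused,
            "fid_components": dict(self.fid_components),
            "caci_excluded_empty_masks": self.caci_excluded_empty_masks,
            "per_class_detection": {
                k: dict(v) for k, v in self.per_class_detection.items()
            },
            "overall_detection": dict(self.overall_detection),
            "ceiling_dice": {k: dict(v) for k, v in self.ceiling_dice.items()},
            "config_echo": dict(self.config_echo),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetricReport":
        return cls(
            rqi=d.get("rqi"),
            ahi=d.get("ahi"),
            caci=d.get("caci"),
            fused=d.get("fused"),
            fid_components=dict(d.get("fid_components", {})),
            caci_excluded_empty_masks=int(d.get("caci_excluded_empty_masks", 0)),
            per_class_detection={
                k: dict(v) for k, v in d.get("per_class_detection", {}).items()
            },
            overall_detection=dict(d.get("overall_detection", {})),
            ceiling_dice={k: dict(v) for k, v in d.get("ceiling_dice", {}).items()},
            config_echo=dict(d.get("config_echo", {})),
        )


# ---------------------------------------------------------------------------
# image loading / saving
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if path.suffix.lower() in _PNG_SUFFIXES:
        return "png"
    raise UsageError(f"cannot infer image format from {path}")


def load_image(
    path: str | Path,
    format: str | None = None,
    slice_index: int | None = None,
    id: str | None = None,
) -> ImageSample:
    """Read a raw (un-preprocessed) image from PNG or NIfTI.

    Multi-channel PNGs are reduced to grayscale by the unweighted mean of
    the color channels (alpha is ignored). 3-D NIfTI volumes require an
    explicit ``slice_index`` along the last axis.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    fmt = format or _infer_format(path)
    image_id = id if id is not None else path.name.split(".")[0]

    if fmt == "png":
        try:
            with Image.open(path) as im:
                arr = np.asarray(im, dtype=np.float64)
        except Exception as exc:  # pragma: no cover - PIL error text varies
            raise DataError(f"cannot read PNG {path}: {exc}") from exc
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=2)
        return ImageSample(id=image_id, pixels=arr)

    if fmt == "nifti":
        import nibabel as nib

        try:
            vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
        except Exception as exc:
            raise DataError(f"cannot read NIfTI {path}: {exc}") from exc
        vol = np.squeeze(vol)
        if vol.ndim == 2:
            return ImageSample(id=image_id, pixels=vol)
        if vol.ndim == 3:
            if slice_index is None:
                raise UsageError(
                    f"{path} is a 3-D volume; pass slice_index to select a slice"
                )
            if not 0 <= slice_index < vol.shape[2]:
                raise UsageError(
                    f"slice_index {slice_index} out of range for {vol.shape}"
                )
            return ImageSample(id=image_id, pixels=vol[:, :, slice_index])
        raise DataError(f"{path}: unsupported NIfTI dimensionality {vol.ndim}")

    raise UsageError(f"unknown image format {fmt!r}")


def save_image_png(image: ImageSample, path: str | Path) -> None:
    """Write a [0, 1] image as 16-bit grayscale PNG."""
    path = Path(path)
    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(path)


def load_images_dir(
    directory: str | Path, preprocess_images: bool = True
) -> list[ImageSample]:
    """Load every PNG/NIfTI in a directory, sorted by id."""
    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"not a directory: {directory}")
    samples = []
    for p in sorted(directory.iterdir()):
        n = p.name.lower()
        if p.suffix.lower() in _PNG_SUFFIXES or n.endswith((".nii", ".nii.gz")):
            img = load_image(p)
            samples.append(preprocess(img) if preprocess_images else img)
    if not samples:
        raise DataError(f"no images found in {directory}")
    return samples


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    image: ImageSample,
    percentile: float = NORMALIZATION_PERCENTILE,
    canonical_size: int = CANONICAL_SIZE,
) -> ImageSample:
    """Normalize, pad to square, and resample to the canonical grid.

    Intensities are divided by the given percentile of the image's own
    intensity distribution (linear interpolation between order statistics,
    over all pixels) and clipped to [0, 1]; the pixel sitting exactly at
    that percentile maps to 1.0. The image is then zero-padded to a
    centered square and resampled to ``canonical_size`` squared with plain
    bilinear interpolation (no anti-alias prefilter, for determinism).
    """
    if not 0 < percentile <= 100:
        raise UsageError(f"percentile must be in (0, 100], got {percentile}")
    if canonical_size < 1:
        raise UsageError(f"canonical_size must be positive, got {canonical_size}")

    ref = float(np.percentile(image.pixels, percentile))
    if ref <= 0:
        raise DegenerateInputError(
            f"image {image.id!r}: {percentile}th-percentile intensity is "
            f"{ref}; cannot normalize"
        )
    arr = np.clip(image.pixels / ref, 0.0, 1.0)

    h, w = arr.shape
    side = max(h, w)
    if h != side or w != side:
        top = (side - h) // 2
        left = (side - w) // 2
        padded = np.zeros((side, side), dtype=np.float64)
        padded[top : top + h, left : left + w] = arr
        arr = padded

    if arr.shape != (canonical_size, canonical_size):
        from skimage.transform import resize

        arr = resize(
            arr,
            (canonical_size, canonical_size),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
            clip=True,
        )
        arr = np.clip(arr, 0.0, 1.0)

    return ImageSample(id=image.id, pixels=arr)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _check_binary(mask: np.ndarray, image_id: str) -> np.ndarray:
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, 1))):
        raise FormatError(
            f"mask for {image_id!r} is not binary after binarization: "
            f"values {values[:8]}"
        )
    return mask.astype(np.uint8)


def binarize_mask_array(
    arr: np.ndarray, image_id: str, tolerance: float = 0.5
) -> np.ndarray:
    """Binarize a raw mask array at 0.5 of its nominal intensity range.

    ``tolerance`` (on the [0, 1] scale) bounds how far raw values may sit
    from {0, 1}; the default 0.5 accepts any value and thresholds it, while
    a stricter tolerance turns in-between values into a format error.
    """
    arr = np.asarray(arr, dtype=np.float64)
    top = float(arr.max())
    if top > 1.0:  # integer-coded mask (e.g. 0/255 PNG)
        arr = arr / (65535.0 if top > 255 else 255.0)
    if tolerance < 0.5:
        bad = (arr > tolerance) & (arr < 1.0 - tolerance)
        if np.any(bad):
            raise FormatError(
                f"mask for {image_id!r} has {int(bad.sum())} values outside "
                f"{{0, 1}} beyond tolerance {tolerance}"
            )
    return (arr >= 0.5).astype(np.uint8)


def load_mask(path: str | Path, tolerance: float = 0.5) -> np.ndarray:
    path = Path(path)
    img = load_image(path)
    return binarize_mask_array(img.pixels, img.id, tolerance=tolerance)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).save(Path(path))


def load_boxes_json(path: str | Path) -> dict[str, list[Box]]:
    """Read boxes as {"image_id": [{"label", "x_min", "y_min", "x_max",
    "y_max"}, ...], ...}."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse box JSON {path}: {exc}") from exc
    boxes: dict[str, list[Box]] = {}
    for image_id, entries in raw.items():
        if not isinstance(entries, list):
            raise FormatError(f"{path}: entry for {image_id!r} is not a list")
        parsed = []
        for e in entries:
            try:
                parsed.append(
                    Box(
                        label=str(e["label"]),
                        x_min=int(e["x_min"]),
                        y_min=int(e["y_min"]),
                        x_max=int(e["x_max"]),
                        y_max=int(e["y_max"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: malformed box for {image_id!r}: {e}"
                ) from exc
        boxes[image_id] = parsed
    return boxes


def save_boxes_json(boxes: Mapping[str, Sequence[Box]], path: str | Path) -> None:
    payload = {
        image_id: [
            {
                "label": b.label,
                "x_min": b.x_min,
                "y_min": b.y_min,
                "x_max": b.x_max,
                "y_max": b.y_max,
            }
            for b in entry
        ]
        for image_id, entry in boxes.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_annotations(
    mask_dir: str | Path | None = None,
    box_file: str | Path | None = None,
    brain_mask_dir: str | Path | None = None,
    image_shapes: Mapping[str, tuple[int, int]] | None = None,
    mask_tolerance: float = 0.5,
) -> AnnotationSet:
    """Load masks and/or boxes into one annotation set.

    At least one of ``mask_dir`` / ``box_file`` is required. When
    ``image_shapes`` is given, every annotation is validated against its
    image grid.
    """
    if mask_dir is None and box_file is None:
        raise UsageError("load_annotations needs mask_dir and/or box_file")

    masks: dict[str, np.ndarray] = {}
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        if not mask_dir.is_dir():
            raise DataError(f"mask directory not found: {mask_dir}")
        for p in sorted(mask_dir.iterdir()):
            n = p.name.lower()
            if p.suffix.lower() in _PNG_SUFFIXES or n.endswith((".nii", ".nii.gz")):
                masks[p.name.split(".")[0]] = load_mask(p, tolerance=mask_tolerance)

    boxes = load_boxes_json(box_file) if box_file is not None else {}

    brain_masks: dict[str, np.ndarray] = {}
    if brain_mask_dir is not None:
        brain_mask_dir = Path(brain_mask_dir)
        for p in sorted(brain_mask_dir.iterdir()):
            if p.suffix.lower() in _PNG_SUFFIXES:
                brain_masks[p.name.split(".")[0]] = load_mask(p)

    annotations = AnnotationSet(masks=masks, boxes=boxes, brain_masks=brain_masks)
    if image_shapes is not None:
        annotations.validate_against(image_shapes)
    return annotations


def resample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample of a binary mask to a new grid."""
    if mask.shape == shape:
        return mask.astype(np.uint8)
    from skimage.transform import resize

    out = resize(
        mask.astype(np.float64),
        shape,
        order=0,
        anti_aliasing=False,
        preserve_range=True,
    )
    return (out >= 0.5).astype(np.uint8)


def scale_box(
    box: Box, from_shape: tuple[int, int], to_shape: tuple[int, int]
) -> Box:
    """Scale a box between grids, rounding outward so it never shrinks."""
    sy = to_shape[0] / from_shape[0]
    sx = to_shape[1] / from_shape[1]
    return Box(
        label=box.label,
        x_min=int(math.floor(box.x_min * sx)),
        y_min=int(math.floor(box.y_min * sy)),
        x_max=min(int(math.ceil(box.x_max * sx)), to_shape[1]),
        y_max=min(int(math.ceil(box.y_max * sy)), to_shape[0]),
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def flatten_report(report: MetricReport) -> list[dict[str, object]]:
    """One row per metric/class/stratum scalar, for the CSV form."""
    rows: list[dict[str, object]] = []

    def add(metric: str, group: str, field_name: str, value) -> None:
        if value is None:
            return
        if isinstance(value, (bool, np.bool_)):
            value = int(value)  # keep the CSV numeric
        rows.append(
            {"metric": metric, "group": group, "field": field_name, "value": value}
        )

    add("rqi", "", "value", report.rqi)
    add("ahi", "", "value", report.ahi)
    add("caci", "", "value", report.caci)
    add("fused", "", "value", report.fused)
    for k, v in report.fid_components.items():
        add("fid", "", k, v)
    add("caci", "", "excluded_empty_masks", report.caci_excluded_empty_masks)
    for label, stats in report.per_class_detection.items():
        for k, v in stats.items():
            add("detection", label, k, v)
    for k, v in report.overall_detection.items():
        add("detection", "__overall__", k, v)
    for stratum, stats in report.ceiling_dice.items():
        for k, v in stats.items():
            add("ceiling_dice", stratum, k, v)
    return rows


def write_report(
    report: MetricReport, path: str | Path, format: str = "json"
) -> None:
    """Serialize a report as nested JSON or flat CSV."""
    path = Path(path)
    if format == "json":
        try:
            path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        except OSError as exc:
            raise DataError(f"cannot write report to {path}: {exc}") from exc
    elif format == "csv":
        rows = flatten_report(report)
        try:
            with open(path, "w", newline="") as fh:
                writer = csv.DictWriter(
                    fh, fieldnames=["metric", "group", "field", "value"]
                )
                writer.writeheader()
                writer.writerows(rows)
        except OSError as exc:
            raise DataError(f"cannot write report to {path}: {exc}") from exc
    else:
        raise UsageError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> MetricReport:
    """Read back a JSON report."""
    return MetricReport.from_dict(json.loads(Path(path).read_text()))


def read_report_csv(path: str | Path) -> list[dict[str, object]]:
    """Read back the flat CSV rows (values as floats where possible)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                row["value"] = float(row["value"])  # type: ignore[arg-type]
            except (TypeError, ValueError):
                pass
            rows.append(dict(row))
    return rows
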