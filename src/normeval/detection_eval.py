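"""Anomaly maps and the detection protocol: box-level F1, ceiling Dice via
threshold search, and lesion-size stratification.

Protocol summary
----------------
* A per-pixel anomaly map S(x) is the absolute residual |x - x_restored|
  (precomputed maps may be supplied instead).
* For box annotations: binarize the map, and call a box *detected* (TP = 1)
  when at least ``min_overlap`` (default 10%) of its pixels are flagged.
  The false-positive ratio FP is flagged healthy-tissue pixels (outside all
  boxes, optionally restricted to a brain mask) divided by correctly
  flagged pixels inside the box. Per-box precision P = TP / (TP + FP) and
  the per-case score 2 P TP / (P + TP) are averaged into the dataset F1.
* For mask annotations: ceiling Dice -- the best pooled Dice over a single
  global threshold searched greedily on the test set, an upper bound on
  what any threshold rule could segment -- reported per lesion-size stratum
  (small/medium/large by the 25th/75th percentile of lesion pixel counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ContractError, DataError, UsageError
from .image_io import Box, ImageSample

MIN_OVERLAP_DEFAULT = 0.10
STRATA = ("small", "medium", "large", "all")
#: lesion pixel-count cut points reported for the stroke-lesion benchmark
ATLAS_SIZE_CUTS = (71, 570)


@dataclass
class AnomalyMap:
    """Per-pixel non-negative anomaly scores for one image."""

    id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ContractError(f"anomaly map {self.id!r} must be 2-D")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ContractError(
                f"anomaly map {self.id!r} must be finite and non-negative"
            )


@dataclass
class BoxResult:
    """Outcome for a single annotated box."""

    label: str
    detected: bool
    overlap_fraction: float
    fp_ratio: float | None  # None when undefined (nothing flagged inside)
    precision: float
    f1_case: float


@dataclass
class DetectionCase:
    """Per-image detection outcome, one entry per annotated box."""

    id: str
    boxes: list[BoxResult] = field(default_factory=list)


@dataclass
class DiceResult:
    """Best-threshold Dice for one lesion-size stratum."""

    stratum: str
    dice: float
    threshold: float
    n_cases: int
    dice_mean_case: float  # mean of per-case Dice at the same threshold
    degenerate: bool = False  # constant scores: threshold search vacuous


# ---------------------------------------------------------------------------
# anomaly maps and image-level scores
# ---------------------------------------------------------------------------

def anomaly_map(
    x: ImageSample, x_restored: ImageSample, method: str = "abs_residual"
) -> AnomalyMap:
    """Pixel-wise anomaly scores from an (input, restoration) pair."""
    if method != "abs_residual":
        raise UsageError(f"unknown anomaly-map method {method!r}")
    if x.shape != x_restored.shape:
        raise ContractError(
            f"anomaly_map: shapes differ {x.shape} vs {x_restored.shape}"
        )
    return AnomalyMap(id=x.id, scores=np.abs(x.pixels - x_restored.pixels))


def image_score(map_: AnomalyMap, mode: Literal["max", "mean"] = "max") -> float:
    """Summarize a map into one image-level anomaly score."""
    if mode == "max":
        return float(map_.scores.max())
    if mode == "mean":
        return float(map_.scores.mean())
    raise UsageError(f"unknown image_score mode {mode!r}")


def binarize(
    map_: AnomalyMap,
    strategy: str = "healthy_quantile",
    threshold: float | None = None,
    quantile: float = 0.95,
    reference_maps: Sequence[AnomalyMap] | None = None,
) -> np.ndarray:
    """Flag pixels whose score strictly exceeds a threshold.

    ``fixed`` uses the given ``threshold``; ``healthy_quantile`` sets the
    threshold to the q-quantile of the pooled scores of healthy-reference
    maps (the package default: a threshold derived from normative data).
    """
    t = resolve_threshold(strategy, threshold, quantile, reference_maps)
    return (map_.scores > t).astype(np.uint8)


def resolve_threshold(
    strategy: str,
    threshold: float | None = None,
    quantile: float = 0.95,
    reference_maps: Sequence[AnomalyMap] | None = None,
) -> float:
    if strategy == "fixed":
        if threshold is None or threshold < 0:
            raise UsageError("fixed binarization needs a threshold >= 0")
        return float(threshold)
    if strategy == "healthy_quantile":
        if not 0 < quantile < 1:
            raise UsageError(f"quantile must be in (0, 1), got {quantile}")
        if not reference_maps:
            raise UsageError(
                "healthy_quantile binarization needs non-empty reference maps"
            )
        pooled = np.concatenate([m.scores.ravel() for m in reference_maps])
        return float(np.quantile(pooled, quantile))
    raise UsageError(f"unknown binarization strategy {strategy!r}")


# ---------------------------------------------------------------------------
# box-based detection (F1 protocol)
# ---------------------------------------------------------------------------

def evaluate_case(
    binary: np.ndarray,
    boxes: Sequence[Box],
    brain_mask: np.ndarray | None = None,
    min_overlap: float = MIN_OVERLAP_DEFAULT,
    case_id: str = "?",
) -> DetectionCase:
    """Score one image's flagged-pixel mask against its annotated boxes.

    Each box is scored independently: it is detected when at least
    ``min_overlap`` of its pixels are flagged; its FP ratio counts flagged
    pixels outside ALL boxes (within the brain mask if given) relative to
    flagged pixels inside the box.
    """
    if not 0 < min_overlap <= 1:
        raise UsageError(f"min_overlap must be in (0, 1], got {min_overlap}")
    if len(boxes) == 0:
        raise UsageError(f"evaluate_case: no boxes for case {case_id!r}")
    binary = np.asarray(binary).astype(bool)

    inside_any = np.zeros_like(binary)
    for box in boxes:
        box.validate_against(binary.shape, case_id)
        inside_any[box.slices] = True
    outside = binary & ~inside_any
    if brain_mask is not None:
        outside &= np.asarray(brain_mask).astype(bool)
    n_outside = int(outside.sum())

    results = []
    for box in boxes:
        n_inside = int(binary[box.slices].sum())
        overlap = n_inside / box.area
        detected = overlap >= min_overlap
        if n_inside > 0:
            fp_ratio: float | None = n_outside / n_inside
        else:
            fp_ratio = None  # undefined; the box cannot be detected anyway
        if detected:
            # fp_ratio is defined here: detection needs >= min_overlap of a
            # positive-area box, hence n_inside >= 1.
            tp = 1.0
            precision = tp / (tp + fp_ratio)  # type: ignore[operator]
            f1_case = 2.0 * precision * tp / (precision + tp)
        else:
            precision = 0.0
            f1_case = 0.0
        results.append(
            BoxResult(
                label=box.label,
                detected=detected,
                overlap_fraction=overlap,
                fp_ratio=fp_ratio,
                precision=precision,
                f1_case=f1_case,
            )
        )
    return DetectionCase(id=case_id, boxes=results)


def dataset_f1(
    cases: Sequence[DetectionCase],
    class_vocabulary: Sequence[str] | None = None,
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Aggregate per-box scores into per-class and overall tables.

    Each annotated box is one case in the F1 average. Returns
    (per_class, overall) where each entry holds n_detected, n_total, f1.
    """
    all_boxes = [(c.id, b) for c in cases for b in c.boxes]
    if not all_boxes:
        raise UsageError("dataset_f1: no cases")
    labels = sorted({b.label for _, b in all_boxes})
    if class_vocabulary is not None:
        unknown = set(labels) - set(class_vocabulary)
        if unknown:
            raise DataError(f"dataset_f1: labels outside vocabulary: {sorted(unknown)}")
        labels = sorted(class_vocabulary)

    def summarize(items: list[BoxResult]) -> dict[str, float]:
        if not items:
            return {"n_detected": 0, "n_total": 0, "f1": float("nan")}
        return {
            "n_detected": int(sum(b.detected for b in items)),
            "n_total": len(items),
            "f1": float(np.mean([b.f1_case for b in items])),
        }

    per_class = {
        label: summarize([b for _, b in all_boxes if b.label == label])
        for label in labels
    }
    overall = summarize([b for _, b in all_boxes])
    return per_class, overall


# ---------------------------------------------------------------------------
# ceiling Dice
# ---------------------------------------------------------------------------

def _dice_candidates(
    pooled: np.ndarray, n_thresholds: int | Literal["exhaustive"]
) -> np.ndarray:
    if n_thresholds == "exhaustive":
        return np.unique(pooled)
    if not isinstance(n_thresholds, int) or n_thresholds < 1:
        raise UsageError(f"n_thresholds must be a positive int or 'exhaustive'")
    lo, hi = float(pooled.min()), float(pooled.max())
    return np.linspace(lo, hi, num=min(n_thresholds, max(1, len(np.unique(pooled)))))

def ceiling_dice_single(
    maps: Sequence[AnomalyMap],
    masks: Mapping[str, np.ndarray],
    n_thresholds: int | Literal["exhaustive"] = 100,
    stratum: str = "all",
) -> DiceResult:
    """Best single global threshold for one group of cases.

    A pixel is predicted anomalous when its score is >= the threshold (>=,
    not >, so the select-everything solution is in the search space).
    Candidates are the unique pooled scores (exhaustive) or ``n_thresholds``
    evenly spaced values over [min, max]. The headline Dice pools pixels
    over all cases; the mean of per-case Dice at the same threshold is
    reported alongside. Ties break toward the smaller threshold.
    """
    if len(maps) == 0:
        return DiceResult(stratum, float("nan"), float("nan"), 0, float("nan"),
                          degenerate=True)
    scores, gts = [], []
    for m in maps:
        if m.id not in masks:
            raise DataError(f"ceiling_dice: no mask for map id {m.id!r}")
        gt = np.asarray(masks[m.id]).astype(bool)
        if gt.shape != m.scores.shape:
            raise ContractError(
                f"ceiling_dice: mask/map shape mismatch for {m.id!r}"
            )
        scores.append(m.scores.ravel())
        gts.append(gt.ravel())
    score_mat = np.stack(scores)  # (cases, pixels)
    gt_mat = np.stack(gts)
    pooled = score_mat.ravel()
    degenerate = bool(pooled.max() == pooled.min())
    candidates = _dice_candidates(pooled, n_thresholds)

    n_gt = gt_mat.sum()
    n_gt_case = gt_mat.sum(axis=1)
    best = (-1.0, 0.0, 0.0)  # (dice, threshold, mean per-case dice)
    for t in candidates:
        pred = score_mat >= t
        inter_case = (pred & gt_mat).sum(axis=1)
        pred_case = pred.sum(axis=1)
        denom = pred_case + n_gt_case
        pooled_dice = (
            2.0 * inter_case.sum() / (pred_case.sum() + n_gt)
            if (pred_case.sum() + n_gt) > 0
            else 0.0
        )
        with np.errstate(invalid="ignore"):
            case_dice = np.where(denom > 0, 2.0 * inter_case / np.maximum(denom, 1), 1.0)
        mean_case = float(case_dice.mean())
        if pooled_dice > best[0]:
            best = (float(pooled_dice), float(t), mean_case)
    return DiceResult(
        stratum=stratum,
        dice=best[0],
        threshold=best[1],
        n_cases=len(maps),
        dice_mean_case=best[2],
        degenerate=degenerate,
    )


def stratify_lesions(
    masks: Mapping[str, np.ndarray],
    mode: Literal["quantile", "fixed"] = "quantile",
    cuts: tuple[float, float] | None = None,
) -> dict[str, str]:
    """Assign each case a size stratum from its lesion pixel count.

    quantile mode derives the cut points as the 25th/75th percentiles of
    the lesion sizes (linear interpolation); fixed mode uses the supplied
    (lo, hi). Boundary semantics: small when size < lo, large when
    size >= hi (and hi > lo), else medium -- so with the stroke-benchmark
    preset (71, 570), 70 px is small and 570 px is large. When all sizes
    coincide the quantile cut points collapse and every case is medium.
    """
    if not masks:
        raise UsageError("stratify_lesions: no masks")
    sizes = {k: int(np.asarray(m).astype(bool).sum()) for k, m in masks.items()}
    if mode == "fixed":
        if cuts is None:
            raise UsageError("fixed stratification needs cut points (lo, hi)")
        lo, hi = cuts
        if lo >= hi:
            raise UsageError(f"fixed cuts need lo < hi, got {cuts}")
    elif mode == "quantile":
        values = np.array(list(sizes.values()), dtype=np.float64)
        lo = float(np.percentile(values, 25))
        hi = float(np.percentile(values, 75))
    else:
        raise UsageError(f"unknown stratification mode {mode!r}")

    out = {}
    for k, size in sizes.items():
        if size < lo:
            out[k] = "small"
        elif size >= hi and hi > lo:
            out[k] = "large"
        else:
            out[k] = "medium"
    return out


def ceiling_dice(
    maps: Sequence[AnomalyMap],
    masks: Mapping[str, np.ndarray],
    n_thresholds: int | Literal["exhaustive"] = 100,
    strata: Mapping[str, str] | None = None,
) -> list[DiceResult]:
    """Ceiling Dice per lesion-size stratum plus the pooled 'all' group.

    ``strata`` maps case id -> stratum; when omitted it is derived from the
    masks with quantile cut points. Each stratum searches its own global
    threshold (the search is on the evaluated test set, so the result is a
    theoretical maximum, not an operating point).
    """
    if strata is None:
        strata = stratify_lesions(masks)
    results = []
    for stratum in STRATA:
        if stratum == "all":
            group = list(maps)
        else:
            group = [m for m in maps if strata.get(m.id) == stratum]
        results.append(
            ceiling_dice_single(group, masks, n_thresholds=n_thresholds,
                                stratum=stratum)
        )
    return results
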