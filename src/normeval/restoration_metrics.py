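"""Restoration-quality metrics: RQI, masked SSIM, CACI, and the fused score.

The three headline indices quantify complementary facets of a
pseudo-healthy restorer:

* **RQI** (restoration quality index): how faithfully the model restores
  *healthy* inputs it has never seen. Per pair, the perceptual distance d
  is mapped through ``1 - (d - min_lp) / (max_lp - min_lp)`` and averaged;
  distances are clipped into [min_lp, max_lp] (worst cases capped) so the
  index stays in [0, 1]. Defaults: min_lp = 0 (an identity restorer),
  max_lp = 25 (worst observed scale on the x100 perceptual convention).
* **CACI** (conservation and correction index): on pathological pairs with
  expert lesion masks, an SSIM map is averaged separately over healthy
  (mask == 0) and anomalous (mask == 1) pixels, and the two requirements --
  preserve healthy tissue (high SSIM_H) and change the lesion (large
  SSIM_H - SSIM_AN) -- are combined by a regularized harmonic mean.
* **fused**: harmonic mean of RQI and CACI, averaged with AHI (computed in
  :mod:`normeval.distribution_metrics`), damping the influence of
  near-zero AHI values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .errors import ContractError, DataError, UsageError
from .feature_backends import PerceptualDistanceBackend, perceptual_distance
from .image_io import ImageSample

DEFAULT_EPS = 1e-8
SSIM_WINDOW = 11
SSIM_SIGMA = 1.5


@dataclass(frozen=True)
class RQIConfig:
    """Normalization constants for the restoration quality index."""

    min_lp: float = 0.0
    max_lp: float = 25.0
    cap_at_max: bool = True

    def __post_init__(self) -> None:
        if self.max_lp <= self.min_lp:
            raise UsageError(
                f"max_lp ({self.max_lp}) must exceed min_lp ({self.min_lp})"
            )


@dataclass
class MaskedSSIMResult:
    """Region-wise SSIM map averages for one (input, restoration) pair."""

    ssim_healthy: float
    ssim_anomalous: float
    n_healthy_px: int
    n_anomalous_px: int
    degenerate: bool = False  # True when the anomaly mask is empty


def rqi(
    pairs: Sequence[tuple[ImageSample, ImageSample]],
    backend: PerceptualDistanceBackend,
    config: RQIConfig = RQIConfig(),
) -> float:
    """Restoration quality index over unseen-healthy (input, restoration)
    pairs. 1 means perceptually perfect restoration; 0 means at (or past)
    the worst-case distance ``max_lp``."""
    if len(pairs) == 0:
        raise UsageError("rqi: empty pair list")
    distances = np.array(
        [perceptual_distance(backend, x, xr) for x, xr in pairs], dtype=np.float64
    )
    return rqi_from_distances(distances, config)


def rqi_from_distances(
    distances: Sequence[float], config: RQIConfig = RQIConfig()
) -> float:
    """Apply the RQI normalization to precomputed perceptual distances."""
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise UsageError("rqi: empty distance list")
    if config.cap_at_max:
        d = np.clip(d, config.min_lp, config.max_lp)
    span = config.max_lp - config.min_lp
    return float(np.mean(1.0 - (d - config.min_lp) / span))


def ssim_map(x: ImageSample, x_restored: ImageSample) -> np.ndarray:
    """Full-image SSIM map: 11x11 Gaussian window, sigma 1.5, population
    covariance, data range 1.0 (canonical [0,1] images)."""
    if x.shape != x_restored.shape:
        raise ContractError(f"ssim_map: shapes differ {x.shape} vs {x_restored.shape}")
    _, smap = structural_similarity(
        x.pixels,
        x_restored.pixels,
        win_size=SSIM_WINDOW,
        gaussian_weights=True,
        sigma=SSIM_SIGMA,
        use_sample_covariance=False,
        data_range=1.0,
        full=True,
    )
    return smap


def masked_ssim(
    x: ImageSample, x_restored: ImageSample, mask: np.ndarray
) -> MaskedSSIMResult:
    """Average the SSIM map over healthy (mask==0) and anomalous (mask==1)
    pixels. Windows overlapping the region border contribute to both
    averages via their center pixel; this is deliberate and documented.

    An empty mask yields ``ssim_anomalous = 0`` with the degenerate flag
    set, since "similarity inside the lesion" is then undefined.
    """
    mask = np.asarray(mask)
    if mask.shape != x.shape:
        raise ContractError(
            f"masked_ssim: mask shape {mask.shape} != image shape {x.shape}"
        )
    smap = ssim_map(x, x_restored)
    anomalous = mask.astype(bool)
    n_an = int(anomalous.sum())
    n_h = int(anomalous.size - n_an)
    ssim_h = float(smap[~anomalous].mean()) if n_h else 0.0
    if n_an:
        return MaskedSSIMResult(ssim_h, float(smap[anomalous].mean()), n_h, n_an)
    return MaskedSSIMResult(ssim_h, 0.0, n_h, 0, degenerate=True)


def caci_pair(ssim_h: float, ssim_an: float, eps: float = DEFAULT_EPS) -> float:
    """Regularized harmonic mean of conservation (SSIM_H) and correction
    (SSIM_H - SSIM_AN) for one pair, clipped into [0, 1].

    SSIM can be negative; SSIM_H is clipped below at 0 before use, and the
    correction term is floored at 0 so restored lesions that stay identical
    (SSIM_AN >= SSIM_H) drive the index to ~0.
    """
    if eps <= 0:
        raise UsageError(f"caci: eps must be positive, got {eps}")
    sh = max(0.0, ssim_h)
    correction = max(0.0, sh - ssim_an)
    value = 2.0 / ((1.0 / (sh + eps)) + (1.0 / (correction + eps)))
    return float(min(1.0, max(0.0, value)))


def caci_detail(
    pairs: Sequence[tuple[ImageSample, ImageSample]],
    masks: Mapping[str, np.ndarray],
    eps: float = DEFAULT_EPS,
) -> tuple[float, list[MaskedSSIMResult], int]:
    """Dataset CACI with per-pair detail.

    Returns (mean CACI over non-degenerate pairs, per-pair masked-SSIM
    results, number of pairs excluded for empty masks). Pairs whose mask is
    empty are excluded from the average -- the correction term is undefined
    without anomalous pixels -- but counted for the report.
    """
    if len(pairs) == 0:
        raise UsageError("caci: empty pair list")
    results: list[MaskedSSIMResult] = []
    values: list[float] = []
    excluded = 0
    for x, x_restored in pairs:
        if x.id not in masks:
            raise DataError(f"caci: no anomaly mask for image id {x.id!r}")
        res = masked_ssim(x, x_restored, masks[x.id])
        results.append(res)
        if res.degenerate:
            excluded += 1
        else:
            values.append(caci_pair(res.ssim_healthy, res.ssim_anomalous, eps))
    if not values:
        raise DataError("caci: all masks empty; CACI undefined")
    return float(np.mean(values)), results, excluded


def caci(
    pairs: Sequence[tuple[ImageSample, ImageSample]],
    masks: Mapping[str, np.ndarray],
    eps: float = DEFAULT_EPS,
) -> float:
    """Dataset CACI: mean per-pair index over pathological pairs."""
    value, _, _ = caci_detail(pairs, masks, eps)
    return value


def fused_metric(rqi_value: float, ahi_value: float, caci_value: float) -> float:
    """Combine the three indices: harmonic mean of RQI and CACI, averaged
    with AHI. The harmonic term is defined as 0 when RQI + CACI == 0."""
    for name, v in (("rqi", rqi_value), ("ahi", ahi_value), ("caci", caci_value)):
        if not 0.0 <= v <= 1.0:
            raise UsageError(f"fused_metric: {name} = {v} outside [0, 1]")
    if rqi_value + caci_value == 0.0:
        harmonic = 0.0
    else:
        harmonic = 2.0 * rqi_value * caci_value / (rqi_value + caci_value)
    return (harmonic + ahi_value) / 2.0
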