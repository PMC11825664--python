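"""Frechet distance between embedded image sets and the anomaly-to-healthy
index (AHI).

The Frechet (2-Wasserstein) distance between Gaussians fit to the
embeddings of two image sets,

    d^2 = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}),

is the standard "FID" construction. AHI rescales the restored set's
distance to the healthy reference by two anchors: the unseen-healthy set
(the achievable floor -- even real healthy images have a positive
finite-sample distance) and the un-restored pathological set (the
no-improvement ceiling):

    AHI = max(0, 1 - max(0, FID_RP,H - FID_UH,H) / (FID_P,H - FID_UH,H + eps))

so 1 means the restorations are distributionally as close to healthy as
real healthy images, and 0 means no improvement over the pathology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError, NumericalError, UsageError
from .feature_backends import EmbeddingBackend, embed
from .image_io import DatasetBundle, ImageSample

DEFAULT_EPS = 1e-8
#: below this set size, production FID estimates are strongly biased
SMALL_SAMPLE_WARNING_N = 50


@dataclass
class GaussianMoments:
    """Sample mean and (unbiased) covariance of a set of embeddings."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        d = self.mean.shape[0]
        if self.covariance.shape != (d, d):
            raise ContractError(
                f"covariance shape {self.covariance.shape} does not match dim {d}"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ContractError("covariance is not symmetric (tolerance 1e-8)")
        if self.n < 2:
            raise UsageError(f"moments need n >= 2 samples, got {self.n}")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class AHIInputs:
    """The three Frechet distances entering the AHI formula."""

    fid_rp_h: float
    fid_uh_h: float
    fid_p_h: float
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        for name in ("fid_rp_h", "fid_uh_h", "fid_p_h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise UsageError(f"{name} must be finite and >= 0, got {v}")
        if self.eps <= 0:
            raise UsageError(f"eps must be positive, got {self.eps}")


def fit_moments(embeddings: np.ndarray) -> GaussianMoments:
    """Column means and unbiased (n-1) sample covariance of an (n, d)
    embedding matrix."""
    x = np.asarray(embeddings, dtype=np.float64)
    if x.ndim != 2:
        raise ContractError(f"expected an (n, d) matrix, got shape {x.shape}")
    n = x.shape[0]
    if n < 2:
        raise UsageError(f"fit_moments needs n >= 2 rows, got {n}")
    mean = x.mean(axis=0)
    cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    return GaussianMoments(mean=mean, covariance=cov, n=n)


def _psd_sqrt(matrix: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, negative
    eigenvalues clipped to 0."""
    w, v = np.linalg.eigh(matrix)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def frechet_distance(a: GaussianMoments, b: GaussianMoments) -> float:
    """Frechet distance between two Gaussians.

    The trace term Tr((S_a S_b)^{1/2}) is computed from the eigenvalues of
    the symmetrized congruence S_a^{1/2} S_b S_a^{1/2}, which is similar to
    S_a S_b but symmetric, so the whole computation stays in real
    arithmetic. Small negative eigenvalues (round-off) are clipped to 0; if
    the clipped mass exceeds 1e-3 of the spectrum a numerical error is
    raised rather than silently truncated.
    """
    if a.dim != b.dim:
        raise ContractError(f"dimension mismatch: {a.dim} vs {b.dim}")
    diff = a.mean - b.mean
    sqrt_a = _psd_sqrt(a.covariance)
    inner = sqrt_a @ b.covariance @ sqrt_a
    inner = (inner + inner.T) / 2.0
    w = np.linalg.eigvalsh(inner)
    neg = -w[w < 0].sum()
    total = np.abs(w).sum()
    if total > 0 and neg / total > 1e-3:
        raise NumericalError(
            f"frechet_distance: negative eigenvalue mass {neg:.3e} exceeds "
            f"1e-3 of spectrum {total:.3e}"
        )
    tr_sqrt = np.sqrt(np.clip(w, 0.0, None)).sum()
    value = float(
        diff @ diff
        + np.trace(a.covariance)
        + np.trace(b.covariance)
        - 2.0 * tr_sqrt
    )
    if not np.isfinite(value):
        raise NumericalError("frechet_distance: non-finite result")
    return max(0.0, value)  # clip round-off below zero


def frechet_from_embeddings(emb_a: np.ndarray, emb_b: np.ndarray) -> float:
    return frechet_distance(fit_moments(emb_a), fit_moments(emb_b))


def ahi(inputs: AHIInputs) -> float:
    """Anomaly-to-healthy index from precomputed Frechet distances.

    Clamped into [0, 1]: the upper clamp only matters in the degenerate
    regime FID_P,H < FID_UH,H (pathology closer to the reference than real
    healthy images), where the normalization loses meaning.
    """
    numerator = max(0.0, inputs.fid_rp_h - inputs.fid_uh_h)
    denominator = inputs.fid_p_h - inputs.fid_uh_h + inputs.eps
    return float(min(1.0, max(0.0, 1.0 - numerator / denominator)))


def ahi_from_bundle(
    bundle: DatasetBundle,
    backend: EmbeddingBackend,
    eps: float = DEFAULT_EPS,
) -> tuple[float, AHIInputs]:
    """Embed the four sets, compute the three anchor distances against the
    healthy reference, and return (AHI, components).

    The unseen-healthy anchor uses the ORIGINAL unseen-healthy inputs, not
    their restorations: it stands for the floor a perfect restorer could
    reach, which is what real healthy images score.
    """
    sets: dict[str, Sequence[ImageSample]] = {
        "healthy_ref": bundle.healthy_ref,
        "unseen_healthy": [inp for inp, _ in bundle.unseen_healthy],
        "pathological": bundle.pathological,
        "restored_pathological": bundle.restored_pathological,
    }
    for name, images in sets.items():
        if len(images) < 2:
            raise UsageError(
                f"ahi_from_bundle: set {name!r} has {len(images)} images; "
                "the Frechet distance needs n >= 2"
            )
    moments = {
        name: fit_moments(embed(backend, images)) for name, images in sets.items()
    }
    inputs = AHIInputs(
        fid_rp_h=frechet_distance(
            moments["restored_pathological"], moments["healthy_ref"]
        ),
        fid_uh_h=frechet_distance(moments["unseen_healthy"], moments["healthy_ref"]),
        fid_p_h=frechet_distance(moments["pathological"], moments["healthy_ref"]),
        eps=eps,
    )
    return ahi(inputs), inputs
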