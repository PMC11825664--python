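"""Pluggable feature backends for the perceptual and distributional metrics.

Two contracts are defined:

* :class:`PerceptualDistanceBackend` -- a symmetric, non-negative pairwise
  image distance with ``distance(a, a) == 0``, used by the restoration
  quality index. The production choice in the field is LPIPS; raw deep
  perceptual distances are typically below 1, so backends report
  ``raw distance x 100`` by default, which makes the conventional worst-case
  cap of 25 attainable. Both the x100 convention and the cap are plain
  numbers in the configuration, not baked in.
* :class:`EmbeddingBackend` -- a deterministic map from a canonical image to
  a fixed-length feature vector, used to fit Gaussians for the Frechet
  distance. The production convention is a 2048-dim classification-network
  pooling layer.

Deterministic "toy" backends ship with the package and need no model
weights: a blurred-L1 perceptual distance and a quadrant-statistics
embedder. They are pure functions of their inputs, which makes every metric
formula testable bit-for-bit. Deep backends (LPIPS, Inception-v3 pooling)
are thin wrappers that import torch lazily; install the ``deep`` extra to
use them.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError, UsageError
from .image_io import ImageSample

DEFAULT_SCALE_MAX = 25.0
PERCEPTUAL_SCALE_FACTOR = 100.0


class PerceptualDistanceBackend(ABC):
    """Contract for pairwise perceptual image distances."""

    name: str = "abstract"
    #: distance value treated as "worst case" when normalizing to [0, 1]
    scale_max: float = DEFAULT_SCALE_MAX

    @abstractmethod
    def distance(self, a: ImageSample, b: ImageSample) -> float:
        """Symmetric non-negative distance between two canonical images."""


class EmbeddingBackend(ABC):
    """Contract for fixed-dimension image embeddings."""

    name: str = "abstract"
    dim: int = 0

    @abstractmethod
    def embed_one(self, image: ImageSample) -> np.ndarray:
        """Embed one image into a length-``dim`` finite real vector."""


def perceptual_distance(
    backend: PerceptualDistanceBackend, a: ImageSample, b: ImageSample
) -> float:
    """Apply a backend with the shared shape contract enforced."""
    if a.shape != b.shape:
        raise ContractError(
            f"perceptual_distance: shapes differ {a.shape} vs {b.shape}"
        )
    return float(backend.distance(a, b))


def embed(backend: EmbeddingBackend, images: Sequence[ImageSample]) -> np.ndarray:
    """Embed a list of images into an (n, dim) matrix, row i = image i."""
    if len(images) == 0:
        raise UsageError("embed: empty image list")
    rows = np.stack([np.asarray(backend.embed_one(img), dtype=np.float64)
                     for img in images])
    if rows.shape != (len(images), backend.dim):
        raise ContractError(
            f"backend {backend.name!r} produced shape {rows.shape}, "
            f"expected ({len(images)}, {backend.dim})"
        )
    if not np.all(np.isfinite(rows)):
        raise ContractError(f"backend {backend.name!r} produced non-finite values")
    return rows


# ---------------------------------------------------------------------------
# toy backends (no downloads, bitwise deterministic)
# ---------------------------------------------------------------------------

class BlurredL1Distance(PerceptualDistanceBackend):
    """Mean absolute difference of Gaussian-blurred images, x100.

    The blur (sigma in pixels) makes the distance insensitive to pixel
    noise, mimicking the low-frequency bias of perceptual metrics while
    staying a closed-form function of the inputs.
    """

    def __init__(self, sigma: float = 1.0, scale_max: float = DEFAULT_SCALE_MAX):
        self.sigma = float(sigma)
        self.scale_max = float(scale_max)
        self.name = f"toy-blur-l1(sigma={self.sigma})"

    def distance(self, a: ImageSample, b: ImageSample) -> float:
        fa = gaussian_filter(a.pixels, self.sigma)
        fb = gaussian_filter(b.pixels, self.sigma)
        return float(np.mean(np.abs(fa - fb)) * PERCEPTUAL_SCALE_FACTOR)


class QuadrantStatsEmbedder(EmbeddingBackend):
    """Per-quadrant (2x2 split) mean, variance, and gradient energy.

    dim = 4 quadrants x 3 statistics = 12. Gradient energy is the mean of
    squared central-difference gradients, a cheap sharpness proxy that
    separates blurred restorations from crisp ones.
    """

    dim = 12

    def __init__(self) -> None:
        self.name = "toy-quadrant-stats"

    def embed_one(self, image: ImageSample) -> np.ndarray:
        px = image.pixels
        h2, w2 = px.shape[0] // 2, px.shape[1] // 2
        quads = (
            px[:h2, :w2], px[:h2, w2:], px[h2:, :w2], px[h2:, w2:],
        )
        feats = []
        for q in quads:
            gy, gx = np.gradient(q)
            feats.extend((q.mean(), q.var(), np.mean(gx * gx + gy * gy)))
        return np.asarray(feats, dtype=np.float64)


def make_toy_backends(
    seed: int = 0,
) -> tuple[BlurredL1Distance, QuadrantStatsEmbedder]:
    """Deterministic backends needing no download.

    Both toys are pure functions of the image pixels; ``seed`` is recorded
    for provenance only and does not alter the outputs (equal seeds --
    indeed all seeds -- give bitwise-identical results).
    """
    perceptual = BlurredL1Distance()
    embedder = QuadrantStatsEmbedder()
    perceptual.name += f"[seed={seed}]"
    embedder.name += f"[seed={seed}]"
    return perceptual, embedder


# ---------------------------------------------------------------------------
# deep-network adapters
# ---------------------------------------------------------------------------

def to_network_input(pixels: np.ndarray, size: int = 299) -> np.ndarray:
    """Adapt a 2-D grayscale [0,1] array for a 3-channel deep network.

    Replicates the single channel to 3 and bilinearly resamples to
    (3, size, size). Pure numpy so the adapter contract is testable without
    any deep-learning runtime.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ContractError(f"expected 2-D grayscale array, got {pixels.shape}")
    if pixels.shape != (size, size):
        from skimage.transform import resize

        pixels = resize(
            pixels, (size, size), order=1, anti_aliasing=False,
            preserve_range=True,
        )
    return np.repeat(pixels[None, :, :], 3, axis=0)


class LPIPSBackend(PerceptualDistanceBackend):
    """LPIPS perceptual distance (x100), lazily importing ``lpips``/torch.

    Requires the ``deep`` extra; raises a usage error with install guidance
    when the runtime is unavailable.
    """

    def __init__(self, net: str = "alex", scale_max: float = DEFAULT_SCALE_MAX):
        self.scale_max = float(scale_max)
        self.name = f"lpips-{net}"
        try:
            import lpips  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:  # pragma: no cover - requires torch
            raise UsageError(
                "the LPIPS backend needs the 'deep' extra "
                "(pip install normeval[deep]); use the toy backend otherwise"
            ) from exc
        self._torch = torch
        self._model = lpips.LPIPS(net=net)
        self._model.eval()

    def distance(self, a: ImageSample, b: ImageSample) -> float:  # pragma: no cover
        torch = self._torch
        ta = torch.from_numpy(to_network_input(a.pixels, a.height) * 2 - 1).float()
        tb = torch.from_numpy(to_network_input(b.pixels, b.height) * 2 - 1).float()
        with torch.no_grad():
            d = self._model(ta[None], tb[None]).item()
        return float(d) * PERCEPTUAL_SCALE_FACTOR


class InceptionEmbedder(EmbeddingBackend):
    """Inception-v3 average-pool embedding (dim 2048), lazily importing
    torchvision. The de-facto convention for the Frechet distance between
    image sets."""

    dim = 2048

    def __init__(self) -> None:
        self.name = "inception-v3-pool"
        try:
            import torch  # type: ignore
            import torchvision  # type: ignore
        except ImportError as exc:  # pragma: no cover - requires torch
            raise UsageError(
                "the Inception backend needs the 'deep' extra "
                "(pip install normeval[deep]); use the toy backend otherwise"
            ) from exc
        self._torch = torch
        model = torchvision.models.inception_v3(weights="DEFAULT")
        model.fc = torch.nn.Identity()
        model.eval()
        self._model = model

    def embed_one(self, image: ImageSample) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        t = torch.from_numpy(to_network_input(image.pixels, 299)).float()
        with torch.no_grad():
            return self._model(t[None]).numpy()[0]


# registry --------------------------------------------------------------

_PERCEPTUAL = {
    "toy": lambda: BlurredL1Distance(),
    "lpips-like": lambda: LPIPSBackend(),
}
_EMBEDDERS = {
    "toy": lambda: QuadrantStatsEmbedder(),
    "inception-like": lambda: InceptionEmbedder(),
}


def get_perceptual_backend(name: str) -> PerceptualDistanceBackend:
    try:
        factory = _PERCEPTUAL[name]
    except KeyError:
        raise UsageError(
            f"unknown perceptual backend {name!r}; choose from {sorted(_PERCEPTUAL)}"
        ) from None
    return factory()


def get_embedding_backend(name: str) -> EmbeddingBackend:
    try:
        factory = _EMBEDDERS[name]
    except KeyError:
        raise UsageError(
            f"unknown embedding backend {name!r}; choose from {sorted(_EMBEDDERS)}"
        ) from None
    return factory()
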