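"""Deterministic synthetic phantoms with known lesions, and stub restorers.

The phantoms are statistical stand-ins for mid-axial T1-weighted brain
slices, not anatomical simulations: a bright ellipse ("brain") on a dark
background, carrying a smooth random intensity texture plus pixel noise.
A lesion, when present, is an intensity shift (hyper- or hypo-intense)
inside a disc or ellipse, with its exact binary mask and tight bounding
box returned alongside -- so every metric has ground truth by construction.

Three stub restorers span the behavioral extremes the metrics must
separate:

* ``identity`` -- copies the input (perfect on healthy data, useless on
  pathology: high RQI, near-zero AHI/CACI);
* ``oracle``   -- regenerates each phantom from its own seed *without* the
  lesion, the true pseudo-healthy counterfactual (high on all indices);
* ``blur``     -- Gaussian-smooths the input, degrading everything mildly
  (intermediate scores).

Every generator here is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DataError, UsageError
from .image_io import (
    AnnotationSet,
    Box,
    DatasetBundle,
    ImageSample,
    save_boxes_json,
    save_image_png,
    save_mask_png,
)

DEFAULT_SIZE = 128
DEFAULT_TEXTURE_SCALE = 0.08
DEFAULT_NOISE_SD = 0.02
DEFAULT_LESION_DELTA = 0.35
DEFAULT_LESION_RADIUS_RANGE = (4.0, 12.0)
_BRAIN_BASE = 0.55
_BACKGROUND = 0.02
_TEXTURE_SIGMA_FRACTION = 1 / 8  # texture correlation length relative to size
_BRAIN_SEMIAXES = (0.42, 0.36)  # (y, x) fractions of the grid


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: shape, placement, and intensity shift."""

    shape: Literal["disc", "ellipse"] = "disc"
    center: tuple[float, float] = (64.0, 64.0)  # (y, x) pixels
    radii: tuple[float, float] = (8.0, 8.0)  # (ry, rx); equal for a disc
    intensity_delta: float = DEFAULT_LESION_DELTA
    polarity: Literal["hyper", "hypo"] = "hyper"


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; equal specs give bitwise-equal images."""

    seed: int
    size: int = DEFAULT_SIZE
    lesion: LesionSpec | None = None
    texture_scale: float = DEFAULT_TEXTURE_SCALE
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise UsageError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.size < 16:
            raise UsageError(f"size must be >= 16, got {self.size}")


def _ellipse_mask(
    size: int, center: tuple[float, float], radii: tuple[float, float]
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _brain_mask(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    return _ellipse_mask(
        size, (c, c), (size * _BRAIN_SEMIAXES[0], size * _BRAIN_SEMIAXES[1])
    )


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the lesion of a spec as a binary mask (all zeros if none)."""
    if spec.lesion is None:
        return np.zeros((spec.size, spec.size), dtype=np.uint8)
    les = spec.lesion
    return _ellipse_mask(spec.size, les.center, les.radii).astype(np.uint8)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageSample, np.ndarray, Box | None]:
    """Generate one phantom: (image, lesion mask, tight lesion box).

    The random texture and noise fields depend only on the seed, never on
    the lesion, so the same spec with ``lesion=None`` is the exact
    pseudo-healthy counterfactual: identical outside the lesion, shifted by
    ``intensity_delta`` inside it (up to [0, 1] clipping).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    texture = gaussian_filter(
        rng.standard_normal((size, size)), sigma=size * _TEXTURE_SIGMA_FRACTION
    )
    peak = np.abs(texture).max()
    if peak > 0:
        texture = texture / peak * spec.texture_scale
    noise = rng.standard_normal((size, size)) * spec.noise_sd

    brain = _brain_mask(size)
    img = np.full((size, size), _BACKGROUND, dtype=np.float64)
    img[brain] = _BRAIN_BASE + texture[brain]
    img += noise

    mask = lesion_mask(spec)
    box: Box | None = None
    if spec.lesion is not None:
        inside = mask.astype(bool)
        if not inside.any():
            raise DataError("lesion rasterized to zero pixels")
        if np.any(inside & ~brain):
            raise DataError("lesion extends outside the brain ellipse")
        delta = spec.lesion.intensity_delta
        img[inside] += delta if spec.lesion.polarity == "hyper" else -delta
        ys, xs = np.nonzero(inside)
        box = Box(
            label="lesion",
            x_min=int(xs.min()),
            y_min=int(ys.min()),
            x_max=int(xs.max()) + 1,
            y_max=int(ys.max()) + 1,
        )
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(id=f"phantom_{spec.seed}", pixels=img), mask, box


def _healthy_spec(seed: int, size: int, texture_scale: float, noise_sd: float
                  ) -> PhantomSpec:
    return PhantomSpec(seed=seed, size=size, lesion=None,
                       texture_scale=texture_scale, noise_sd=noise_sd)


def generate_bundle(
    seed: int,
    n_healthy: int = 64,
    n_unseen: int = 16,
    n_path: int = 32,
    lesion_size_range: tuple[float, float] = DEFAULT_LESION_RADIUS_RANGE,
    size: int = DEFAULT_SIZE,
    intensity_delta: float = DEFAULT_LESION_DELTA,
    texture_scale: float = DEFAULT_TEXTURE_SCALE,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[DatasetBundle, AnnotationSet]:
    """Generate the four evaluation sets with aligned annotations.

    Healthy sets (reference and unseen) share the lesion-free generator;
    pathological phantoms draw lesion radii uniformly from
    ``lesion_size_range`` and centers uniformly within the central brain
    region. Restorations are left unpopulated; apply :func:`stub_restorer`.
    """
    for name, n in (("n_healthy", n_healthy), ("n_unseen", n_unseen),
                    ("n_path", n_path)):
        if n < 2:
            raise UsageError(f"{name} must be >= 2 (Frechet distance), got {n}")
    lo, hi = lesion_size_range
    if not 0 < lo <= hi:
        raise UsageError(f"invalid lesion_size_range {lesion_size_range}")

    rng = np.random.default_rng(seed)
    # disjoint seed blocks per set so sets are independent draws
    seeds = rng.integers(0, 2**31 - 1, size=n_healthy + n_unseen + n_path)

    specs: dict[str, PhantomSpec] = {}
    healthy_ref, unseen, pathological = [], [], []
    annotations = AnnotationSet()

    idx = 0
    for i in range(n_healthy):
        spec = _healthy_spec(int(seeds[idx]), size, texture_scale, noise_sd)
        idx += 1
        img, _, _ = generate_phantom(spec)
        img.id = f"h_{i:03d}"
        specs[img.id] = spec
        healthy_ref.append(img)
    for i in range(n_unseen):
        spec = _healthy_spec(int(seeds[idx]), size, texture_scale, noise_sd)
        idx += 1
        img, _, _ = generate_phantom(spec)
        img.id = f"uh_{i:03d}"
        specs[img.id] = spec
        unseen.append((img, None))

    c = (size - 1) / 2.0
    for i in range(n_path):
        ry = float(rng.uniform(lo, hi))
        rx = float(rng.uniform(lo, hi))
        max_r = max(ry, rx)
        # keep the lesion well inside the brain ellipse
        span_y = size * _BRAIN_SEMIAXES[0] * 0.6 - max_r
        span_x = size * _BRAIN_SEMIAXES[1] * 0.6 - max_r
        cy = c + float(rng.uniform(-max(span_y, 0.0), max(span_y, 0.0)))
        cx = c + float(rng.uniform(-max(span_x, 0.0), max(span_x, 0.0)))
        lesion = LesionSpec(
            shape="ellipse" if ry != rx else "disc",
            center=(cy, cx),
            radii=(ry, rx),
            intensity_delta=intensity_delta,
            polarity="hyper",
        )
        spec = PhantomSpec(seed=int(seeds[idx]), size=size, lesion=lesion,
                           texture_scale=texture_scale, noise_sd=noise_sd)
        idx += 1
        img, mask, box = generate_phantom(spec)
        img.id = f"p_{i:03d}"
        specs[img.id] = spec
        pathological.append(img)
        annotations.masks[img.id] = mask
        assert box is not None
        annotations.boxes[img.id] = [box]

    bundle = DatasetBundle(
        healthy_ref=healthy_ref,
        unseen_healthy=unseen,
        pathological=pathological,
        restored_pathological=[],
        annotations=annotations,
        phantom_specs=specs,  # type: ignore[arg-type]
    )
    return bundle, annotations


def stub_restorer(
    kind: Literal["identity", "oracle", "blur"],
    bundle: DatasetBundle,
    blur_sigma: float = 2.0,
) -> DatasetBundle:
    """Return a copy of the bundle with restorations filled in.

    ``oracle`` needs the bundle's phantom specs (synthetic bundles only):
    it regenerates every image from its own seed with the lesion removed.
    """
    def restore(img: ImageSample) -> ImageSample:
        if kind == "identity":
            return ImageSample(id=img.id, pixels=img.pixels.copy())
        if kind == "blur":
            return ImageSample(
                id=img.id, pixels=gaussian_filter(img.pixels, blur_sigma)
            )
        if kind == "oracle":
            if bundle.phantom_specs is None or img.id not in bundle.phantom_specs:
                raise UsageError(
                    "oracle restorer needs a synthetic bundle with phantom specs"
                )
            spec: PhantomSpec = bundle.phantom_specs[img.id]  # type: ignore
            healthy, _, _ = generate_phantom(replace(spec, lesion=None))
            return ImageSample(id=img.id, pixels=healthy.pixels)
        raise UsageError(f"unknown restorer kind {kind!r}")

    restored_path = [restore(img) for img in bundle.pathological]
    unseen = [(inp, restore(inp)) for inp, _ in bundle.unseen_healthy]
    out = DatasetBundle(
        healthy_ref=bundle.healthy_ref,
        unseen_healthy=unseen,
        pathological=bundle.pathological,
        restored_pathological=restored_path,
        annotations=bundle.annotations,
        phantom_specs=bundle.phantom_specs,
    )
    out.validate()
    return out


def affine_augment(
    image: ImageSample,
    seed: int,
    max_rotation_deg: float = 10.0,
    max_translation: float = 0.1,
    scale_range: tuple[float, float] = (0.9, 1.1),
    hflip_p: float = 0.5,
) -> ImageSample:
    """Random affine training augmentation: rotation up to
    ``max_rotation_deg`` degrees, translation up to ``max_translation`` of
    the image side, scaling within ``scale_range``, horizontal flip with
    probability ``hflip_p``. Deterministic given the seed; the flip is an
    exact index reversal, the rest is a single bilinear warp (skipped
    entirely when all parameters are identity)."""
    if not 0 <= hflip_p <= 1:
        raise UsageError(f"hflip_p must be in [0, 1], got {hflip_p}")
    if scale_range[0] > scale_range[1] or scale_range[0] <= 0:
        raise UsageError(f"invalid scale_range {scale_range}")
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    h, w = image.shape
    ty = float(rng.uniform(-max_translation, max_translation)) * h
    tx = float(rng.uniform(-max_translation, max_translation)) * w
    scale = float(rng.uniform(scale_range[0], scale_range[1]))
    flip = bool(rng.uniform() < hflip_p)

    px = image.pixels
    if flip:
        px = px[:, ::-1]
    if angle != 0.0 or tx != 0.0 or ty != 0.0 or scale != 1.0:
        from skimage.transform import AffineTransform, warp

        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        shift = AffineTransform(translation=-center)
        transform = AffineTransform(
            rotation=np.deg2rad(angle), scale=(scale, scale),
            translation=(tx, ty),
        )
        unshift = AffineTransform(translation=center)
        px = warp(
            px, (shift + transform + unshift).inverse, order=1, mode="constant",
            cval=0.0, preserve_range=True,
        )
    return ImageSample(id=image.id, pixels=np.ascontiguousarray(px))


def write_bundle(
    bundle: DatasetBundle, annotations: AnnotationSet, out_dir: str | Path
) -> None:
    """Write a bundle to disk in the formats the I/O layer reads:
    16-bit PNG images per set, mask PNGs, and boxes.json."""
    out = Path(out_dir)
    for sub, images in (
        ("healthy", bundle.healthy_ref),
        ("unseen_healthy", [inp for inp, _ in bundle.unseen_healthy]),
        ("pathological", bundle.pathological),
        ("restored_pathological", bundle.restored_pathological),
    ):
        d = out / sub
        d.mkdir(parents=True, exist_ok=True)
        for img in images:
            save_image_png(img, d / f"{img.id}.png")
    restored_unseen = [r for _, r in bundle.unseen_healthy if r is not None]
    if restored_unseen:
        d = out / "restored_unseen"
        d.mkdir(parents=True, exist_ok=True)
        for img in restored_unseen:
            save_image_png(img, d / f"{img.id}.png")
    mask_dir = out / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    for image_id, mask in annotations.masks.items():
        save_mask_png(mask, mask_dir / f"{image_id}.png")
    save_boxes_json(annotations.boxes, out / "boxes.json")
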