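"""Image preparation and the offline augmentation plan.

Two preparation paths exist downstream of slice export:

* detection path: whole slices resized (anisotropically) to a fixed
  1280 x 1050 frame, then contrast-limited adaptive histogram equalization
  (CLAHE);
* classification path: the minimal square crop containing the lesion's
  ground-truth box, resized to 224 x 224.

The offline augmentation plan enumerates geometric and gray-level transforms
with a fixed number of uniform random draws each; the default plan makes 37
augmented copies per image, so a set of n originals grows to 38 n images when
originals are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "AugmentationPlan",
    "LesionCrop",
    "apply_clahe",
    "prepare_detection_image",
    "crop_lesion_square",
    "augment_offline",
    "count_augmented",
    "DEFAULT_PLAN",
]

_DEFAULT_TRANSFORMS: tuple[tuple[str, tuple[float, float] | float | None, int], ...] = (
    ("shift", (-0.1, 0.1), 2),
    ("rotation", (-170.0, 170.0), 10),
    ("skew", 0.2, 10),
    ("shear", (-10.0, 10.0), 10),
    ("flip_ud", None, 1),
    ("flip_lr", None, 1),
    ("hist_eq", None, 1),
    ("brightness", (0.8, 1.2), 1),
    ("contrast", (0.6, 1.5), 1),
)


@dataclass(frozen=True)
class AugmentationPlan:
    """Ordered offline transforms, each (name, parameter range, n_draws).

    Shift is a fraction of the image side; rotation and shear are degrees;
    skew is a corner-displacement magnitude (fraction of side); brightness
    and contrast are multiplicative gains; histogram equalization and the two
    flips are parameter-free.
    """

    transforms: tuple[tuple[str, tuple[float, float] | float | None, int], ...] = \
        _DEFAULT_TRANSFORMS
    seed: int = 0

    def __post_init__(self) -> None:
        for name, _rng, nd in self.transforms:
            if nd < 0:
                raise ValueError(f"n_draws for {name!r} must be >= 0")

    @property
    def total_draws(self) -> int:
        return sum(nd for _, _, nd in self.transforms)


DEFAULT_PLAN = AugmentationPlan()


@dataclass(frozen=True)
class LesionCrop:
    """A fixed-size square lesion crop with provenance back to its scan."""

    image: np.ndarray  # (side, side) uint8
    provenance: tuple[str, str, str, int, tuple[int, int, int, int]]
    label: str

    def __post_init__(self) -> None:
        h, w = self.image.shape
        if h != w:
            raise ValueError("lesion crop must be square")


def _require_gray_u8(image: np.ndarray) -> None:
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got {image.dtype}")


def apply_clahe(image: np.ndarray, clip_limit: float = 0.01,
                tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    clip_limit follows the scikit-image convention (clipping fraction in
    (0, 1]); tile_grid is the number of contextual tiles per axis.
    """
    _require_gray_u8(image)
    kernel = (max(1, image.shape[0] // tile_grid[0]),
              max(1, image.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(image, kernel_size=kernel,
                                      clip_limit=clip_limit)
    return (out * 255.0 + 0.5).astype(np.uint8)


def prepare_detection_image(image: np.ndarray,
                            target: tuple[int, int] = (1280, 1050),
                            clahe: bool = True,
                            clip_limit: float = 0.01) -> np.ndarray:
    """Whole-slice preparation for the detector: direct (anisotropic) resize to
    `target` (height, width), then CLAHE."""
    _require_gray_u8(image)
    if image.size == 0:
        raise ValueError("empty image")
    resized = transform.resize(image, target, order=1, anti_aliasing=True,
                               preserve_range=True)
    resized = np.clip(resized, 0, 255).astype(np.uint8)
    if clahe:
        resized = apply_clahe(resized, clip_limit=clip_limit)
    return resized


def crop_lesion_square(image: np.ndarray, bbox: tuple[int, int, int, int],
                       out_size: int = 224,
                       provenance: tuple[str, str, str, int] | None = None,
                       label: str = "benign") -> LesionCrop:
    """Minimal square crop containing the ground-truth box, resized.

    The square has side max(w, h), is centered on the bbox center, and is
    shifted -- never shrunk -- to stay inside the frame.  If the side exceeds
    the smaller image dimension it is clipped to that dimension with a
    warning.
    """
    _require_gray_u8(image)
    H, W = image.shape
    x, y, w, h = bbox
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(f"bbox {bbox} not inside {H}x{W} frame")
    side = max(w, h)
    if side > min(H, W):
        warnings.warn(f"square side {side} exceeds frame; clipping to {min(H, W)}")
        side = min(H, W)
    cx, cy = x + w / 2.0, y + h / 2.0
    x0 = int(round(cx - side / 2.0))
    y0 = int(round(cy - side / 2.0))
    x0 = min(max(0, x0), W - side)
    y0 = min(max(0, y0), H - side)
    crop = image[y0:y0 + side, x0:x0 + side]
    resized = transform.resize(crop, (out_size, out_size), order=1,
                               anti_aliasing=True, preserve_range=True)
    resized = np.clip(resized, 0, 255).astype(np.uint8)
    prov = (provenance or ("", "", "", -1)) + ((x0, y0, side, side),)
    return LesionCrop(image=resized, provenance=prov, label=label)


# ---------------------------------------------------------------------------
# individual offline transforms (uint8 in, uint8 out, shape-preserving)

def _shift(img: np.ndarray, rng: np.random.Generator,
           lo: float, hi: float) -> np.ndarray:
    dy = rng.uniform(lo, hi) * img.shape[0]
    dx = rng.uniform(lo, hi) * img.shape[1]
    out = ndimage.shift(img.astype(np.float64), (dy, dx), order=1, mode="reflect")
    return np.clip(out, 0, 255).astype(np.uint8)


def _rotate(img: np.ndarray, rng: np.random.Generator,
            lo: float, hi: float) -> np.ndarray:
    angle = rng.uniform(lo, hi)
    out = ndimage.rotate(img.astype(np.float64), angle, reshape=False,
                         order=1, mode="reflect")
    return np.clip(out, 0, 255).astype(np.uint8)


def _skew(img: np.ndarray, rng: np.random.Generator,
          magnitude: float) -> np.ndarray:
    """Random-corner perspective skew: one corner of the unit square is pulled
    inward by `magnitude` of the side along both axes."""
    h, w = img.shape
    src = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]],
                   dtype=np.float64)
    dst = src.copy()
    corner = int(rng.integers(0, 4))
    dx = rng.uniform(0, magnitude) * w
    dy = rng.uniform(0, magnitude) * h
    sign = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=np.float64)
    dst[corner] += sign[corner] * (dx, dy)
    if hasattr(transform.ProjectiveTransform, "from_estimate"):
        tf = transform.ProjectiveTransform.from_estimate(dst, src)
    else:  # older scikit-image
        tf = transform.ProjectiveTransform()
        tf.estimate(dst, src)
    out = transform.warp(img.astype(np.float64), tf, order=1, mode="reflect",
                         preserve_range=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def _shear(img: np.ndarray, rng: np.random.Generator,
           lo: float, hi: float) -> np.ndarray:
    angle = np.deg2rad(rng.uniform(lo, hi))
    h, w = img.shape
    center = np.array([w / 2.0, h / 2.0])
    tf = (transform.AffineTransform(translation=-center)
          + transform.AffineTransform(shear=angle)
          + transform.AffineTransform(translation=center))
    out = transform.warp(img.astype(np.float64), tf.inverse, order=1,
                         mode="reflect", preserve_range=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def _hist_eq(img: np.ndarray) -> np.ndarray:
    out = exposure.equalize_hist(img)
    return (out * 255.0 + 0.5).astype(np.uint8)


def _brightness(img: np.ndarray, rng: np.random.Generator,
                lo: float, hi: float) -> np.ndarray:
    gain = rng.uniform(lo, hi)
    return np.clip(img.astype(np.float64) * gain, 0, 255).astype(np.uint8)


def _contrast(img: np.ndarray, rng: np.random.Generator,
              lo: float, hi: float) -> np.ndarray:
    gain = rng.uniform(lo, hi)
    mean = img.mean()
    out = (img.astype(np.float64) - mean) * gain + mean
    return np.clip(out, 0, 255).astype(np.uint8)


def augment_offline(image: np.ndarray, plan: AugmentationPlan = DEFAULT_PLAN,
                    rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """All offline augmented copies of one image (the original is NOT included).

    Returns exactly plan.total_draws images; parameters are drawn uniformly in
    each transform's stated range, deterministically under the rng/plan seed.
    """
    _require_gray_u8(image)
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    out: list[np.ndarray] = []
    for name, prm, n_draws in plan.transforms:
        for _ in range(n_draws):
            if name == "shift":
                out.append(_shift(image, rng, *prm))
            elif name == "rotation":
                out.append(_rotate(image, rng, *prm))
            elif name == "skew":
                out.append(_skew(image, rng, float(prm)))
            elif name == "shear":
                out.append(_shear(image, rng, *prm))
            elif name == "flip_ud":
                out.append(np.flipud(image).copy())
            elif name == "flip_lr":
                out.append(np.fliplr(image).copy())
            elif name == "hist_eq":
                out.append(_hist_eq(image))
            elif name == "brightness":
                out.append(_brightness(image, rng, *prm))
            elif name == "contrast":
                out.append(_contrast(image, rng, *prm))
            else:
                raise ValueError(f"unknown transform {name!r}")
    return out


def count_augmented(n_images: int, plan: AugmentationPlan = DEFAULT_PLAN) -> int:
    """Final image count for a set of n originals: originals are retained
    alongside their augmented copies, so n * (1 + total draws)."""
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    return n_images * (1 + plan.total_draws)
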