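"""Seeded synthetic DBT-like cohorts for pipeline testing.

Generates grayscale slice stacks with one or more bright lesion blobs, the
matching annotation CSVs, and optional detector-style prediction files, so the
whole pipeline is exercisable without any external image collection.  Lesions
follow the clinical annotation convention this pipeline assumes: a lesion is
annotated on a single central slice and is visible over 25% of the volume's
slices in each direction around it, fading toward the span edges.  Benign
lesions get smooth elliptical margins; cancerous lesions get irregular,
spiculated margins produced by random radial perturbation.

The background is a smoothed random field (Gaussian-filtered noise) standing
in for parenchyma texture; it makes no claim to anatomical realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .ingest import DbtVolume, LesionAnnotation, lesion_slice_span, write_annotations_csv

__all__ = [
    "SyntheticCohortSpec",
    "generate_volume",
    "generate_cohort",
    "generate_crop_dataset",
    "lesion_margin_roughness",
    "write_annotations_csv",
]

BACKGROUND_LEVEL = 90.0  # mean parenchyma gray level, 8-bit scale
BACKGROUND_AMPLITUDE = 35.0  # amplitude of the smoothed texture field


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort; identical spec + seed => bit-identical output.

    class_ratio is the fraction of *benign* scans.  lesion_radius_range is in
    pixels.  contrast is the lesion-over-background intensity gain
    (dimensionless, additive fraction of the local background level).
    noise_sd is per-pixel Gaussian noise in gray-level units.
    """

    n_patients: int = 100
    scans_per_patient: int = 2
    n_slices: int = 40
    height: int = 160
    width: int = 128
    class_ratio: float = 0.62
    lesion_radius_range: tuple[int, int] = (8, 16)
    contrast: float = 0.9
    noise_sd: float = 6.0
    seed: int = 0
    lesions_per_scan: int = 1

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 0.0 <= self.class_ratio <= 1.0:
            raise ValueError("class_ratio must lie in [0, 1]")
        if self.lesions_per_scan < 1:
            raise ValueError("lesions_per_scan must be >= 1")
        rmin, rmax = self.lesion_radius_range
        if rmin < 2 or rmax < rmin:
            raise ValueError("lesion_radius_range must satisfy 2 <= rmin <= rmax")
        # margin of 1.6*r keeps spiculations inside the frame
        if 2 * int(1.6 * rmax) + 2 >= min(self.height, self.width):
            raise ValueError(
                f"lesion radius up to {rmax}px cannot fit inside a "
                f"{self.height}x{self.width} frame; shrink the radius range "
                "or enlarge the frame"
            )


def _background_stack(rng: np.random.Generator, n_slices: int, h: int, w: int,
                      noise_sd: float) -> np.ndarray:
    """Smoothed random field shared across slices plus per-slice noise."""
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    base = base / (np.abs(base).max() + 1e-9)
    stack = BACKGROUND_LEVEL + BACKGROUND_AMPLITUDE * base
    stack = np.repeat(stack[None], n_slices, axis=0)
    stack += noise_sd * rng.standard_normal((n_slices, h, w))
    return stack


def _lesion_mask(rng: np.random.Generator, h: int, w: int, cy: float, cx: float,
                 radius: float, label: str) -> np.ndarray:
    """Soft [0,1] lesion footprint; smooth ellipse for benign, perturbed radial
    margin with spiculations for cancer."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dy, dx)

    if label == "benign":
        axis_ratio = rng.uniform(0.75, 1.0)
        phi = rng.uniform(0, np.pi)
        c, s = np.cos(phi), np.sin(phi)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        dist = np.hypot(u / 1.0, v / axis_ratio)
        boundary = radius
        soft = 1.0 / (1.0 + np.exp((dist - boundary) / (0.08 * radius + 0.5)))
    else:
        # radial boundary r(theta) = radius * (1 + sum of random harmonics)
        n_harm = 6
        amps = rng.uniform(0.08, 0.22, size=n_harm)
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)
        orders = rng.integers(3, 9, size=n_harm)
        pert = np.zeros_like(theta)
        for a, p, k in zip(amps, phases, orders):
            pert += a * np.cos(k * theta + p)
        boundary = radius * (1.0 + pert)
        # spiculations: narrow radial spikes
        n_spic = int(rng.integers(4, 8))
        spic_theta = rng.uniform(0, 2 * np.pi, size=n_spic)
        spic_len = rng.uniform(0.25, 0.55, size=n_spic) * radius
        for t0, ln in zip(spic_theta, spic_len):
            ang = np.angle(np.exp(1j * (theta - t0)))
            boundary = boundary + ln * np.exp(-(ang / 0.09) ** 2)
        soft = 1.0 / (1.0 + np.exp((rr - boundary) / (0.035 * radius + 0.3)))
    return soft


def _tight_bbox(mask: np.ndarray, thresh: float = 0.5) -> tuple[int, int, int, int]:
    """(x, y, w, h), half-open, of the thresholded footprint."""
    ys, xs = np.nonzero(mask > thresh)
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    return x0, y0, x1 - x0, y1 - y0


def generate_volume(spec: SyntheticCohortSpec, label: str,
                    rng: np.random.Generator,
                    patient_id: str = "P000", study_id: str = "S0",
                    view: str = "lcc") -> tuple[DbtVolume, list[LesionAnnotation]]:
    """One synthetic scan with `spec.lesions_per_scan` lesions of class `label`.

    Lesion signal is added over the span [central - floor(0.25 n), central +
    floor(0.25 n)] (clipped to the volume), strictly zero outside it, fading
    linearly from the central slice toward the span edges.
    """
    spec.validate()
    if label not in ("benign", "cancer"):
        raise ValueError(f"label must be 'benign' or 'cancer', got {label!r}")

    n, h, w = spec.n_slices, spec.height, spec.width
    stack = _background_stack(rng, n, h, w, spec.noise_sd)

    annotations: list[LesionAnnotation] = []
    for _ in range(spec.lesions_per_scan):
        radius = float(rng.uniform(*spec.lesion_radius_range))
        margin = int(1.6 * radius) + 1
        cy = float(rng.uniform(margin, h - margin))
        cx = float(rng.uniform(margin, w - margin))
        central = int(rng.integers(0, n))
        lo, hi = lesion_slice_span(n, central)

        mask = _lesion_mask(rng, h, w, cy, cx, radius, label)
        span_half = max(1, int(np.floor(0.25 * n)))
        gain = spec.contrast * BACKGROUND_LEVEL
        for s in range(lo, hi + 1):
            fade = 1.0 - 0.8 * abs(s - central) / span_half
            stack[s] += gain * fade * mask

        bbox = _tight_bbox(mask)
        annotations.append(LesionAnnotation(
            patient_id=patient_id, study_id=study_id, view=view,
            central_slice=central, bbox=bbox, label=label))

    voxels = np.clip(stack, 0, 255).astype(np.uint8)
    vol = DbtVolume(voxels=voxels, patient_id=patient_id, study_id=study_id, view=view)
    return vol, annotations


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> Path:
    """Write a cohort to `out_dir`: per-scan PNG slice directories plus a single
    annotations.csv.  Benign scan count = round(class_ratio * total scans);
    labels are assigned to scans by a seeded shuffle.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec.n_patients == 0:
        warnings.warn("n_patients=0: writing an empty cohort")
        write_annotations_csv([], out_dir / "annotations.csv")
        return out_dir

    rng = np.random.default_rng(spec.seed)
    total = spec.n_patients * spec.scans_per_patient
    n_benign = int(np.floor(spec.class_ratio * total + 0.5))
    labels = np.array(["benign"] * n_benign + ["cancer"] * (total - n_benign))
    rng.shuffle(labels)

    all_annotations: list[LesionAnnotation] = []
    views = ("lcc", "lmlo", "rcc", "rmlo")
    scan = 0
    for p in range(spec.n_patients):
        pid = f"P{p:04d}"
        for s in range(spec.scans_per_patient):
            vol, anns = generate_volume(
                spec, str(labels[scan]), rng,
                patient_id=pid, study_id="S0", view=views[s % len(views)])
            vol.write_png_dir(out_dir / pid / "S0" / vol.view)
            all_annotations.extend(anns)
            scan += 1

    write_annotations_csv(all_annotations, out_dir / "annotations.csv")
    return out_dir


def lesion_margin_roughness(mask: np.ndarray, thresh: float = 0.5) -> float:
    """Margin-roughness proxy: perimeter^2 / area of the thresholded footprint.

    Scale-free (=4*pi for a disc); stochastically larger for spiculated than
    for smooth margins.
    """
    from skimage import measure

    binary = mask > thresh
    perim = measure.perimeter(binary)
    area = binary.sum()
    if area == 0:
        return np.nan
    return float(perim ** 2 / area)


def generate_crop_dataset(n_train: int, n_test: int, size: int = 64,
                          seed: int = 0, class_ratio: float = 0.5,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Balanced-ish 2-class lesion-crop dataset for classifier tests.

    Returns (X_train, y_train, X_test, y_test); X is (N, size, size) uint8,
    y is 0 for benign, 1 for cancer.  Each crop is a single central-slice
    lesion rendered on parenchyma texture, the same construction used for full
    volumes, cropped to the minimal square around the lesion footprint.
    """
    rng = np.random.default_rng(seed)

    def make(n: int) -> tuple[np.ndarray, np.ndarray]:
        n_benign = int(np.floor(class_ratio * n + 0.5))
        labels = np.array([0] * n_benign + [1] * (n - n_benign))
        rng.shuffle(labels)
        imgs = np.empty((n, size, size), dtype=np.uint8)
        frame = int(size * 1.5)
        for i, lab in enumerate(labels):
            name = "benign" if lab == 0 else "cancer"
            radius = float(rng.uniform(0.14, 0.22) * frame)
            cy = float(rng.uniform(0.4, 0.6) * frame)
            cx = float(rng.uniform(0.4, 0.6) * frame)
            bg = _background_stack(rng, 1, frame, frame, noise_sd=6.0)[0]
            mask = _lesion_mask(rng, frame, frame, cy, cx, radius, name)
            img = bg + 0.9 * BACKGROUND_LEVEL * mask
            x, y, bw, bh = _tight_bbox(mask)
            side = max(bw, bh)
            x0 = min(max(0, x + bw // 2 - side // 2), frame - side)
            y0 = min(max(0, y + bh // 2 - side // 2), frame - side)
            crop = np.clip(img[y0:y0 + side, x0:x0 + side], 0, 255)
            from skimage.transform import resize
            crop = resize(crop, (size, size), order=1, anti_aliasing=True,
                          preserve_range=True)
            imgs[i] = crop.astype(np.uint8)
        return imgs, labels

    X_train, y_train = make(n_train)
    X_test, y_test = make(n_test)
    return X_train, y_train, X_test, y_test
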