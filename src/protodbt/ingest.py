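"""Volume and annotation ingestion, slice-span arithmetic, and patient splits.

Conventions used throughout the package:

* slice indices and pixel coordinates are 0-based;
* bounding boxes are (x, y, width, height) with a top-left origin and
  half-open extent [x, x+w) x [y, y+h);
* a lesion annotated on its central slice is assumed visible over
  floor(0.25 * n_slices) slices in each direction (the clinical annotation
  convention for tomosynthesis collections), clipped to the volume.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DbtVolume",
    "LesionAnnotation",
    "SplitAssignment",
    "lesion_slice_span",
    "select_slices",
    "export_slices",
    "patient_split",
    "read_annotations",
    "write_annotations_csv",
    "read_volume_png_dir",
    "read_volume_dicom",
]

ANNOTATION_COLUMNS = ["patient_id", "study_id", "view", "slice",
                      "x", "y", "width", "height", "label"]
VALID_LABELS = frozenset({"benign", "cancer"})


@dataclass
class DbtVolume:
    """A stack of grayscale slices with patient/study/view identity."""

    voxels: np.ndarray  # (n_slices, height, width), uint8
    patient_id: str
    study_id: str
    view: str

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a non-empty (n_slices, H, W) array")

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    def write_png_dir(self, out_dir: str | Path) -> list[Path]:
        return export_slices(self, list(range(self.n_slices)), out_dir)

    def write_dicom(self, path: str | Path) -> Path:
        """Minimal multi-frame secondary-capture DICOM export."""
        import pydicom
        from pydicom.dataset import FileMetaDataset
        from pydicom.uid import (ExplicitVRLittleEndian, SecondaryCaptureImageStorage,
                                 generate_uid)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.PatientID = self.patient_id
        ds.StudyInstanceUID = generate_uid()
        ds.SeriesInstanceUID = generate_uid()
        ds.Modality = "OT"
        ds.NumberOfFrames = self.n_slices
        ds.Rows, ds.Columns = self.frame_shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(self.voxels).tobytes()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        ds.save_as(path, enforce_file_format=True)
        return path


@dataclass(frozen=True)
class LesionAnnotation:
    """One lesion: identity, central slice, pixel bbox, benign/cancer label."""

    patient_id: str
    study_id: str
    view: str
    central_slice: int
    bbox: tuple[int, int, int, int]  # (x, y, w, h), half-open
    label: str

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"bbox width/height must be positive, got {self.bbox}")
        if x < 0 or y < 0:
            raise ValueError(f"bbox origin must be non-negative, got {self.bbox}")
        if self.central_slice < 0:
            raise ValueError("central_slice must be >= 0")
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}")

    @property
    def scan_key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.study_id, self.view)


@dataclass(frozen=True)
class SplitAssignment:
    """patient_id -> partition mapping; partitions are disjoint and complete."""

    assignment: dict[str, str]
    seed: int

    def patients(self, partition: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == partition)

    def sizes(self) -> dict[str, int]:
        out = {"train": 0, "valid": 0, "test": 0}
        for s in self.assignment.values():
            out[s] += 1
        return out

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "partition", "seed"])
            for pid in sorted(self.assignment):
                w.writerow([pid, self.assignment[pid], self.seed])


def lesion_slice_span(n_slices: int, central_slice: int) -> tuple[int, int]:
    """Inclusive slice range over which an annotated lesion is assumed visible.

    The lesion spans floor(0.25 * n_slices) slices in each direction from the
    central slice, clipped to [0, n_slices - 1].
    """
    if not 0 <= central_slice < n_slices:
        raise ValueError(
            f"central_slice {central_slice} out of range for {n_slices} slices")
    half = math.floor(0.25 * n_slices)
    lo = max(0, central_slice - half)
    hi = min(n_slices - 1, central_slice + half)
    return lo, hi


def _round_half_down(x: float) -> int:
    """Round to nearest, ties toward the smaller integer."""
    return int(math.ceil(x - 0.5))


def select_slices(span: tuple[int, int], label: str,
                  central_slice: int | None = None) -> list[int]:
    """Pick the inter-slice augmentation slices within a lesion's span.

    7 slices for benign, 9 for cancer (partially balancing the classes),
    evenly spaced across the span and always including the central slice.
    Spans shorter than the requested count return every slice in the span.
    """
    lo, hi = span
    if lo > hi:
        raise ValueError(f"invalid span {span}")
    k = {"benign": 7, "cancer": 9}[label]
    length = hi - lo + 1
    if length <= k:
        return list(range(lo, hi + 1))
    picks = {lo + _round_half_down(i * (hi - lo) / (k - 1)) for i in range(k)}
    if central_slice is not None and central_slice not in picks:
        if not lo <= central_slice <= hi:
            raise ValueError("central_slice outside span")
        # swap the nearest pick for the central slice
        nearest = min(picks, key=lambda s: (abs(s - central_slice), s))
        picks.discard(nearest)
        picks.add(central_slice)
    return sorted(picks)


def _slice_filename(volume: DbtVolume, index: int) -> str:
    return (f"{volume.patient_id}_{volume.study_id}_{volume.view}"
            f"_slice_{index:03d}.png")


def export_slices(volume: DbtVolume, indices: list[int],
                  out_dir: str | Path) -> list[Path]:
    """Write the chosen slices as 8-bit grayscale PNGs (lossless).

    Filenames encode (patient, study, view, slice index).
    """
    out_dir = Path(out_dir)
    for i in indices:
        if not 0 <= i < volume.n_slices:
            raise IndexError(f"slice index {i} out of range [0, {volume.n_slices})")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in indices:
        arr = volume.voxels[i]
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        p = out_dir / _slice_filename(volume, i)
        Image.fromarray(arr, mode="L").save(p)
        paths.append(p)
    return paths


def read_volume_png_dir(dir_path: str | Path, patient_id: str = "",
                        study_id: str = "", view: str = "") -> DbtVolume:
    """Load a per-slice PNG directory (sorted filename order) as a volume."""
    dir_path = Path(dir_path)
    files = sorted(dir_path.glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG slices in {dir_path}")
    slices = [np.asarray(Image.open(f).convert("L")) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"slices have inconsistent shapes: {shapes}")
    return DbtVolume(np.stack(slices), patient_id or dir_path.name,
                     study_id, view)


def read_volume_dicom(path: str | Path, patient_id: str = "",
                      study_id: str = "", view: str = "") -> DbtVolume:
    """Load a multi-frame DICOM stack, rescaled to 8-bit grayscale."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    return DbtVolume(arr.astype(np.uint8),
                     patient_id or str(getattr(ds, "PatientID", "")),
                     study_id or str(getattr(ds, "StudyInstanceUID", "")),
                     view)


def patient_split(patient_ids: list[str], seed: int) -> SplitAssignment:
    """Nested 80-20 patient-level split into train/valid/test.

    20% of patients (rounded to nearest) go to test; of the remainder, 20%
    (rounded to nearest) to valid; the rest to train.  With 100 patients this
    yields the 64/16/20 allocation.  All scans of a patient inherit its
    partition, so no patient leaks across sets.
    """
    ids = list(dict.fromkeys(patient_ids))  # stable de-dup
    if len(ids) < 3:
        raise ValueError(f"need at least 3 distinct patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(ids))[rng.permutation(len(ids))])
    n = len(order)
    n_test = int(math.floor(0.2 * n + 0.5))
    n_valid = int(math.floor(0.2 * (n - n_test) + 0.5))
    assignment: dict[str, str] = {}
    for i, pid in enumerate(order):
        if i < n_test:
            assignment[pid] = "test"
        elif i < n_test + n_valid:
            assignment[pid] = "valid"
        else:
            assignment[pid] = "train"
    return SplitAssignment(assignment=assignment, seed=seed)


def write_annotations_csv(annotations: list[LesionAnnotation],
                          path: str | Path) -> Path:
    """Write the annotation table; duplicate rows are an error."""
    path = Path(path)
    seen = set()
    for a in annotations:
        key = (a.patient_id, a.study_id, a.view, a.central_slice, a.bbox)
        if key in seen:
            raise ValueError(f"duplicate annotation row: {key}")
        seen.add(key)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            x, y, bw, bh = a.bbox
            w.writerow([a.patient_id, a.study_id, a.view, a.central_slice,
                        x, y, bw, bh, a.label])
    return path


def read_annotations(path: str | Path) -> list[LesionAnnotation]:
    """Read and validate an annotation CSV; malformed rows are reported with
    their (1-based, header-inclusive) row numbers."""
    path = Path(path)
    out: list[LesionAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ANNOTATION_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"annotation CSV missing column(s): {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(LesionAnnotation(
                    patient_id=row["patient_id"],
                    study_id=row["study_id"],
                    view=row["view"],
                    central_slice=int(row["slice"]),
                    bbox=(int(row["x"]), int(row["y"]),
                          int(row["width"]), int(row["height"])),
                    label=row["label"].strip().lower(),
                ))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {i}: {exc}") from exc
    return out
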