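"""Cohort data model and TIFF/manifest I/O.

A patient contributes three tumor cuts — the slice with the largest
tumor area (central) and its immediate cranial and caudal neighbors —
each stored as a grayscale TIFF plus a binary mask TIFF delineating the
irregular tumor region S. A CSV manifest ties slices, clinical data and
the binary KRAS label together.

Conventions: row-major arrays, origin top-left, 0-based indices; images
are 8-bit on disk (gray levels 0..255); in a mask any nonzero pixel is
in-ROI.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .clinical import CLINICAL_FIELDS, ClinicalRecord

SLICE_ROLES = ("caudal", "central", "cranial")

LABELS = {"KRAS+": 1, "KRAS-": 0}
LABEL_NAMES = {1: "KRAS+", 0: "KRAS-"}

#: minimum image side — a 3-level dyadic wavelet decomposition needs 2**3
MIN_SIDE = 8
#: minimum in-ROI pixel count (degenerate-ROI guard)
MIN_ROI_PIXELS = 16

MANIFEST_COLUMNS = (
    ("patient_id", "label")
    + CLINICAL_FIELDS
    + ("img_caudal", "msk_caudal", "img_central", "msk_central", "img_cranial", "msk_cranial")
)


@dataclass(frozen=True)
class RoiSlice:
    """One grayscale tumor cut plus its binary ROI mask."""

    image: np.ndarray
    mask: np.ndarray
    role: str

    def __post_init__(self) -> None:
        image = np.asarray(self.image)
        mask = np.asarray(self.mask, dtype=bool)
        if image.ndim != 2:
            raise ValueError("image must be a 2-D gray-level array")
        if image.shape != mask.shape:
            raise ValueError(
                f"image shape {image.shape} != mask shape {mask.shape}"
            )
        if min(image.shape) < MIN_SIDE:
            raise ValueError(f"image sides must be >= {MIN_SIDE}, got {image.shape}")
        if self.role not in SLICE_ROLES:
            raise ValueError(f"unknown slice role {self.role!r}")
        n_roi = int(mask.sum())
        if n_roi < MIN_ROI_PIXELS:
            raise ValueError(f"ROI has {n_roi} pixels; need >= {MIN_ROI_PIXELS}")
        object.__setattr__(self, "image", image)
        object.__setattr__(self, "mask", mask)

    @property
    def roi_size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Patient:
    """Three tumor cuts, clinical record and binary KRAS status (1 = KRAS+)."""

    patient_id: str
    slices: tuple[RoiSlice, RoiSlice, RoiSlice]
    clinical: ClinicalRecord
    label: int

    def __post_init__(self) -> None:
        roles = tuple(s.role for s in self.slices)
        if sorted(roles) != sorted(SLICE_ROLES):
            raise ValueError(
                f"patient {self.patient_id}: need one slice per role "
                f"{SLICE_ROLES}, got {roles}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"patient {self.patient_id}: label must be 0/1")


def _to_gray(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3]
        if np.all(rgb[..., 0] == rgb[..., 1]) and np.all(rgb[..., 0] == rgb[..., 2]):
            return rgb[..., 0]
        # ITU-R 601 luminance for genuinely colored input
        return np.round(rgb @ np.array([0.299, 0.587, 0.114])).astype(arr.dtype)
    raise ValueError(f"{path}: cannot interpret shape {arr.shape} as grayscale")


def read_roi_slice(image_path, mask_path, role: str) -> RoiSlice:
    """Read an image/mask TIFF pair; any nonzero mask pixel is in-ROI."""
    image = _to_gray(tifffile.imread(image_path), image_path)
    mask = _to_gray(tifffile.imread(mask_path), mask_path)
    if image.shape != mask.shape:
        raise ValueError(
            f"{image_path} shape {image.shape} does not match mask "
            f"{mask_path} shape {mask.shape}"
        )
    if not np.any(mask):
        raise ValueError(f"{mask_path}: empty ROI mask")
    return RoiSlice(image=image.astype(np.int64), mask=mask != 0, role=role)


def write_roi_slice(roi: RoiSlice, image_path, mask_path) -> None:
    """Write an 8-bit grayscale TIFF pair (mask: 0/255)."""
    tifffile.imwrite(image_path, np.asarray(roi.image, dtype=np.uint8))
    tifffile.imwrite(mask_path, np.where(roi.mask, 255, 0).astype(np.uint8))


def load_cohort(manifest_path) -> list[Patient]:
    """Load a cohort from a CSV manifest; paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    patients: list[Patient] = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        warnings.warn(f"{manifest_path}: empty manifest, returning empty cohort")
        return []
    missing = set(MANIFEST_COLUMNS) - set(rows[0])
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    for row in rows:
        pid = row["patient_id"]
        if row["label"] not in LABELS:
            raise ValueError(f"patient {pid}: unknown label {row['label']!r}")
        try:
            clinical = ClinicalRecord(
                liver_met=int(row["liver_met"]),
                lung_met=int(row["lung_met"]),
                sex=int(row["sex"]),
                age=float(row["age"]),
                location=int(row["location"]),
                t_stage=int(row["t_stage"]),
                n_stage=int(row["n_stage"]),
                m_stage=int(row["m_stage"]),
                differentiation=int(row["differentiation"]),
            )
        except ValueError as exc:
            raise ValueError(f"patient {pid}: {exc}") from exc
        slices = []
        for role in SLICE_ROLES:
            img_p, msk_p = row[f"img_{role}"], row[f"msk_{role}"]
            if not img_p or not msk_p:
                raise ValueError(f"patient {pid}: missing {role} slice paths")
            img_file, msk_file = base / img_p, base / msk_p
            for f in (img_file, msk_file):
                if not f.exists():
                    raise ValueError(f"patient {pid}: file not found: {f}")
            slices.append(read_roi_slice(img_file, msk_file, role))
        patients.append(
            Patient(patient_id=pid, slices=tuple(slices), clinical=clinical,
                    label=LABELS[row["label"]])
        )
    return patients


def write_cohort(patients: Sequence[Patient], out_dir) -> Path:
    """Write TIFF pairs plus ``manifest.csv`` under ``out_dir``.

    Returns the manifest path. Layout: ``images/<pid>_<role>_{img,msk}.tiff``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for p in patients:
            paths = {}
            for roi in p.slices:
                img_rel = f"images/{p.patient_id}_{roi.role}_img.tiff"
                msk_rel = f"images/{p.patient_id}_{roi.role}_msk.tiff"
                write_roi_slice(roi, out_dir / img_rel, out_dir / msk_rel)
                paths[roi.role] = (img_rel, msk_rel)
            clin = [getattr(p.clinical, f) for f in CLINICAL_FIELDS]
            row = [p.patient_id, LABEL_NAMES[p.label]] + clin
            for role in SLICE_ROLES:
                row.extend(paths[role])
            writer.writerow(row)
    return manifest


def class_counts(patients: Sequence[Patient]) -> tuple[int, int]:
    """(n_positive, n_negative) for a cohort."""
    n_pos = sum(p.label == 1 for p in patients)
    return n_pos, len(patients) - n_pos
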