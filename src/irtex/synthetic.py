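"""Synthetic CT-phantom cohorts.

The real study cohort (56 colorectal-cancer patients, 30 KRAS+ and 26
KRAS−, three tumor cuts each) is private, so this module generates
phantom cohorts carrying exactly the statistical structure the analysis
relies on:

* irregular connected tumor masks (thresholded low-pass-filtered noise);
* stationary in-ROI textures whose *second-order* statistics depend on
  class — white noise convolved with a Gaussian kernel of width w0 for
  KRAS− and w0·(1 + texture_effect) for KRAS+, rescaled to 8-bit;
* nine clinical variables whose metastasis/stage components shift with
  class by ``clinical_effect`` on the log-odds scale.

With both effects at 0 the two classes are identically distributed
(null cohort); the generator is a pure function of (EffectSpec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .clinical import ClinicalRecord
from .cohort import Patient, RoiSlice, SLICE_ROLES, write_cohort

#: base Gaussian kernel width (pixels) of the KRAS− texture; chosen so
#: the distance-1 GLCM at 64 quantization levels is structured but not
#: saturated on its diagonal.
BASE_KERNEL_WIDTH = 1.0
#: per-patient log-normal jitter of the kernel width, so the three cuts
#: of one patient correlate more than cuts of different patients
PATIENT_JITTER_SD = 0.05

# class-conditional baselines (KRAS− class); effects shift the KRAS+ class
_P_LIVER = 0.30
_P_LUNG = 0.20
_P_SEX = 0.50
_AGE_MEAN, _AGE_SD = 66.0, 9.0
_T_BASE = np.array([0.05, 0.10, 0.25, 0.40, 0.20])  # T stage 0..4
_N_BASE = np.array([0.40, 0.35, 0.25])  # N stage 0..2
_DIFF_BASE = np.array([0.15, 0.35, 0.35, 0.15])  # differentiation 1..4
_N_LOCATIONS = 4


@dataclass(frozen=True)
class EffectSpec:
    """Cohort recipe: class separations, counts, geometry and seed."""

    texture_effect: float = 0.0
    clinical_effect: float = 0.0
    n_pos: int = 30
    n_neg: int = 26
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_effect < 0 or self.clinical_effect < 0:
            raise ValueError("effects must be >= 0")
        if self.n_pos + self.n_neg < 2:
            raise ValueError("need at least 2 patients")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")


def _mask_from_rng(size: int, rng: np.random.Generator) -> np.ndarray:
    """One attempt: threshold smoothed noise, keep the largest blob."""
    noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 6)
    target = rng.uniform(0.20, 0.45)
    mask = noise >= np.quantile(noise, 1 - target)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros((size, size), dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_mask(size: int, seed: int | np.random.Generator) -> np.ndarray:
    """Irregular connected ROI mask (8-connectivity, one component).

    Thresholded low-pass-filtered noise; regenerates internally until the
    largest blob occupies 10-60% of the frame (in practice the first
    attempt almost always does).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(100):
        mask = _mask_from_rng(size, rng)
        frac = mask.mean()
        if 0.10 <= frac <= 0.60 and mask.sum() >= 16:
            return mask
    raise RuntimeError("mask generation failed to converge")  # pragma: no cover


def _texture_from_rng(
    size: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=sigma)
    lo, hi = field.min(), field.max()
    return np.clip(np.floor((field - lo) / (hi - lo) * 256), 0, 255).astype(np.int64)


def class_kernel_width(class_label: int, effect: EffectSpec) -> float:
    """Gaussian kernel width for a class: w0 (KRAS−) or w0·(1+effect) (KRAS+)."""
    w = BASE_KERNEL_WIDTH
    return w * (1.0 + effect.texture_effect) if class_label == 1 else w


def generate_texture(
    size: int, class_label: int, effect: EffectSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Stationary class-dependent texture, rescaled to gray levels 0..255."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _texture_from_rng(size, class_kernel_width(class_label, effect), rng)


def _shift_logit(p: float, delta: float) -> float:
    logit = np.log(p / (1 - p)) + delta
    return 1.0 / (1.0 + np.exp(-logit))


def _ordinal_sample(base: np.ndarray, delta: float, rng: np.random.Generator) -> int:
    """Proportional-odds draw: every cumulative log-odds shifts by delta.

    A logistic latent variable with class mean delta is cut at the
    thresholds implied by the baseline category probabilities, so for a
    binary split at any grade the class shift equals delta — the exact
    ordinal analog of the dichotomous log-odds shift.
    """
    cum = np.cumsum(base)[:-1]
    cuts = np.log(cum / (1.0 - cum))
    u = rng.uniform(1e-12, 1 - 1e-12)
    latent = np.log(u / (1.0 - u)) + delta
    return int(np.sum(latent > cuts))


def generate_clinical(
    class_label: int, effect: EffectSpec, seed: int | np.random.Generator
) -> ClinicalRecord:
    """Draw one clinical record from class-conditional distributions.

    Metastasis indicators and T/N stages and differentiation shift with
    ``clinical_effect`` (log-odds scale) for KRAS+; sex, age and tumor
    location are class-independent; M stage is 1 iff any distant
    metastasis was drawn, so it inherits the class shift.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    delta = effect.clinical_effect if class_label == 1 else 0.0
    liver = int(rng.random() < _shift_logit(_P_LIVER, delta))
    lung = int(rng.random() < _shift_logit(_P_LUNG, delta))
    sex = int(rng.random() < _P_SEX)
    age = float(np.clip(np.round(rng.normal(_AGE_MEAN, _AGE_SD)), 30, 95))
    location = int(rng.integers(_N_LOCATIONS))
    t_stage = _ordinal_sample(_T_BASE, delta, rng)
    n_stage = _ordinal_sample(_N_BASE, delta, rng)
    m_stage = int(liver or lung)
    differentiation = 1 + _ordinal_sample(_DIFF_BASE, delta, rng)
    return ClinicalRecord(
        liver_met=liver, lung_met=lung, sex=sex, age=age, location=location,
        t_stage=t_stage, n_stage=n_stage, m_stage=m_stage,
        differentiation=differentiation,
    )


def _patient_masks(size: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Central cut carries the full outline; neighbors are eroded copies."""
    central = generate_mask(size, rng)
    masks = {"central": central}
    for role in ("caudal", "cranial"):
        eroded = ndimage.binary_erosion(central, np.ones((3, 3), dtype=bool))
        labels, n = ndimage.label(eroded, structure=np.ones((3, 3), dtype=int))
        if n >= 1:
            sizes = ndimage.sum_labels(
                np.ones_like(labels), labels, index=np.arange(1, n + 1)
            )
            eroded = labels == (1 + int(np.argmax(sizes)))
        if eroded.sum() < 16:
            eroded = central
        masks[role] = eroded
    return masks


def generate_patient(
    patient_id: str, class_label: int, effect: EffectSpec, seed_seq: np.random.SeedSequence
) -> Patient:
    rng = np.random.default_rng(seed_seq)
    masks = _patient_masks(effect.image_size, rng)
    sigma = class_kernel_width(class_label, effect) * float(
        np.exp(rng.normal(0.0, PATIENT_JITTER_SD))
    )
    slices = tuple(
        RoiSlice(
            image=_texture_from_rng(effect.image_size, sigma, rng),
            mask=masks[role],
            role=role,
        )
        for role in SLICE_ROLES
    )
    clinical = generate_clinical(class_label, effect, rng)
    return Patient(patient_id=patient_id, slices=slices, clinical=clinical,
                   label=class_label)


def generate_cohort(effect: EffectSpec, out_dir: str | Path | None = None) -> list[Patient]:
    """Generate the full phantom cohort; optionally write TIFFs + manifest.

    Patients P001..P0xx are the KRAS+ block followed by the KRAS−
    block. Every patient derives its own random stream from
    (effect.seed, patient index), so the cohort is reproducible and
    individual patients are independent.
    """
    labels = [1] * effect.n_pos + [0] * effect.n_neg
    patients = [
        generate_patient(
            f"P{idx + 1:03d}", label, effect,
            np.random.SeedSequence([int(effect.seed) & 0x7FFFFFFF, idx]),
        )
        for idx, label in enumerate(labels)
    ]
    if out_dir is not None:
        write_cohort(patients, out_dir)
    return patients


def null_cohort(seed: int, n_pos: int = 30, n_neg: int = 26, image_size: int = 64) -> list[Patient]:
    """Cohort with no class signal at all (both effects 0)."""
    return generate_cohort(
        EffectSpec(texture_effect=0.0, clinical_effect=0.0, n_pos=n_pos,
                   n_neg=n_neg, image_size=image_size, seed=seed)
    )
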