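"""Clinical record encoding.

Each patient carries nine clinical values alongside the imaging data:
presence of liver and lung metastases, sex, age, tumor location, TNM
staging (T 0-4, N 0-2, M 0-1) and tumor differentiation grade (1-4).
These are encoded into a fixed-order 9-value feature vector that can be
used alone or concatenated in front of any texture descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .features import FeatureVector

CLINICAL_FIELDS = (
    "liver_met",
    "lung_met",
    "sex",
    "age",
    "location",
    "t_stage",
    "n_stage",
    "m_stage",
    "differentiation",
)

#: valid integer range per field (age is continuous and range-checked loosely)
_RANGES = {
    "liver_met": (0, 1),
    "lung_met": (0, 1),
    "sex": (0, 1),
    "age": (0, 130),
    "location": (0, 10),
    "t_stage": (0, 4),
    "n_stage": (0, 2),
    "m_stage": (0, 1),
    "differentiation": (1, 4),
}


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical variables.

    ``location`` is an integer tumor-site code (0 = right colon,
    1 = transverse, 2 = left colon, 3 = sigmoid/rectum by convention of
    the synthetic generator); it is kept as a single integer rather than
    one-hot so the encoded vector has exactly nine entries.
    """

    liver_met: int
    lung_met: int
    sex: int
    age: float
    location: int
    t_stage: int
    n_stage: int
    m_stage: int
    differentiation: int

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = _RANGES[f.name]
            v = getattr(self, f.name)
            if not np.isfinite(v) or not (lo <= v <= hi):
                raise ValueError(
                    f"clinical field {f.name}={v!r} outside valid range [{lo}, {hi}]"
                )


def encode_clinical(record: ClinicalRecord) -> FeatureVector:
    """Encode a validated record as the 9-value clinical feature vector.

    Order is fixed: liver_met, lung_met, sex, age, location, t_stage,
    n_stage, m_stage, differentiation. Binary fields map to {0, 1},
    ordinals to their integer codes; age passes through unscaled
    (standardization happens per cross-validation fold in the harness).
    """
    values = np.array([float(getattr(record, f)) for f in CLINICAL_FIELDS])
    return FeatureVector("clinical", values)


def concat_features(clinical: FeatureVector, texture: FeatureVector) -> FeatureVector:
    """Concatenate clinical values in front of a texture descriptor."""
    values = np.concatenate([clinical.values, texture.values])
    return FeatureVector(f"{clinical.descriptor_id}+{texture.descriptor_id}", values)
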