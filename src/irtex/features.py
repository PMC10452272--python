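"""Named feature vectors — the common currency of every extractor."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, finite descriptor output with a stable identifier."""

    descriptor_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("feature vector must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.descriptor_id}: non-finite feature values")

    def __len__(self) -> int:
        return self.values.size
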