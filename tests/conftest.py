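import numpy as np
import pytest

from irtex import EffectSpec, RoiSlice, generate_cohort, generate_mask, generate_texture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def roi_slice():
    """One deterministic 64x64 synthetic tumor slice."""
    spec = EffectSpec(seed=5)
    image = generate_texture(64, 0, spec, seed=5)
    mask = generate_mask(64, seed=5)
    return RoiSlice(image=image, mask=mask, role="central")


@pytest.fixture(scope="session")
def tiny_cohort():
    """10-patient cohort with texture and clinical signal, for harness tests."""
    return generate_cohort(
        EffectSpec(texture_effect=1.0, clinical_effect=2.0, n_pos=5, n_neg=5, seed=42)
    )


def random_masked_image(rng, size, min_roi=20):
    """Random gray image + random blob-ish mask with at least min_roi pixels."""
    image = rng.integers(0, 64, size=(size, size))
    while True:
        mask = rng.random((size, size)) < 0.7
        if mask.sum() >= min_roi:
            return image, mask
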