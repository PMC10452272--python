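"""Extract all 27 texture descriptors from one tumor slice.

Every descriptor is restricted to the irregular ROI: co-occurrence
pairs need both endpoints inside the mask, LBP centers need all sampled
neighbors inside it, and wavelet statistics use per-level downsampled
masks. The printed lengths are the documented dimensionalities
(e.g. DWT = 4 statistics x 13 regions = 52).
"""

from irtex import EffectSpec, RoiSlice, generate_mask, generate_texture
from irtex.texture import enumerate_texture_configs

spec = EffectSpec(seed=3)
roi = RoiSlice(image=generate_texture(64, 0, spec, seed=3),
               mask=generate_mask(64, seed=3), role="central")
print(f"slice: 64x64, ROI of {roi.roi_size} pixels\n")

print(f"{'descriptor':<14} {'len':>4}  first three values")
for cfg in enumerate_texture_configs():
    vec = cfg.extract(roi)
    head = ", ".join(f"{v:.4g}" for v in vec.values[:3])
    print(f"{vec.descriptor_id:<14} {len(vec):>4}  [{head}, ...]")

print("\n27 descriptors; Haralick entries are energy/correlation/contrast/"
      "homogeneity(/entropy) of the orientation-averaged masked GLCM.")
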