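"""Texture descriptors over irregular regions of interest.

All statistics are restricted to the irregular pixel set S delineating
the tumor; global/frequency techniques that need rectangular support are
deliberately absent. Six descriptor families are implemented:

* ``Hf_dm`` — Haralick coefficients of the orientation-averaged
  gray-level co-occurrence matrix (GLCM) at pixel distance d ∈ {1,2,3}
  or the d = 123 concatenation, with m ∈ {4,5} coefficients
  (energy, correlation, contrast, homogeneity, optionally entropy).
* ``LBP_R`` — rotation-invariant uniform local binary patterns with
  8 neighbors at radius R ∈ {1,2,3} (10-bin histogram) or the 30-value
  R = 123 concatenation.
* ``DWT`` — mean/energy/entropy/standard deviation of the wavelet
  coefficients in the ROI of the original image and each of the 12
  subbands of a 3-level decomposition: 4 × 13 = 52 features.
* ``WCF_dm`` — Haralick coefficients at distance d on the four
  first-level wavelet subbands (4m features).
* ``WDCF_fm`` — Haralick coefficients at distance 1 across decomposition
  levels, either the three LL approximations (f = LL, 3m features) or
  all 12 subbands (f = All, 12m features); scale is carried by the
  dyadic downsampling instead of the GLCM distance.
* ``LBP_s`` — radius-1 LBP on the level-s low-pass approximation
  (10 features; 30 for s = 123).

Exactly 27 configurations exist: 8 Hf + 4 LBP_R + 4 LBP_s + 1 DWT +
6 WCF + 4 WDCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy.ndimage import map_coordinates

from .cohort import RoiSlice
from .features import FeatureVector

#: GLCM gray-level quantization depth. Unstated upstream; 64 keeps the
#: matrix well-populated for ROIs of a few hundred pixels.
DEFAULT_LEVELS = 64
#: orientations averaged for rotation invariance, degrees
DEFAULT_ORIENTATIONS = (0, 45, 90, 135)
DEFAULT_WAVELET = "haar"  # shortest support -> least leakage across the mask edge
WAVELET_LEVELS = 3
ENTROPY_BINS = 64

# displacement (drow, dcol) per orientation at unit distance
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


# ---------------------------------------------------------------------------
# quantization and GLCM


def quantize(image: np.ndarray, mask: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Map the in-ROI gray range linearly onto {0..levels-1}.

    Uniform binning of the in-ROI min–max range; the in-ROI maximum maps
    to ``levels - 1``. A constant ROI maps to all zeros (convention).
    Out-of-ROI pixels are set to 0 and never enter any statistic.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(image.shape, dtype=np.int64)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
        out[mask] = np.clip(q[mask], 0, levels - 1)
    return out


@dataclass(frozen=True)
class Glcm:
    """Normalized, symmetric, orientation-averaged co-occurrence matrix."""

    matrix: np.ndarray = field(repr=False)
    d: int
    orientations: tuple[int, ...]

    def __post_init__(self) -> None:
        total = float(self.matrix.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM not normalized (sum={total})")


def compute_glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    d: int,
    orientations: Sequence[int] = DEFAULT_ORIENTATIONS,
    levels: int | None = None,
) -> Glcm:
    """Masked GLCM: a pixel pair contributes only if BOTH endpoints are in S.

    Pairs are counted symmetrically; the raw count matrices of the four
    orientations are pooled and normalized once, which is the
    rotation-invariance averaging step.
    """
    if d < 1:
        raise ValueError("distance d must be >= 1")
    quantized = np.asarray(quantized)
    mask = np.asarray(mask, dtype=bool)
    n_levels = int(levels) if levels is not None else int(quantized[mask].max()) + 1
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    h, w = quantized.shape
    for angle in orientations:
        sr, sc = _ANGLE_STEPS[angle]
        dr, dc = sr * d, sc * d
        # overlap window of the image with itself shifted by (dr, dc)
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        m = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a = quantized[r0:r1, c0:c1][m]
        b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc][m]
        pair = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        counts += pair.reshape(n_levels, n_levels)
    counts = counts + counts.T  # symmetric pairing
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"no valid pixel pairs in ROI at distance {d}: ROI too small or fragmented"
        )
    return Glcm(matrix=counts / total, d=d, orientations=tuple(orientations))


HARALICK_NAMES = ("energy", "correlation", "contrast", "homogeneity", "entropy")


def haralick_coeffs(glcm: Glcm, m: int = 5) -> FeatureVector:
    """Haralick coefficients of a normalized GLCM.

    Returns [energy, correlation, contrast, homogeneity] and, for m = 5,
    entropy (natural log, 0·ln 0 = 0). Correlation of a zero-variance
    matrix is defined as 0.
    """
    if m not in (4, 5):
        raise ValueError("m must be 4 or 5")
    p = glcm.matrix
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    energy = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    values = [energy, correlation, contrast, homogeneity]
    if m == 5:
        nz = p[p > 0]
        values.append(float(-(nz * np.log(nz)).sum()))
    return FeatureVector(f"haralick_m{m}", np.array(values))


def hf_vector(
    roi: RoiSlice,
    d: int | str,
    m: int,
    levels: int = DEFAULT_LEVELS,
    orientations: Sequence[int] = DEFAULT_ORIENTATIONS,
) -> FeatureVector:
    """Haralick descriptor Hf_dm; d = "123" concatenates d = 1, 2, 3."""
    q = quantize(roi.image, roi.mask, levels)
    distances = (1, 2, 3) if str(d) == "123" else (int(d),)
    parts = [
        haralick_coeffs(
            compute_glcm(q, roi.mask, dist, orientations, levels=levels), m
        ).values
        for dist in distances
    ]
    return FeatureVector(f"Hf_d{d}m{m}", np.concatenate(parts))


# ---------------------------------------------------------------------------
# local binary patterns


def _lbp_offsets(radius: float, n_points: int = 8) -> np.ndarray:
    k = np.arange(n_points)
    theta = 2.0 * np.pi * k / n_points
    return np.stack([-radius * np.sin(theta), radius * np.cos(theta)], axis=1)


def _is_uniform(bits: np.ndarray) -> np.ndarray:
    """<= 2 circular 0/1 transitions; bits has shape (..., P)."""
    rolled = np.roll(bits, -1, axis=-1)
    return (bits != rolled).sum(axis=-1) <= 2


def lbp_hist(
    image: np.ndarray, mask: np.ndarray, radius: float, n_points: int = 8
) -> FeatureVector:
    """Rotation-invariant uniform LBP histogram restricted to the ROI.

    Each neighbor is sampled by bilinear interpolation at radius
    ``radius``; a neighbor at or above the center's gray level
    contributes a 1-bit. Uniform patterns (<= 2 circular transitions)
    fall into bins 0..8 by their number of 1-bits; every non-uniform
    pattern falls into bin 9. A center is valid only when the center
    pixel and every pixel touched by the 8 bilinear interpolations lie
    inside S, so tumor texture is never contaminated by background;
    this effectively erodes the ROI by the radius. The histogram is
    normalized over valid centers.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    offsets = _lbp_offsets(radius, n_points)
    rows, cols = np.nonzero(mask)
    centers = image[rows, cols]
    bits = np.empty((rows.size, n_points), dtype=bool)
    valid = np.ones(rows.size, dtype=bool)
    maskf = mask.astype(float)
    for k, (dr, dc) in enumerate(offsets):
        coords = np.stack([rows + dr, cols + dc])
        sample = map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
        inside = map_coordinates(maskf, coords, order=1, mode="constant", cval=0.0)
        # bilinear interp of the 0/1 mask equals 1 iff every pixel with
        # nonzero weight is in S
        valid &= inside > 1.0 - 1e-9
        bits[:, k] = sample >= centers - 1e-9
    if not np.any(valid):
        raise ValueError(
            f"no valid LBP centers at radius {radius}: ROI too small or thin"
        )
    bits = bits[valid]
    codes = np.where(_is_uniform(bits), bits.sum(axis=1), n_points + 1)
    hist = np.bincount(codes, minlength=n_points + 2).astype(float)
    return FeatureVector(f"lbp_r{radius:g}", hist / hist.sum())


def lbp_vector(roi: RoiSlice, radius: int | str) -> FeatureVector:
    """LBP_R descriptor; R = "123" concatenates radii 1, 2, 3 (30 values)."""
    radii = (1, 2, 3) if str(radius) == "123" else (int(radius),)
    parts = [lbp_hist(roi.image, roi.mask, r).values for r in radii]
    return FeatureVector(f"LBP_R{radius}", np.concatenate(parts))


# ---------------------------------------------------------------------------
# wavelet decomposition and hybrid descriptors

SUBBAND_NAMES = ("LL", "LH", "HL", "HH")


def _downsample_mask(mask: np.ndarray) -> np.ndarray:
    """A coarse pixel is in-ROI iff ANY pixel of its 2x2 block is."""
    h, w = mask.shape
    if h % 2 or w % 2:  # pad to even with background
        padded = np.zeros((h + h % 2, w + w % 2), dtype=bool)
        padded[:h, :w] = mask
        mask = padded
    return mask[0::2, 0::2] | mask[1::2, 0::2] | mask[0::2, 1::2] | mask[1::2, 1::2]


def wavelet_decompose(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = WAVELET_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
) -> list[dict[str, np.ndarray]]:
    """Recursive 2-D DWT with per-level mask downsampling.

    Returns one dict per level l = 1..levels with keys LL, LH, HL, HH
    and ``mask`` (the ROI downsampled l times); LL of level l-1 is
    decomposed to produce level l. Periodized filtering keeps subband
    sides exactly halved.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if min(image.shape) < 2**levels:
        raise ValueError(f"image sides must be >= {2**levels} for {levels} levels")
    out: list[dict[str, np.ndarray]] = []
    ll = image
    m = mask
    for level in range(1, levels + 1):
        ll, (lh, hl, hh) = pywt.dwt2(ll, wavelet, mode="periodization")
        m = _downsample_mask(m)
        if not np.any(m):
            raise ValueError(f"ROI mask vanished at decomposition level {level}")
        out.append({"LL": ll, "LH": lh, "HL": hl, "HH": hh, "mask": m})
    return out


def _region_stats(values: np.ndarray) -> list[float]:
    """mean, energy, entropy, SD of in-mask coefficients.

    Energy is the mean squared coefficient; entropy uses a 64-bin
    equal-width histogram over the in-mask range (0·ln 0 = 0, constant
    region -> 0); SD is the population standard deviation.
    """
    mean = float(values.mean())
    energy = float((values**2).mean())
    lo, hi = values.min(), values.max()
    if hi > lo:
        hist, _ = np.histogram(values, bins=ENTROPY_BINS, range=(lo, hi))
        p = hist[hist > 0] / values.size
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0
    return [mean, energy, entropy, float(values.std())]


def dwt_vector(roi: RoiSlice, wavelet: str = DEFAULT_WAVELET) -> FeatureVector:
    """52-value wavelet statistics descriptor.

    Four measures (mean, energy, entropy, SD) over 13 regions: the
    original in-ROI image and the 12 subbands of a 3-level
    decomposition, each restricted to its downsampled mask.
    """
    bands = wavelet_decompose(roi.image, roi.mask, WAVELET_LEVELS, wavelet)
    regions = [np.asarray(roi.image, dtype=float)[roi.mask]]
    for lvl in bands:
        for name in SUBBAND_NAMES:
            regions.append(lvl[name][lvl["mask"]])
    values = np.concatenate([_region_stats(r) for r in regions])
    return FeatureVector("DWT", values)


def _subband_haralick(
    band: np.ndarray, mask: np.ndarray, d: int, m: int, levels: int, orientations
) -> np.ndarray:
    q = quantize(band, mask, levels)
    return haralick_coeffs(compute_glcm(q, mask, d, orientations, levels=levels), m).values


def wdcf_vector(
    roi: RoiSlice,
    f: str,
    m: int,
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    orientations: Sequence[int] = DEFAULT_ORIENTATIONS,
) -> FeatureVector:
    """Wavelet-decomposition Haralick descriptor WDCF_fm.

    Haralick coefficients at distance d = 1 on each selected subband
    (scale is carried by the downsampling). f = "LL": the three
    low-pass approximations LL_1..LL_3 (3m values); f = "All": all 12
    subbands in level-major LL, LH, HL, HH order (12m values).
    """
    if f not in ("LL", "All"):
        raise ValueError("f must be 'LL' or 'All'")
    bands = wavelet_decompose(roi.image, roi.mask, WAVELET_LEVELS, wavelet)
    selected = []
    for lvl in bands:
        names = SUBBAND_NAMES if f == "All" else ("LL",)
        selected.extend((lvl[name], lvl["mask"]) for name in names)
    parts = [
        _subband_haralick(band, mask, 1, m, levels, orientations)
        for band, mask in selected
    ]
    return FeatureVector(f"WDCF_f{f}m{m}", np.concatenate(parts))


def wcf_vector(
    roi: RoiSlice,
    d: int,
    m: int,
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    orientations: Sequence[int] = DEFAULT_ORIENTATIONS,
) -> FeatureVector:
    """First-level wavelet Haralick descriptor WCF_dm (4m values)."""
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    lvl1 = wavelet_decompose(roi.image, roi.mask, 1, wavelet)[0]
    parts = [
        _subband_haralick(lvl1[name], lvl1["mask"], d, m, levels, orientations)
        for name in SUBBAND_NAMES
    ]
    return FeatureVector(f"WCF_d{d}m{m}", np.concatenate(parts))


def wavelet_lbp_vector(
    roi: RoiSlice, s: int | str, wavelet: str = DEFAULT_WAVELET
) -> FeatureVector:
    """LBP_s: radius-1 LBP on the level-s low-pass approximation."""
    scales = (1, 2, 3) if str(s) == "123" else (int(s),)
    bands = wavelet_decompose(roi.image, roi.mask, max(scales), wavelet)
    parts = [
        lbp_hist(bands[sc - 1]["LL"], bands[sc - 1]["mask"], 1.0).values
        for sc in scales
    ]
    return FeatureVector(f"LBP_s{s}", np.concatenate(parts))


# ---------------------------------------------------------------------------
# configuration registry


@dataclass(frozen=True)
class TextureConfig:
    """One of the 27 descriptor configurations."""

    family: str  # Hf | LBP_R | LBP_s | DWT | WCF | WDCF
    d: int | str | None = None
    m: int | None = None
    R: int | str | None = None
    s: int | str | None = None
    f: str | None = None

    @property
    def descriptor_id(self) -> str:
        if self.family == "Hf":
            return f"Hf_d{self.d}m{self.m}"
        if self.family == "LBP_R":
            return f"LBP_R{self.R}"
        if self.family == "LBP_s":
            return f"LBP_s{self.s}"
        if self.family == "DWT":
            return "DWT"
        if self.family == "WCF":
            return f"WCF_d{self.d}m{self.m}"
        if self.family == "WDCF":
            return f"WDCF_f{self.f}m{self.m}"
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def length(self) -> int:
        if self.family == "Hf":
            return (3 if str(self.d) == "123" else 1) * self.m
        if self.family in ("LBP_R", "LBP_s"):
            r = self.R if self.family == "LBP_R" else self.s
            return 30 if str(r) == "123" else 10
        if self.family == "DWT":
            return 52
        if self.family == "WCF":
            return 4 * self.m
        if self.family == "WDCF":
            return (12 if self.f == "All" else 3) * self.m
        raise ValueError(self.family)

    def extract(self, roi: RoiSlice) -> FeatureVector:
        if self.family == "Hf":
            return hf_vector(roi, self.d, self.m)
        if self.family == "LBP_R":
            return lbp_vector(roi, self.R)
        if self.family == "LBP_s":
            return wavelet_lbp_vector(roi, self.s)
        if self.family == "DWT":
            return dwt_vector(roi)
        if self.family == "WCF":
            return wcf_vector(roi, self.d, self.m)
        if self.family == "WDCF":
            return wdcf_vector(roi, self.f, self.m)
        raise ValueError(self.family)


def enumerate_texture_configs() -> list[TextureConfig]:
    """The 27 descriptor configurations in stable order.

    8 Hf (d = 1,2,3,123 x m = 4,5), 4 LBP_R (R = 1,2,3,123),
    4 LBP_s (s = 1,2,3,123), 1 DWT, 6 WCF (d = 1,2,3 x m = 4,5),
    4 WDCF (f = LL,All x m = 4,5).
    """
    configs: list[TextureConfig] = []
    for d in (1, 2, 3, "123"):
        for m in (4, 5):
            configs.append(TextureConfig(family="Hf", d=d, m=m))
    for r in (1, 2, 3, "123"):
        configs.append(TextureConfig(family="LBP_R", R=r))
    for s in (1, 2, 3, "123"):
        configs.append(TextureConfig(family="LBP_s", s=s))
    configs.append(TextureConfig(family="DWT"))
    for d in (1, 2, 3):
        for m in (4, 5):
            configs.append(TextureConfig(family="WCF", d=d, m=m))
    for f in ("LL", "All"):
        for m in (4, 5):
            configs.append(TextureConfig(family="WDCF", f=f, m=m))
    return configs


def get_texture_config(descriptor_id: str) -> TextureConfig:
    for cfg in enumerate_texture_configs():
        if cfg.descriptor_id == descriptor_id:
            return cfg
    raise KeyError(f"unknown descriptor id {descriptor_id!r}")
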