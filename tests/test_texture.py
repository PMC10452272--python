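"""Texture descriptors: hand-worked examples, brute-force oracles,
invariances, and the 27-configuration catalogue."""

import numpy as np
import pytest

from irtex.cohort import RoiSlice
from irtex.texture import (
    DEFAULT_ORIENTATIONS,
    Glcm,
    compute_glcm,
    dwt_vector,
    enumerate_texture_configs,
    get_texture_config,
    haralick_coeffs,
    hf_vector,
    lbp_hist,
    lbp_vector,
    quantize,
    wavelet_decompose,
    wavelet_lbp_vector,
    wcf_vector,
    wdcf_vector,
)
from conftest import random_masked_image

# ---------------------------------------------------------------------------
# independent brute-force oracles


def glcm_oracle(q, mask, d, orientations):
    """Exhaustive double loop over all pixel pairs, symmetric counts."""
    steps = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    n = int(q[mask].max()) + 1
    counts = np.zeros((n, n))
    h, w = q.shape
    for angle in orientations:
        sr, sc = steps[angle]
        for r in range(h):
            for c in range(w):
                r2, c2 = r + sr * d, c + sc * d
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def lbp_oracle(image, mask, radius):
    """Per-pixel LBP coder with manual bilinear interpolation."""
    def bilinear(img, r, c):
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        dr, dc = r - r0, c - c0
        total = 0.0
        for (rr, cc, w) in [(r0, c0, (1 - dr) * (1 - dc)), (r0, c0 + 1, (1 - dr) * dc),
                            (r0 + 1, c0, dr * (1 - dc)), (r0 + 1, c0 + 1, dr * dc)]:
            if w > 1e-12:
                if not (0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]):
                    return None  # touches outside the frame
                if not mask[rr, cc]:
                    return None  # touches background
                total += w * img[rr, cc]
        return total

    img = image.astype(float)
    hist = np.zeros(10)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if not mask[r, c]:
                continue
            bits = []
            for k in range(8):
                theta = 2 * np.pi * k / 8
                v = bilinear(img, r - radius * np.sin(theta), c + radius * np.cos(theta))
                if v is None:
                    bits = None
                    break
                bits.append(1 if v >= img[r, c] - 1e-9 else 0)
            if bits is None:
                continue
            transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
            hist[sum(bits) if transitions <= 2 else 9] += 1
    return hist / hist.sum()


# ---------------------------------------------------------------------------


class TestQuantize:
    def test_full_range_maps_to_top_level(self):
        img = np.arange(256).reshape(16, 16)
        q = quantize(img, np.ones_like(img, bool), 64)
        assert q.max() == 63 and q.min() == 0

    def test_constant_roi_maps_to_zero(self):
        img = np.full((8, 8), 7)
        assert quantize(img, np.ones_like(img, bool), 64).max() == 0

    def test_two_valued_roi(self):
        img = np.where(np.indices((8, 8)).sum(0) % 2 == 0, 10, 200)
        q = quantize(img, np.ones_like(img, bool), 2)
        assert set(np.unique(q)) == {0, 1}
        assert np.all((q == 1) == (img == 200))


class TestGlcm:
    def test_two_by_two_hand_count(self):
        # [[0,1],[0,1]] with d=1 horizontally: two (0,1) pairs, symmetric
        img = np.array([[0, 1], [0, 1]])
        mask = np.ones((2, 2), bool)
        g = compute_glcm(img, mask, d=1, orientations=(0,), levels=2)
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)
        assert g.matrix[0, 0] == g.matrix[1, 1] == 0

    def test_constant_roi_single_entry(self):
        img = np.zeros((8, 8), int)
        g = compute_glcm(img, np.ones((8, 8), bool), d=1, levels=1)
        assert g.matrix[0, 0] == pytest.approx(1.0)

    def test_entries_sum_to_one(self, rng):
        img, mask = random_masked_image(rng, 12)
        g = compute_glcm(img, mask, d=2)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_degenerate_pairs_raise(self):
        mask = np.zeros((8, 8), bool)
        mask[::2, ::2] = True  # isolated pixels: every d=1 offset is odd
        with pytest.raises(ValueError, match="pair"):
            compute_glcm(np.zeros((8, 8), int), mask, d=1)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, rng, d):
        for _ in range(25):
            img, mask = random_masked_image(rng, 8)
            q = quantize(img, mask, 8)
            got = compute_glcm(q, mask, d)
            expected = glcm_oracle(q, mask, d, DEFAULT_ORIENTATIONS)
            n = expected.shape[0]
            assert np.allclose(got.matrix[:n, :n], expected, atol=1e-12)


class TestHaralick:
    def test_single_cell_matrix_degenerate_conventions(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        v = haralick_coeffs(Glcm(m, d=1, orientations=(0,)), m=5)
        energy, correlation, contrast, homogeneity, entropy = v.values
        assert energy == 1 and contrast == 0 and homogeneity == 1
        assert entropy == 0 and correlation == 0

    def test_uniform_two_by_two_closed_form(self):
        m = np.full((2, 2), 0.25)
        v = haralick_coeffs(Glcm(m, d=1, orientations=(0,)), m=5)
        energy, correlation, contrast, homogeneity, entropy = v.values
        assert energy == pytest.approx(0.25)
        assert contrast == pytest.approx(0.5)
        assert entropy == pytest.approx(np.log(4))
        assert homogeneity == pytest.approx(0.75)
        assert correlation == pytest.approx(0.0)

    def test_m4_is_prefix_of_m5(self, rng):
        img, mask = random_masked_image(rng, 10)
        g = compute_glcm(quantize(img, mask, 16), mask, 1)
        v4 = haralick_coeffs(g, 4).values
        v5 = haralick_coeffs(g, 5).values
        assert np.allclose(v4, v5[:4])


class TestHfVector:
    @pytest.mark.parametrize("d,m,length", [(1, 4, 4), (2, 5, 5), ("123", 4, 12), ("123", 5, 15)])
    def test_lengths(self, roi_slice, d, m, length):
        assert len(hf_vector(roi_slice, d, m)) == length

    def test_concatenation_order(self, roi_slice):
        whole = hf_vector(roi_slice, "123", 4).values
        parts = [hf_vector(roi_slice, d, 4).values for d in (1, 2, 3)]
        assert np.allclose(whole, np.concatenate(parts))


class TestLbp:
    def test_constant_roi_all_mass_in_bin8(self):
        img = np.full((16, 16), 5)
        mask = np.ones((16, 16), bool)
        h = lbp_hist(img, mask, 1).values
        assert h[8] == pytest.approx(1.0)

    def test_histogram_normalized_length10(self, roi_slice):
        for r in (1, 2, 3):
            h = lbp_hist(roi_slice.image, roi_slice.mask, r).values
            assert h.size == 10 and h.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, rng, radius):
        for _ in range(15):
            img = rng.integers(0, 256, size=(16, 16))
            mask = rng.random((16, 16)) < 0.85
            try:
                got = lbp_hist(img, mask, radius).values
            except ValueError:
                continue  # no valid centers; oracle would agree
            assert np.allclose(got, lbp_oracle(img, mask, radius), atol=1e-12)

    def test_no_valid_centers_raises(self):
        mask = np.zeros((16, 16), bool)
        mask[::3, ::3] = True  # isolated pixels: neighbors always outside S
        with pytest.raises(ValueError, match="valid LBP centers"):
            lbp_hist(np.ones((16, 16)), mask, 1)

    @pytest.mark.parametrize("r,length", [(1, 10), ("123", 30)])
    def test_vector_lengths(self, roi_slice, r, length):
        assert len(lbp_vector(roi_slice, r)) == length

    def test_concatenation_order(self, roi_slice):
        whole = lbp_vector(roi_slice, "123").values
        parts = [lbp_vector(roi_slice, r).values for r in (1, 2, 3)]
        assert np.allclose(whole, np.concatenate(parts))


class TestWavelet:
    def test_dyadic_sizes(self, roi_slice):
        bands = wavelet_decompose(roi_slice.image, roi_slice.mask, 3)
        sides = [lvl["LL"].shape[0] for lvl in bands]
        assert sides == [32, 16, 8]
        assert all(lvl["mask"].shape == lvl["LL"].shape for lvl in bands)

    def test_constant_image_zero_details(self):
        img = np.full((32, 32), 9.0)
        bands = wavelet_decompose(img, np.ones((32, 32), bool), 3)
        for lvl in bands:
            for b in ("LH", "HL", "HH"):
                assert np.allclose(lvl[b], 0.0)

    def test_single_pixel_mask_survives_any_rule(self):
        mask = np.zeros((32, 32), bool)
        mask[17, 5] = True
        img = np.arange(32 * 32).reshape(32, 32).astype(float)
        bands = wavelet_decompose(img, mask, 3)
        for lvl in bands:
            assert lvl["mask"].sum() >= 1

    def test_dwt_vector_length_52(self, roi_slice):
        assert len(dwt_vector(roi_slice)) == 52

    def test_dwt_constant_image_detail_stats_zero(self):
        img = np.full((32, 32), 100)
        mask = np.ones((32, 32), bool)
        roi = RoiSlice(image=img, mask=mask, role="central")
        v = dwt_vector(roi).values.reshape(13, 4)
        # regions 1.. follow level-major LL, LH, HL, HH; detail rows have
        # zero mean/energy/entropy/SD
        for region in (2, 3, 4, 6, 7, 8, 10, 11, 12):
            assert np.allclose(v[region], 0.0)

    def test_dwt_statistics_match_per_subband_oracle(self, roi_slice):
        v = dwt_vector(roi_slice).values.reshape(13, 4)
        bands = wavelet_decompose(roi_slice.image, roi_slice.mask, 3)
        regions = [np.asarray(roi_slice.image, float)[roi_slice.mask]]
        for lvl in bands:
            for name in ("LL", "LH", "HL", "HH"):
                regions.append(lvl[name][lvl["mask"]])
        for i, vals in enumerate(regions):
            assert v[i, 0] == pytest.approx(vals.mean())
            assert v[i, 1] == pytest.approx(np.mean(vals**2))
            assert v[i, 3] == pytest.approx(vals.std())
            hist, _ = np.histogram(vals, bins=64, range=(vals.min(), vals.max()))
            p = hist[hist > 0] / vals.size
            expected_entropy = float(-(p * np.log(p)).sum()) if vals.min() < vals.max() else 0.0
            assert v[i, 2] == pytest.approx(expected_entropy)


class TestHybridVectors:
    @pytest.mark.parametrize("f,m,length", [("All", 4, 48), ("All", 5, 60),
                                            ("LL", 4, 12), ("LL", 5, 15)])
    def test_wdcf_lengths(self, roi_slice, f, m, length):
        assert len(wdcf_vector(roi_slice, f, m)) == length

    @pytest.mark.parametrize("d,m,length", [(1, 4, 16), (3, 5, 20)])
    def test_wcf_lengths(self, roi_slice, d, m, length):
        assert len(wcf_vector(roi_slice, d, m)) == length

    @pytest.mark.parametrize("s,length", [(2, 10), ("123", 30)])
    def test_wavelet_lbp_lengths(self, roi_slice, s, length):
        assert len(wavelet_lbp_vector(roi_slice, s)) == length

    def test_constant_image_zero_contrast(self):
        roi = RoiSlice(image=np.full((32, 32), 50), mask=np.ones((32, 32), bool),
                       role="central")
        for m, fam in ((4, "wcf"), (4, "wdcf")):
            vec = (wcf_vector(roi, 1, m) if fam == "wcf" else wdcf_vector(roi, "LL", m))
            contrasts = vec.values.reshape(-1, m)[:, 2]
            assert np.allclose(contrasts, 0.0)

    def test_wavelet_lbp_constant_image_bin8(self):
        roi = RoiSlice(image=np.full((32, 32), 50), mask=np.ones((32, 32), bool),
                       role="central")
        for s in (1, 2, 3):
            h = wavelet_lbp_vector(roi, s).values
            assert h[8] == pytest.approx(1.0)


class TestInvariances:
    def test_rotation_90_exact_for_d1(self, roi_slice):
        """Orientation-averaged d=1 Haralick is exact under 90° rotation."""
        rotated = RoiSlice(image=np.rot90(roi_slice.image).copy(),
                           mask=np.rot90(roi_slice.mask).copy(), role="central")
        v1 = hf_vector(roi_slice, 1, 5).values
        v2 = hf_vector(rotated, 1, 5).values
        assert np.allclose(v1, v2, atol=1e-12)

    def test_mask_locality_glcm_and_lbp(self, rng, roi_slice):
        """Features ignore arbitrary changes outside the ROI."""
        tampered_img = roi_slice.image.copy()
        tampered_img[~roi_slice.mask] = rng.integers(0, 256, size=(~roi_slice.mask).sum())
        tampered = RoiSlice(image=tampered_img, mask=roi_slice.mask, role="central")
        assert np.allclose(hf_vector(roi_slice, "123", 5).values,
                           hf_vector(tampered, "123", 5).values)
        assert np.allclose(lbp_vector(roi_slice, "123").values,
                           lbp_vector(tampered, "123").values)

    def test_mask_locality_wavelets_outside_filter_support(self, rng, roi_slice):
        """Wavelet statistics ignore pixels whose aligned 8x8 block (the
        level-3 Haar support) contains no ROI pixel."""
        h, w = roi_slice.mask.shape
        blocks = roi_slice.mask.reshape(h // 8, 8, w // 8, 8).any(axis=(1, 3))
        far = ~np.kron(blocks, np.ones((8, 8), dtype=bool)) & ~roi_slice.mask
        assert far.any()  # fixture mask leaves some untouched blocks
        tampered_img = roi_slice.image.copy()
        tampered_img[far] = rng.integers(0, 256, size=int(far.sum()))
        tampered = RoiSlice(image=tampered_img, mask=roi_slice.mask, role="central")
        assert np.allclose(dwt_vector(roi_slice).values, dwt_vector(tampered).values)
        assert np.allclose(wdcf_vector(roi_slice, "All", 5).values,
                           wdcf_vector(tampered, "All", 5).values)


class TestConfigCatalogue:
    def test_exactly_27_configs(self):
        assert len(enumerate_texture_configs()) == 27

    def test_family_counts(self):
        fams = [c.family for c in enumerate_texture_configs()]
        assert (fams.count("Hf"), fams.count("LBP_R"), fams.count("LBP_s"),
                fams.count("DWT"), fams.count("WCF"), fams.count("WDCF")) == \
            (8, 4, 4, 1, 6, 4)

    def test_ids_unique_and_stable(self):
        ids = [c.descriptor_id for c in enumerate_texture_configs()]
        assert len(set(ids)) == 27
        assert ids[0] == "Hf_d1m4" and "DWT" in ids and "WDCF_fAllm4" in ids

    def test_all_configs_finite_and_documented_length(self, roi_slice):
        for cfg in enumerate_texture_configs():
            vec = cfg.extract(roi_slice)
            assert len(vec) == cfg.length
            assert np.all(np.isfinite(vec.values))

    def test_lookup_roundtrip(self):
        for cfg in enumerate_texture_configs():
            assert get_texture_config(cfg.descriptor_id) == cfg
        with pytest.raises(KeyError):
            get_texture_config("nope")
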