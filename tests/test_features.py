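"""Vegetation indices and GLCM texture features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatcgi.features import (
    GLCMSpec,
    TEXTURE_NAMES,
    VI_NAMES,
    compute_vis,
    feature_table,
    glcm,
    patch_textures,
    quantize,
    texture_features,
)
from wheatcgi.imagery import BandMeans, QuadratPatch

from oracles import glcm_bruteforce, texture_bruteforce


def bm(b=0.05, g=0.2, r=0.1, re=0.3, nir=0.5):
    return BandMeans("q01", b, g, r, re, nir)


class TestVegetationIndices:
    def test_all_twelve_present(self):
        out = compute_vis(bm())
        assert set(VI_NAMES) <= set(out)

    def test_nir_equals_red_zeroes_difference_indices(self):
        out = compute_vis(bm(r=0.4, nir=0.4))
        assert out["NDVI"] == 0 and out["RDVI"] == 0 and out["DVI"] == 0

    def test_hand_values(self):
        out = compute_vis(bm(b=0.05, g=0.2, r=0.1, re=0.3, nir=0.5))
        assert out["NDVI"] == pytest.approx((0.5 - 0.1) / 0.6)
        assert out["RVI"] == pytest.approx(5.0)
        assert out["DVI"] == pytest.approx(0.4)
        assert out["TVI"] == pytest.approx(60 * 0.3 - 100 * (-0.1))  # 28.0
        assert out["EXR"] == pytest.approx(1.4 * 0.1 - 0.2)  # -0.06
        assert out["SAVI"] == pytest.approx(1.5 * 0.4 / 1.1)
        assert out["OSAVI"] == pytest.approx(1.16 * 0.4 / 0.76)
        assert out["NDRE"] == pytest.approx(0.2 / 0.8)
        assert out["NPCI"] == pytest.approx(0.05 / 0.15)
        assert out["EVI2"] == pytest.approx(0.4 / (1 + 0.5 + 0.24))
        assert out["MVI"] == pytest.approx(0.4 / math.sqrt(1.1))
        assert out["RDVI"] == pytest.approx(0.4 / math.sqrt(0.6))

    def test_zero_denominator_flags_nan_not_crash(self):
        out = compute_vis(BandMeans("q", 0.0, 0.2, 0.0, 0.3, 0.0))
        assert math.isnan(out["RVI"])
        assert math.isnan(out["NDVI"])
        assert math.isnan(out["NPCI"])

    @given(
        nir=st.floats(0.01, 1.0),
        nir2=st.floats(0.01, 1.0),
        r=st.floats(0.01, 1.0),
    )
    @settings(deadline=None)
    def test_ndvi_increasing_in_nir(self, nir, nir2, r):
        lo, hi = sorted((nir, nir2))
        v_lo = compute_vis(bm(r=r, nir=lo))["NDVI"]
        v_hi = compute_vis(bm(r=r, nir=hi))["NDVI"]
        assert v_hi >= v_lo - 1e-12  # slack for rounding at adjacent floats


class TestQuantize:
    def test_constant_band_all_zero(self):
        assert quantize(np.full((4, 4), 0.37)).max() == 0

    def test_range_endpoints(self):
        band = np.array([[0.1, 0.9], [0.1, 0.9]])
        codes = quantize(band, GLCMSpec(levels=32))
        assert set(codes.ravel()) == {0, 31}

    def test_ramp_monotone(self):
        band = np.linspace(0, 1, 64).reshape(8, 8)
        codes = quantize(band, GLCMSpec(levels=8)).ravel()
        assert (np.diff(codes.astype(int)) >= 0).all()
        assert codes.min() == 0 and codes.max() == 7

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.array([[0.1, np.nan]]))


class TestGLCM:
    def test_constant_patch_all_mass_at_origin(self):
        p = glcm(np.zeros((2, 2), dtype=np.uint8), GLCMSpec(levels=4))
        assert p[0, 0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_two_column_patch_single_offset(self):
        codes = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        p = glcm(codes, GLCMSpec(levels=2, angles_deg=(0.0,)))
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])

    def test_sum_to_one_random_patches(self, rng):
        spec = GLCMSpec(levels=8)
        for _ in range(20):
            codes = rng.integers(0, 8, size=(6, 6)).astype(np.uint8)
            assert glcm(codes, spec).sum() == pytest.approx(1.0)

    def test_symmetric_matrix(self, rng):
        codes = rng.integers(0, 8, size=(7, 7)).astype(np.uint8)
        p = glcm(codes, GLCMSpec(levels=8))
        np.testing.assert_allclose(p, p.T)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            glcm(np.zeros((1, 1), dtype=np.uint8), GLCMSpec(levels=2))

    def test_out_of_range_codes_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.full((3, 3), 9, dtype=np.uint8), GLCMSpec(levels=8))


class TestTextureFeatures:
    def test_constant_image_degenerate_values(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        out = texture_features(p)
        assert out == {
            "mean": 0.0, "var": 0.0, "con": 0.0, "dis": 0.0,
            "hom": 1.0, "ent": 0.0, "sm": 1.0, "corr": 0.0,
        }

    def test_antidiagonal_hand_values(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        out = texture_features(p)
        assert out["mean"] == pytest.approx(0.5)
        assert out["var"] == pytest.approx(0.25)
        assert out["con"] == pytest.approx(1.0)
        assert out["dis"] == pytest.approx(1.0)
        assert out["hom"] == pytest.approx(0.5)
        assert out["ent"] == pytest.approx(math.log(2))
        assert out["sm"] == pytest.approx(0.5)
        assert out["corr"] == pytest.approx(-1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            texture_features(np.ones((3, 3)))

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(25):
            raw = rng.uniform(0, 1, size=(5, 5))
            p = raw / raw.sum()
            got = texture_features(p)
            want = texture_bruteforce(p)
            for name in TEXTURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-12)


class TestPatchTextures:
    def make_patch(self, rng, size=10):
        return QuadratPatch("q05", rng.uniform(0.05, 0.6, size=(size, size, 5)))

    def test_two_band_records_with_eight_features(self, rng):
        recs = patch_textures(self.make_patch(rng))
        assert [r["band"] for r in recs] == ["red", "green"]
        for r in recs:
            assert set(TEXTURE_NAMES) <= set(r)

    def test_deterministic(self, rng):
        patch = self.make_patch(rng)
        assert patch_textures(patch) == patch_textures(patch)

    def test_pixel_permutation_changes_spatial_features(self, rng):
        patch = self.make_patch(rng)
        arr = patch.array.copy()
        flat = arr.reshape(-1, 5)
        perm = rng.permutation(flat.shape[0])
        shuffled = QuadratPatch("q05", flat[perm].reshape(arr.shape))
        a = patch_textures(patch)[0]
        b = patch_textures(shuffled)[0]
        # same histogram by construction, different arrangement
        assert a["con"] != pytest.approx(b["con"])
        assert a["hom"] != pytest.approx(b["hom"])


def test_feature_table_columns(default_dataset):
    table = feature_table(default_dataset.patches[:4])
    assert len(table) == 4
    for col in ("quadrat_id", "red", "nir", "NDVI", "MVI", "red_con", "green_ent"):
        assert col in table.columns
    assert table.shape[1] == 1 + 5 + 12 + 16
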