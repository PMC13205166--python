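"""Texture feature families: first-order, GLCM/Haralick, LBP-TOP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petct_radiomics.io import VolumePair
from petct_radiomics.texture import (
    FIRST_ORDER_NAMES,
    GLCM_OFFSETS,
    HARALICK_NAMES,
    extract_all,
    feature_names,
    first_order,
    glcm_features,
    glcm_pair_counts,
    lbp_top_features,
    quantize,
)


from oracles import brute_force_pair_counts


def _full(values):
    v = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return v, np.ones_like(v, dtype=bool)


class TestFirstOrder:
    def test_hand_example(self):
        vol, mask = _full([1.0, 2.0, 3.0, 4.0])
        f = first_order(vol, mask)
        assert f["mean"] == 2.5
        assert f["variance"] == 1.25  # population variance
        assert f["range"] == 3.0
        assert f["energy"] == 30.0
        assert f["minimum"] == 1.0 and f["maximum"] == 4.0

    def test_constant_region_conventions(self):
        vol, mask = _full([3.0] * 8)
        f = first_order(vol, mask)
        assert f["mean"] == 3.0
        assert f["variance"] == 0.0
        assert f["range"] == 0.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["entropy"] == 0.0

    def test_twelve_features_in_order(self):
        vol, mask = _full([1.0, 2.0])
        assert tuple(first_order(vol, mask)) == FIRST_ORDER_NAMES
        assert len(FIRST_ORDER_NAMES) == 12

    def test_against_direct_formulas(self, rng):
        vol = rng.normal(5, 2, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.6
        x = vol[mask]
        f = first_order(vol, mask)
        assert f["mean"] == pytest.approx(x.mean())
        assert f["median"] == pytest.approx(np.median(x))
        assert f["variance"] == pytest.approx(x.var())
        z = (x - x.mean()) / x.std()
        assert f["skewness"] == pytest.approx((z**3).mean())
        assert f["kurtosis"] == pytest.approx((z**4).mean() - 3)
        assert f["energy"] == pytest.approx((x**2).sum())
        assert f["p10"] == pytest.approx(np.percentile(x, 10))
        assert f["p90"] == pytest.approx(np.percentile(x, 90))
        counts, _ = np.histogram(x, bins=64, range=(x.min(), x.max()))
        p = counts[counts > 0] / x.size
        assert f["entropy"] == pytest.approx(-(p * np.log2(p)).sum())

    def test_invariant_to_voxel_permutation(self, rng):
        vol = rng.random((5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.5
        shuffled = vol.copy()
        vals = shuffled[mask]
        shuffled[mask] = rng.permutation(vals)
        a = first_order(vol, mask)
        b = first_order(shuffled, mask)
        for name in FIRST_ORDER_NAMES:
            assert a[name] == pytest.approx(b[name])


class TestQuantize:
    def test_twelve_bit_range(self):
        vol, mask = _full(np.arange(4096))
        q = quantize(vol, mask, ng=32)
        assert q.levels.flat[0] == 0
        assert q.levels.flat[-1] == 31
        # level width 128: value 127 -> 0, 128 -> 1
        assert q.levels.flat[127] == 0 and q.levels.flat[128] == 1

    def test_constant_maps_to_zero(self):
        vol, mask = _full([5.0, 5.0, 5.0])
        assert quantize(vol, mask).levels.max() == 0

    def test_midpoint_split(self):
        vol, mask = _full([1.0, 2.0, 3.0, 4.0])
        assert quantize(vol, mask, ng=2).levels.ravel().tolist() == [0, 0, 1, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40).filter(
            lambda v: max(v) > min(v)
        ),
        st.integers(2, 64),
    )
    def test_range_endpoints(self, values, ng):
        vol, mask = _full(values)
        q = quantize(vol, mask, ng=ng)
        levels = q.levels[mask]
        assert levels.min() >= 0 and levels.max() <= ng - 1
        assert levels[np.argmin(vol.ravel())] == 0
        assert levels[np.argmax(vol.ravel())] == ng - 1


class TestGlcm:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            vol = rng.integers(0, 4096, size=(6, 6, 6)).astype(float)
            mask = rng.random((6, 6, 6)) < 0.7
            if not mask.any():
                continue
            q = quantize(vol, mask, ng=8)
            for off in GLCM_OFFSETS:
                expected = brute_force_pair_counts(q.levels, mask, off, 8)
                np.testing.assert_array_equal(glcm_pair_counts(q, off), expected)

    def test_line_contrast_hand_count(self):
        vol, mask = _full([0.0, 1.0, 0.0, 1.0])
        q = quantize(vol, mask, ng=2)
        f = glcm_features(q)
        assert f["glcm_d00_contrast"] == pytest.approx(1.0)
        # other 12 offsets have no valid pair in a 1x1x4 line
        assert np.isnan(f["glcm_d01_contrast"])

    def test_single_gray_level(self):
        vol, mask = _full([2.0] * 27)
        vol = vol.reshape(3, 3, 3)
        mask = mask.reshape(3, 3, 3)
        f = glcm_features(quantize(vol, mask))
        for d in range(13):
            assert f[f"glcm_d{d:02d}_contrast"] == 0.0
            assert f[f"glcm_d{d:02d}_asm"] == 1.0
            assert f[f"glcm_d{d:02d}_entropy"] == 0.0
            assert f[f"glcm_d{d:02d}_idm"] == 1.0

    def test_count_182(self, rng):
        vol = rng.random((5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        f = glcm_features(quantize(vol, mask))
        assert len(f) == 13 * 14 == 182

    def test_probability_matrix_properties(self, rng):
        vol = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.8
        q = quantize(vol, mask, ng=6)
        for off in GLCM_OFFSETS:
            c = glcm_pair_counts(q, off)
            assert (c >= 0).all()
            np.testing.assert_array_equal(c, c.T)
            if c.sum() > 0:
                p = c / c.sum()
                assert p.sum() == pytest.approx(1.0)

    def test_haralick_ranges(self, rng):
        vol = rng.random((7, 7, 7))
        mask = rng.random((7, 7, 7)) < 0.7
        f = glcm_features(quantize(vol, mask, ng=8))
        for d in range(13):
            corr = f[f"glcm_d{d:02d}_correlation"]
            if not np.isnan(corr):
                assert -1.0 - 1e-9 <= corr <= 1.0 + 1e-9
            assert 0.0 < f[f"glcm_d{d:02d}_asm"] <= 1.0
            assert f[f"glcm_d{d:02d}_entropy"] >= 0.0


class TestLbpTop:
    def test_constant_volume_all_code_15(self):
        vol = np.full((6, 6, 6), 4.0)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        f = lbp_top_features(vol, mask)
        for plane in ("xy", "xz", "yz"):
            assert f[f"lbp_{plane}_b15"] == 1.0
            assert sum(f[f"lbp_{plane}_b{b:02d}"] for b in range(15)) == 0.0

    def test_histograms_sum_to_one(self, rng):
        vol = rng.random((8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.6
        mask[3, 3, 3] = True
        f = lbp_top_features(vol, mask)
        for plane in ("xy", "xz", "yz"):
            total = sum(f[f"lbp_{plane}_b{b:02d}"] for b in range(16))
            assert total == pytest.approx(1.0)

    def test_count_48(self, rng):
        vol = rng.random((6, 6, 6))
        f = lbp_top_features(vol, np.ones((6, 6, 6), dtype=bool))
        assert len(f) == 48

    def test_rotation_permutes_xy_codes(self, rng):
        # rot90 about z maps the (+r,+c,-r,-c) neighbor set by one cyclic
        # bit shift, so the xy histogram permutes by code -> ((code<<1)|(code>>3))&15
        vol = rng.random((9, 9, 5))
        mask = np.zeros((9, 9, 5), dtype=bool)
        mask[2:7, 2:7, 1:4] = rng.random((5, 5, 3)) < 0.8
        mask[3, 3, 2] = True
        f = lbp_top_features(vol, mask)
        fr = lbp_top_features(np.rot90(vol, axes=(0, 1)), np.rot90(mask, axes=(0, 1)))
        for code in range(16):
            rotated = ((code << 1) | (code >> 3)) & 15
            assert fr[f"lbp_xy_b{rotated:02d}"] == pytest.approx(f[f"lbp_xy_b{code:02d}"])

    def test_border_only_mask_warns_nan(self):
        vol = np.random.default_rng(3).random((5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.warns(UserWarning, match="LBP-TOP"):
            f = lbp_top_features(vol, mask)
        assert all(np.isnan(v) for v in f.values())


class TestExtractAll:
    def test_counts_and_prefixes(self, small_cohort):
        p = small_cohort[0]
        s = extract_all(p.volumes, p.mask)
        assert len(s) == 484
        assert sum(n.startswith("CT_") for n in s.index) == 242
        assert sum(n.startswith("PET_") for n in s.index) == 242
        assert list(s.index) == feature_names("CT") + feature_names("PET")

    def test_identical_modalities_identical_features(self, rng):
        vol = rng.random((8, 8, 8)) * 100
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        pair = VolumePair(ct=vol, pet=vol, spacing_mm=(1, 1, 1))
        s = extract_all(pair, mask)
        for name in feature_names():
            ct, pet = s[f"CT_{name}"], s[f"PET_{name}"]
            assert (np.isnan(ct) and np.isnan(pet)) or ct == pet

    def test_registry_is_stable(self):
        names = feature_names()
        assert len(names) == 242
        assert names == feature_names()  # deterministic ordering
        assert len(set(names)) == 242
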