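import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from veinsemble.feature_maps import (
    FeatureMapSet,
    GaborBank,
    GaborParams,
    LbpParams,
    build_feature_maps,
    compute_lbp,
    gabor_feature,
    gabor_kernel,
    segment_veins,
)
from veinsemble.synthetic_data import generate_template, render_sample


def lbp_oracle(image: np.ndarray, params: LbpParams) -> np.ndarray:
    """Exhaustive per-pixel bitwise reference for the LBP code."""
    img = np.pad(image.astype(int), params.radius, mode="edge")
    r = params.radius
    h, w = image.shape
    out = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            gc = image[y, x]
            code = 0
            for p, (dy, dx) in enumerate(params.offsets()):
                gp = img[y + r + dy, x + r + dx]
                if gp - gc >= 0:
                    code += 2**p
            out[y, x] = code
    return out


class TestComputeLbp:
    def test_constant_image_all_255(self):
        img = np.full((5, 7), 42, dtype=np.uint8)
        codes = compute_lbp(img)
        assert (codes == 255).all()

    def test_bright_center_code_zero(self):
        img = np.ones((3, 3), dtype=np.uint8)
        img[1, 1] = 200
        assert compute_lbp(img)[1, 1] == 0

    def test_3x3_patch_against_oracle(self):
        img = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=np.uint8)
        params = LbpParams()
        np.testing.assert_array_equal(compute_lbp(img, params), lbp_oracle(img, params))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_images_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        params = LbpParams()
        np.testing.assert_array_equal(compute_lbp(img, params), lbp_oracle(img, params))

    @given(
        data=hnp.arrays(
            dtype=np.uint8,
            shape=st.tuples(
                st.integers(3, 10), st.integers(3, 10)
            ),
        ),
        offset=st.integers(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_property_oracle_and_offset_invariance(self, data, offset):
        params = LbpParams()
        codes = compute_lbp(data, params)
        np.testing.assert_array_equal(codes, lbp_oracle(data, params))
        shifted = data.astype(np.int64) + offset
        np.testing.assert_array_equal(codes, compute_lbp(shifted, params))

    def test_invariant_to_constant_offset(self, rng):
        img = rng.integers(0, 200, size=(12, 12)).astype(np.int64)
        np.testing.assert_array_equal(compute_lbp(img), compute_lbp(img + 50))

    def test_output_shape_and_range(self, rng):
        img = rng.integers(0, 256, size=(9, 17), dtype=np.uint8)
        codes = compute_lbp(img)
        assert codes.shape == img.shape
        assert codes.max() <= 255 and codes.min() >= 0

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            compute_lbp(np.zeros((2, 2), dtype=np.uint8))

    def test_only_eight_neighbors_supported(self):
        with pytest.raises(ValueError):
            LbpParams(neighbors=16)

    def test_clockwise_ordering_differs(self, rng):
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        ccw = compute_lbp(img, LbpParams(counter_clockwise=True))
        cw = compute_lbp(img, LbpParams(counter_clockwise=False))
        assert (ccw != cw).any()
        np.testing.assert_array_equal(
            cw, lbp_oracle(img, LbpParams(counter_clockwise=False))
        )


def gabor_scalar(x, y, wavelength, theta, psi, sigma, gamma):
    """Direct pointwise evaluation of the real Gabor function."""
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    envelope = math.exp(-(xp**2 + gamma**2 * yp**2) / (2 * sigma**2))
    return envelope * math.cos(2 * math.pi * xp / wavelength + psi)


class TestGaborKernel:
    def test_center_is_one_at_zero_phase(self):
        k = gabor_kernel(GaborParams(wavelength=3.0, psi=0.0, kernel_size=7))
        assert k[3, 3] == pytest.approx(1.0, abs=1e-15)

    def test_quarter_turn_symmetry(self):
        k0 = gabor_kernel(GaborParams(wavelength=4.0, theta=0.0, kernel_size=9))
        k90 = gabor_kernel(
            GaborParams(wavelength=4.0, theta=math.pi / 2, kernel_size=9)
        )
        np.testing.assert_allclose(np.rot90(k0, 1), k90, atol=1e-12)

    def test_pointwise_formula_oracle(self):
        params = GaborParams(
            wavelength=math.pi / 2, theta=0.0, psi=0.0, sigma=0.88, gamma=0.5,
            kernel_size=7,
        )
        k = gabor_kernel(params)
        half = 3
        for row in range(7):
            for col in range(7):
                expected = gabor_scalar(
                    col - half, row - half,
                    params.wavelength, params.theta, params.psi,
                    params.sigma, params.gamma,
                )
                assert k[row, col] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_even_kernel_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            GaborParams(wavelength=3.0, kernel_size=8)


class TestGaborFeature:
    def test_constant_image_maps_to_zero(self):
        img = np.full((32, 64), 77, dtype=np.uint8)
        out = gabor_feature(img)
        assert (out == 0).all()

    def test_output_is_8bit_range(self, rng):
        img = rng.integers(0, 256, size=(48, 48), dtype=np.uint8)
        out = gabor_feature(img)
        assert out.dtype == np.uint8
        assert out.min() >= 0 and out.max() <= 255

    def test_diagonal_line_strongest_for_matching_orientation(self):
        from veinsemble.feature_maps import _bank_responses

        img = np.full((64, 64), 200.0)
        for i in range(8, 56):
            img[i, 63 - i] = 60.0  # dark line along the "/" diagonal (+45 deg)
        bank = GaborBank()
        responses = _bank_responses(img, bank)
        line_px = ([i for i in range(16, 48)], [63 - i for i in range(16, 48)])
        by_theta = {}
        for member, resp in zip(bank.members(), responses):
            key = round(math.degrees(member.theta))
            by_theta[key] = by_theta.get(key, 0.0) + np.abs(resp[line_px]).mean()
        assert max(by_theta, key=by_theta.get) == 45

    def test_empty_bank_rejected(self, rng):
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        with pytest.raises(ValueError):
            gabor_feature(img, GaborBank(scales=()))


class TestSegmentVeins:
    def test_constant_image_gives_empty_foreground(self):
        img = np.full((64, 128), 150, dtype=np.uint8)
        seg = segment_veins(img)
        assert set(np.unique(seg)) <= {0}

    def test_binary_output(self):
        tpl = generate_template(0, master_seed=9)
        img, _ = render_sample(tpl)
        seg = segment_veins(img)
        assert set(np.unique(seg)) <= {0, 1}

    def test_dice_against_ground_truth(self):
        dices = []
        for cid in range(4):
            tpl = generate_template(cid, master_seed=9)
            img, mask = render_sample(tpl)
            seg = segment_veins(img).astype(bool)
            dices.append(
                2 * (seg & mask).sum() / (seg.sum() + mask.sum())
            )
        assert np.mean(dices) >= 0.5

    def test_deterministic(self):
        tpl = generate_template(1, master_seed=9)
        img, _ = render_sample(tpl)
        np.testing.assert_array_equal(segment_veins(img), segment_veins(img))


@pytest.fixture(scope="module")
def sample():
    tpl = generate_template(3, master_seed=9)
    return render_sample(tpl)[0]


class TestBuildFeatureMaps:
    def test_six_maps_same_shape(self, sample):
        maps = build_feature_maps(sample)
        assert len(maps.maps) == 6
        assert all(m.shape == sample.shape for m in maps)

    def test_composition_contracts(self, sample):
        maps = build_feature_maps(sample)
        np.testing.assert_array_equal(maps[0], sample)
        seg = segment_veins(sample)
        np.testing.assert_array_equal(maps[1], seg)
        np.testing.assert_array_equal(maps[2], compute_lbp(sample))
        np.testing.assert_array_equal(maps[3], compute_lbp(seg * np.uint8(255)))
        np.testing.assert_array_equal(maps[4], gabor_feature(sample))

    def test_segmentation_foreground_ratio(self, sample):
        maps = build_feature_maps(sample)
        ratio = maps[1].mean()
        assert 0.0 < ratio < 0.5

    def test_deterministic(self, sample):
        a = build_feature_maps(sample)
        b = build_feature_maps(sample)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_wrong_ndim_rejected(self):
        with pytest.raises(ValueError):
            build_feature_maps(np.zeros((3, 4, 5)))

    def test_mapset_requires_six_equal_shapes(self):
        with pytest.raises(ValueError):
            FeatureMapSet(maps=[np.zeros((4, 4))] * 5)
        with pytest.raises(ValueError):
            FeatureMapSet(maps=[np.zeros((4, 4))] * 5 + [np.zeros((5, 5))])
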