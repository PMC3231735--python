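"""NTTP code generation, uniform lookup and feature assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nttp.baselines import lbp_codes
from nttp.core import (
    NeighborhoodSpec,
    build_feature_vector,
    center_code,
    extract_nttp,
    nttp_codes,
    sample_neighbors,
    uniform_index,
    uniform_lookup,
)
from nttp.noise_band import NoiseBandParams

from conftest import (
    naive_band,
    naive_neighbors,
    naive_ternary_digit,
    naive_transitions,
    naive_uniform_bins,
)


class TestSampling:
    def test_constant_image_gives_constant_samples(self):
        img = np.full((9, 9), 42.0)
        for spec in (NeighborhoodSpec(8, 1), NeighborhoodSpec(8, 2)):
            assert sample_neighbors(img, (4, 4), spec) == pytest.approx([42.0] * 8)

    def test_bilinear_exact_on_affine_ramp(self):
        img = np.tile(np.arange(9, dtype=float), (9, 1))  # f(r, c) = c
        spec = NeighborhoodSpec(8, 2)
        samples = sample_neighbors(img, (4, 4), spec)
        expected = [4 + 2 * math.cos(2 * math.pi * l / 8) for l in range(8)]
        assert samples == pytest.approx(expected)

    def test_diagonal_bilinear_weights_hand_computed(self):
        # 3x3 ramp f = 3r + c; NE sample of the center at (1 - 1/sqrt2, 1 + 1/sqrt2)
        img = np.arange(9, dtype=float).reshape(3, 3)
        samples = sample_neighbors(img, (1, 1), NeighborhoodSpec(8, 1))
        s = 1 / math.sqrt(2)
        fr, fc = 1 - s, s  # fractional offsets into the NE unit cell
        hand = (
            img[0, 1] * (1 - fr) * (1 - fc)
            + img[0, 2] * (1 - fr) * fc
            + img[1, 1] * fr * (1 - fc)
            + img[1, 2] * fr * fc
        )
        assert samples[1] == pytest.approx(hand)
        assert samples[1] == pytest.approx(2.5857864376)

    def test_matches_naive_oracle_on_random_image(self, rng):
        img = rng.uniform(0, 255, (11, 11))
        for n, r in ((8, 1), (8, 2), (16, 2)):
            spec = NeighborhoodSpec(n, r)
            got = sample_neighbors(img, (5, 5), spec)
            assert got == pytest.approx(naive_neighbors(img, 5, 5, n, r))

    def test_margin_pixel_rejected(self):
        img = np.zeros((9, 9))
        with pytest.raises(ValueError):
            sample_neighbors(img, (0, 4), NeighborhoodSpec(8, 2))


class TestUniformLookup:
    def test_known_uniform_and_nonuniform_codes(self):
        lut = uniform_lookup(8)
        assert uniform_index(0b11100011, 8) < lut.n_uniform
        assert uniform_index(0b11101011, 8) == lut.n_uniform  # catch-all

    def test_eight_neighbour_bin_counts(self):
        lut = uniform_lookup(8)
        assert lut.n_uniform == 58
        assert lut.n_bins == 59

    @pytest.mark.parametrize("n", [4, 8, 16])
    def test_uniform_count_formula(self, n):
        lut = uniform_lookup(n)
        assert lut.n_uniform == n * (n - 1) + 2
        _, count = naive_uniform_bins(n)
        assert count == lut.n_uniform

    def test_full_enumeration_matches_naive_transition_count(self):
        lut = uniform_lookup(8)
        naive_table, _ = naive_uniform_bins(8)
        for code in range(256):
            assert lut[np.asarray(code)] == naive_table[code]
            assert (naive_transitions(code, 8) <= 2) == (
                lut[np.asarray(code)] < lut.n_uniform
            )

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            uniform_index(256, 8)


class TestCenterCode:
    def test_constant_image_all_ones(self):
        assert center_code(np.full((5, 5), 7.0)).all()

    def test_half_and_half_split(self):
        img = np.concatenate([np.zeros((4, 8)), np.full((4, 8), 100.0)])
        bits = center_code(img)
        assert not bits[:4].any() and bits[4:].all()

    def test_single_bright_pixel(self):
        img = np.zeros((3, 3))
        img[0, 2] = 255.0
        bits = center_code(img)
        assert bits.sum() == 1 and bits[0, 2] == 1


class TestNttpCodes:
    def test_constant_image_codes_are_zero(self):
        codes = nttp_codes(np.full((12, 12), 80.0))
        assert not codes.upper.any() and not codes.lower.any()

    def test_zero_band_upper_equals_lbp(self, random_images):
        params = NoiseBandParams(mode="constant", beta=0.0)
        spec = NeighborhoodSpec(8, 2)
        for img in random_images:
            assert np.array_equal(
                nttp_codes(img, spec, params).upper, lbp_codes(img, spec)
            )

    def test_mutual_exclusion_of_split_codes(self, random_images):
        for img in random_images:
            codes = nttp_codes(img)
            assert not (codes.upper & codes.lower).any()

    def test_lossless_ternary_split_matches_direct_evaluation(self, rng):
        """Reconstructed ternary digits equal a naive evaluation of the
        three-way threshold at every coded pixel."""
        spec = NeighborhoodSpec(8, 1)
        params = NoiseBandParams()
        for _ in range(5):
            img = rng.integers(0, 256, (10, 10)).astype(float)
            codes = nttp_codes(img, spec, params)
            ternary = codes.ternary()
            for row in range(1, 9):
                for col in range(1, 9):
                    gc = img[row, col]
                    band = naive_band(gc)
                    expected = sum(
                        naive_ternary_digit(g - gc, band) * 3**l
                        for l, g in enumerate(naive_neighbors(img, row, col, 8, 1))
                    )
                    assert ternary[row - 1, col - 1] == expected

    def test_single_neighbor_fluctuation_within_band_is_absorbed(self, rng):
        """Perturbing one neighbour while both old and new differences stay
        strictly inside the center's band never changes the center's code
        (exact-pixel geometry so the perturbation cannot leak through
        interpolation)."""
        spec = NeighborhoodSpec(4, 1)
        params = NoiseBandParams()
        checked = 0
        for _ in range(200):
            if checked >= 25:
                break
            img = rng.integers(40, 200, (7, 7)).astype(float)
            row, col = rng.integers(1, 6, 2)
            gc = img[row, col]
            band = naive_band(gc)
            offsets = [(0, 1), (-1, 0), (0, -1), (1, 0)]
            dr, dc = offsets[rng.integers(0, 4)]
            nr, nc = row + dr, col + dc
            if abs(img[nr, nc] - gc) >= band:
                continue
            eps = rng.uniform(-band, band)
            new_val = np.clip(gc + eps, 0, 255)
            if abs(new_val - gc) >= band:
                continue
            before = nttp_codes(img, spec, params)
            img2 = img.copy()
            img2[nr, nc] = new_val
            after = nttp_codes(img2, spec, params)
            assert before.upper[row - 1, col - 1] == after.upper[row - 1, col - 1]
            assert before.lower[row - 1, col - 1] == after.lower[row - 1, col - 1]
            checked += 1
        assert checked >= 10


class TestFeatureVector:
    def test_constant_image_mass_in_two_bins(self):
        fv = extract_nttp(np.full((10, 10), 90.0))
        lut = uniform_lookup(8)
        zero_bin = int(lut[np.asarray(0)])
        b = lut.n_bins
        # center bit 1, code 0, in both the U-part and the L-part
        expected = np.zeros(4 * b)
        expected[b + zero_bin] = 1.0
        expected[2 * b + b + zero_bin] = 1.0
        assert fv.values == pytest.approx(expected)

    def test_mass_conservation_and_normalisation(self, random_images):
        spec = NeighborhoodSpec(8, 2)
        for img in random_images:
            codes = nttp_codes(img, spec)
            n_coded = (img.shape[0] - 4) * (img.shape[1] - 4)
            assert codes.upper.size == n_coded
            fv = build_feature_vector(codes)
            assert fv.values[:118].sum() == pytest.approx(1.0, abs=1e-9)
            assert fv.values[118:].sum() == pytest.approx(1.0, abs=1e-9)
            assert (fv.values >= 0).all()

    def test_recount_oracle_on_collage(self, rng):
        """Full-feature cross-check against a per-pixel dictionary recount."""
        img = np.zeros((8, 8))
        img[:, :4] = rng.integers(0, 100, (8, 4))
        img[:, 4:] = rng.integers(150, 256, (8, 4))
        spec = NeighborhoodSpec(8, 1)
        fv = extract_nttp(img, spec)
        naive_table, n_uni = naive_uniform_bins(8)
        b = n_uni + 1
        mean = img.mean()
        hist = np.zeros(4 * b)
        for row in range(1, 7):
            for col in range(1, 7):
                gc = img[row, col]
                band = naive_band(gc)
                up = lo = 0
                for l, g in enumerate(naive_neighbors(img, row, col, 8, 1)):
                    if g - gc >= band:
                        up |= 1 << l
                    if g - gc <= -band:
                        lo |= 1 << l
                c = 1 if gc >= mean else 0
                hist[c * b + naive_table[up]] += 1
                hist[2 * b + c * b + naive_table[lo]] += 1
        hist[: 2 * b] /= hist[: 2 * b].sum()
        hist[2 * b :] /= hist[2 * b :].sum()
        assert fv.values == pytest.approx(hist)

    def test_extraction_is_deterministic(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        a = extract_nttp(img)
        b = extract_nttp(img)
        assert np.array_equal(a.values, b.values) and a.layout == b.layout

    @pytest.mark.parametrize("n, expected_len", [(4, 60), (8, 236)])
    def test_vector_length(self, rng, n, expected_len):
        img = rng.uniform(0, 255, (16, 16))
        fv = extract_nttp(img, NeighborhoodSpec(n, 1))
        assert len(fv) == expected_len

    def test_empty_code_map_rejected(self):
        with pytest.raises(ValueError):
            extract_nttp(np.zeros((3, 3)), NeighborhoodSpec(8, 2))
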