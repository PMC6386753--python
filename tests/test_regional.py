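"""Voxelwise regional features: ALFF/fALFF against a direct-DFT oracle,
Kendall's W identities for ReHo, map standardization and ROI averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_series
from parcelstack.atlas import Atlas, resolve_design
from parcelstack.bold import BandSpec
from parcelstack.regional import (
    aggregate_regional,
    compute_alff,
    compute_falff,
    compute_reho,
    kendalls_w,
    standardize_map,
)


def dft_amplitude_oracle(x, tr, low, high):
    """Independent direct-DFT oracle: explicit complex exponential sums,
    single-sided amplitude, summed over bins with low <= k/(n*tr) <= high."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    total = 0.0
    for k in range(n // 2 + 1):
        f = k / (n * tr)
        if not (low <= f <= high):
            continue
        coef = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        scale = 1.0 if k == 0 or (n % 2 == 0 and k == n // 2) else 2.0
        total += scale * abs(coef) / n
    return total


class TestAlff:
    def test_zero_series_gives_zero(self):
        out = compute_alff(make_series(np.zeros((2, 2, 2, 64))))
        assert np.all(out.values == 0)

    def test_linearity_in_amplitude(self, rng):
        x = rng.standard_normal((3, 3, 3, 80))
        a1 = compute_alff(make_series(x)).values
        a3 = compute_alff(make_series(3.0 * x)).values
        np.testing.assert_allclose(a3, 3.0 * a1, rtol=1e-12)

    def test_matches_direct_dft_oracle_on_random_series(self, rng):
        # >= 50 random cases against the independent oracle
        for _ in range(50):
            x = rng.standard_normal(143)
            series = make_series(x.reshape(1, 1, 1, -1), tr=2.0)
            got = compute_alff(series).values[0, 0, 0]
            want = dft_amplitude_oracle(x, 2.0, 0.01, 0.08)
            assert got == pytest.approx(want, rel=1e-8)

    def test_sinusoid_value_matches_oracle(self):
        t = np.arange(143) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        got = compute_alff(make_series(x.reshape(1, 1, 1, -1))).values[0, 0, 0]
        want = dft_amplitude_oracle(x, 2.0, 0.01, 0.08)
        assert got == pytest.approx(want, rel=1e-8)

    def test_band_without_bins_rejected(self):
        s = make_series(np.random.default_rng(0).standard_normal((1, 1, 1, 16)))
        with pytest.raises(ValueError):
            compute_alff(s, BandSpec(0.011, 0.012))


class TestFalff:
    def test_in_band_signal_gives_one(self):
        t = np.arange(128) * 2.0
        x = np.sin(2 * np.pi * 0.0390625 * t)  # exactly bin 10 of 128
        out = compute_falff(make_series(x.reshape(1, 1, 1, -1)))
        assert out.values[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_out_of_band_signal_gives_near_zero(self):
        t = np.arange(128) * 2.0
        x = np.sin(2 * np.pi * (52 / 256) * t)  # ~0.2 Hz, exact DFT bin
        out = compute_falff(make_series(x.reshape(1, 1, 1, -1)))
        assert out.values[0, 0, 0] < 1e-8

    def test_white_noise_mean_near_band_fraction(self, rng):
        n, tr = 256, 2.0
        x = rng.standard_normal((6, 6, 6, n))  # 216 voxels Monte-Carlo
        out = compute_falff(make_series(x, tr=tr))
        freqs = np.fft.rfftfreq(n, d=tr)
        frac = ((freqs >= 0.01) & (freqs <= 0.08)).sum() / (len(freqs) - 1)
        assert out.values.mean() == pytest.approx(frac, rel=0.1)

    def test_bounded_and_scale_invariant(self, rng):
        x = rng.standard_normal((3, 3, 3, 100))
        v1 = compute_falff(make_series(x)).values
        v2 = compute_falff(make_series(5.0 * x)).values
        assert np.all((v1 >= 0) & (v1 <= 1))
        np.testing.assert_allclose(v1, v2, atol=1e-12)


class TestReho:
    def test_identical_series_give_w_one(self):
        x = np.tile(np.sin(np.arange(30)), (3, 3, 3, 1))
        out = compute_reho(make_series(x), neighborhood=27)
        assert out.values[1, 1, 1] == pytest.approx(1.0, abs=1e-10)

    def test_reversed_rank_pair_gives_w_zero(self):
        # K=2 series with exactly reversed ranks: rank sums constant
        base = np.arange(10, dtype=float)
        mat = np.stack([base, base[::-1]])
        assert kendalls_w(mat) == pytest.approx(0.0, abs=1e-12)

    def test_null_mean_w_is_one_over_k(self, rng):
        x = rng.standard_normal((10, 10, 10, 24))
        out = compute_reho(make_series(x), neighborhood=27)
        interior = out.values[1:-1, 1:-1, 1:-1]  # K = 27 exactly
        assert interior.mean() == pytest.approx(1 / 27, rel=0.1)

    def test_voxel_map_matches_reference_statistic(self, rng):
        x = rng.standard_normal((3, 3, 3, 15))
        out = compute_reho(make_series(x), neighborhood=7)
        # centre voxel: neighbourhood = itself + 6 face neighbours
        centre_block = np.stack([
            x[1, 1, 1], x[0, 1, 1], x[2, 1, 1],
            x[1, 0, 1], x[1, 2, 1], x[1, 1, 0], x[1, 1, 2],
        ])
        assert out.values[1, 1, 1] == pytest.approx(
            kendalls_w(centre_block), abs=1e-10
        )

    def test_tie_correction_matches_reference_on_integer_data(self, rng):
        x = rng.integers(0, 3, size=(3, 3, 3, 12)).astype(float)
        out = compute_reho(make_series(x), neighborhood=7)
        centre_block = np.stack([
            x[1, 1, 1], x[0, 1, 1], x[2, 1, 1],
            x[1, 0, 1], x[1, 2, 1], x[1, 1, 0], x[1, 1, 2],
        ])
        assert out.values[1, 1, 1] == pytest.approx(
            kendalls_w(centre_block), abs=1e-10
        )

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((3, 3, 3, 12))
        w1 = compute_reho(make_series(x), neighborhood=27).values
        w2 = compute_reho(make_series(np.exp(x)), neighborhood=27).values
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_reho(make_series(np.zeros((2, 2, 2, 2))))

    def test_values_bounded(self, rng):
        x = rng.standard_normal((5, 5, 5, 20))
        out = compute_reho(make_series(x))
        assert np.all((out.values >= 0) & (out.values <= 1))


class TestStandardize:
    def test_hand_computed_z_scores(self):
        from parcelstack.regional import VoxelMap

        mask = np.array([[[True, True, True]]])
        vmap = VoxelMap(np.array([[[1.0, 2.0, 3.0]]]), mask, "ALFF")
        out = standardize_map(vmap)
        np.testing.assert_allclose(
            out.values[0, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_idempotent(self, rng):
        from parcelstack.regional import VoxelMap

        mask = np.ones((4, 4, 4), dtype=bool)
        vmap = VoxelMap(rng.standard_normal((4, 4, 4)), mask, "ALFF")
        once = standardize_map(vmap)
        twice = standardize_map(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_map_zeroed_with_warning(self):
        from parcelstack.regional import VoxelMap

        mask = np.ones((2, 2, 2), dtype=bool)
        vmap = VoxelMap(np.full((2, 2, 2), 5.0), mask, "ReHo")
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_map(vmap)
        assert np.all(out.values == 0)


class TestAggregate:
    def test_single_voxel_roi_returns_its_value(self):
        from parcelstack.regional import VoxelMap

        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0, 0, 0] = 1
        atlas = Atlas("a", "labels", labels, np.eye(4), ["roi_1"])
        mask = np.ones((3, 3, 3), dtype=bool)
        design = resolve_design(atlas, mask, np.eye(4))
        values = np.zeros((3, 3, 3))
        values[0, 0, 0] = 3.5
        got = aggregate_regional(
            VoxelMap(values, mask, "ALFF", standardized=True), design
        )
        assert got == pytest.approx([3.5])

    def test_map_weights_give_weighted_mean(self):
        from parcelstack.regional import VoxelMap

        stack = np.zeros((2, 1, 1, 1))
        stack[0, 0, 0, 0] = 1.0
        stack[1, 0, 0, 0] = 1.0
        atlas = Atlas("m", "maps", stack, np.eye(4), ["net_1"])
        mask = np.ones((2, 1, 1), dtype=bool)
        design = resolve_design(atlas, mask, np.eye(4))
        values = np.array([[[2.0]], [[4.0]]])
        got = aggregate_regional(
            VoxelMap(values, mask, "ALFF", standardized=True), design
        )
        assert got == pytest.approx([3.0])  # (2+4)/2 with equal weights

    def test_output_length_equals_n_rois(self, rng):
        from parcelstack.regional import VoxelMap

        labels = (rng.integers(1, 9, size=(6, 6, 6))).astype(int)
        atlas = Atlas("a", "labels", labels, np.eye(4),
                      [f"roi_{k}" for k in range(1, 9)])
        mask = np.ones((6, 6, 6), dtype=bool)
        design = resolve_design(atlas, mask, np.eye(4))
        got = aggregate_regional(
            VoxelMap(rng.standard_normal((6, 6, 6)), mask, "ALFF",
                     standardized=True), design
        )
        assert got.shape == (8,)
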