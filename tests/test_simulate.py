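"""Synthetic Z-spectrum / phantom generator and the two augmentation schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zspeed import (
    DEFAULT_POOLS,
    OffsetGrid,
    PoolSpec,
    ZSpectrumTable,
    augment_gaussian,
    augment_subsample,
    lorentzian_pool,
    make_offset_grid,
    simulate_corpus,
    simulate_phantom,
    simulate_zspectrum,
)
from zspeed.preprocess import slice_average


class TestOffsetGrid:
    @pytest.mark.parametrize(
        "start,stop,step,n",
        [(-5, 5, 0.2, 51), (-5, 5, 0.1, 101), (0, 1, 0.5, 3)],
    )
    def test_point_counts(self, start, stop, step, n):
        grid = make_offset_grid(start, stop, step)
        assert len(grid) == n
        assert grid.start == start and grid.stop == stop

    def test_symmetric_grid_contains_zero(self, grid51, grid101):
        for g in (grid51, grid101):
            assert 0.0 in g.offsets

    @pytest.mark.parametrize(
        "start,stop,step",
        [(0, 0, 0.1), (1, 0, 0.1), (-5, 5, -0.2), (-5, 5, 0.0), (0, 1, 0.3)],
    )
    def test_degenerate_ranges_rejected(self, start, stop, step):
        with pytest.raises(ValueError):
            make_offset_grid(start, stop, step)

    def test_non_uniform_rejected(self):
        with pytest.raises(ValueError):
            OffsetGrid(np.array([0.0, 0.1, 0.3]))


class TestLorentzianPool:
    def test_peak_amplitude_at_center(self, grid101):
        pool = PoolSpec(0.3, 1.5, 1.0)
        vec = lorentzian_pool(grid101, pool)
        i = grid101.index_of(1.5)
        assert vec[i] == pytest.approx(0.3)
        assert np.argmax(vec) == i

    def test_half_maximum_at_half_width(self, grid101):
        pool = PoolSpec(0.4, 0.0, 1.0)  # FWHM edges at +-0.5 ppm, on grid
        vec = lorentzian_pool(grid101, pool)
        assert vec[grid101.index_of(0.5)] == pytest.approx(0.2)
        assert vec[grid101.index_of(-0.5)] == pytest.approx(0.2)

    def test_zero_amplitude_gives_zero_vector(self, grid101):
        assert not lorentzian_pool(grid101, PoolSpec(0.0, 0.0, 1.0)).any()

    def test_invalid_pools_rejected(self):
        with pytest.raises(ValueError):
            PoolSpec(-0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            PoolSpec(0.1, 0.0, 0.0)


class TestSimulateZspectrum:
    def test_empty_pool_list_gives_unit_signal(self, grid101):
        s = simulate_zspectrum(grid101, [], noise_sd=0.0)
        assert np.all(s.values == 1.0)

    def test_water_only_symmetric_minimum_at_zero(self, water_spectrum, grid101):
        assert grid101.offsets[np.argmin(water_spectrum.values)] == 0.0
        np.testing.assert_allclose(water_spectrum.values,
                                   water_spectrum.values[::-1], atol=1e-12)

    def test_noise_free_values_within_amplitude_bounds(self, brain_spectrum):
        total = sum(p.amplitude for p in DEFAULT_POOLS)
        assert brain_spectrum.values.min() >= 1.0 - total - 1e-12
        assert brain_spectrum.values.max() <= 1.0

    def test_amplitude_sum_above_one_rejected(self, grid101):
        with pytest.raises(ValueError):
            simulate_zspectrum(grid101, [PoolSpec(0.7, 0, 1), PoolSpec(0.4, 3, 1)])

    def test_noise_sd_empirical(self):
        # ~10^4 independent draws on a flat (pool-free) spectrum
        grid = make_offset_grid(-5, 5, 0.001)
        s = simulate_zspectrum(grid, [], noise_sd=0.01, seed=5)
        sd = np.std(s.values - 1.0)
        assert abs(sd - 0.01) < 0.001

    def test_seed_reproducibility(self, grid101):
        a = simulate_zspectrum(grid101, DEFAULT_POOLS, noise_sd=0.01, seed=3)
        b = simulate_zspectrum(grid101, DEFAULT_POOLS, noise_sd=0.01, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulatePhantom:
    def test_uniform_noise_free_pixels_identical(self, small_phantom):
        ref = small_phantom.data[0, 0, 0]
        assert np.all(small_phantom.data[:, :, 0, :] == ref)

    def test_zero_b0_argmin_at_zero_ppm(self, small_phantom, grid51):
        argmins = small_phantom.data.argmin(axis=3)
        assert np.all(grid51.offsets[argmins] == 0.0)

    def test_slice_average_matches_generator_exactly(self, small_phantom, grid51):
        avg = slice_average(small_phantom, 0)
        expected = simulate_zspectrum(grid51, DEFAULT_POOLS, noise_sd=0.0)
        np.testing.assert_allclose(avg.values, expected.values, atol=1e-12)

    def test_seed_gives_bit_identical_volumes(self, grid51):
        kw = dict(n_subjects=2, n_slices=1, shape=(6, 6), grid=grid51, seed=9)
        a = simulate_phantom(**kw)
        b = simulate_phantom(**kw)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_mismatched_field_shape_rejected(self, grid51):
        with pytest.raises(ValueError):
            simulate_phantom(n_subjects=1, shape=(6, 6), grid=grid51,
                             b0_field=np.zeros((4, 4)), seed=0)


class TestAugmentGaussian:
    def test_row_count_multiplicative(self, grid101):
        base = ZSpectrumTable(grid101, np.full((30, 101), 0.9))
        out = augment_gaussian(base, n_copies=100, seed=0)
        assert len(out) == 3000

    def test_zero_noise_copies_identical(self, brain_spectrum):
        base = ZSpectrumTable.from_spectra([brain_spectrum])
        out = augment_gaussian(base, n_copies=5, noise_sd=0.0, seed=0)
        for row in out.values:
            np.testing.assert_array_equal(row, brain_spectrum.values)

    def test_mean_of_copies_near_base(self, brain_spectrum):
        base = ZSpectrumTable.from_spectra([brain_spectrum])
        out = augment_gaussian(base, n_copies=100, noise_sd=0.01, seed=1)
        # CLT: per-offset mean within 3 * sd/sqrt(100) of the base
        np.testing.assert_allclose(out.values.mean(axis=0),
                                   brain_spectrum.values, atol=3 * 0.01 / 10)

    def test_empty_input_rejected(self, grid101):
        with pytest.raises(ValueError):
            augment_gaussian(ZSpectrumTable(grid101, np.ones((0, 101))), 10)


class TestAugmentSubsample:
    def test_default_size_ladder_has_16_sizes(self):
        assert len(range(800, 1551, 50)) == 16

    def test_one_spectrum_per_slice_and_size(self, grid51):
        vol = simulate_phantom(1, n_slices=2, shape=(40, 40), grid=grid51,
                               noise_sd=0.01, seed=2)[0]
        out = augment_subsample(vol, seed=0)
        assert len(out) == 2 * 16

    def test_full_population_equals_slice_average(self, small_phantom):
        n_pix = int(small_phantom.mask[:, :, 0].sum())
        out = augment_subsample(small_phantom, sizes=[n_pix], seed=0)
        np.testing.assert_allclose(out.values[0],
                                   slice_average(small_phantom, 0).values,
                                   atol=1e-12)

    def test_oversized_subsample_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            augment_subsample(small_phantom, sizes=[65], seed=0)

    def test_seeded_reproducibility(self, grid51):
        vol = simulate_phantom(1, n_slices=1, shape=(40, 40), grid=grid51,
                               noise_sd=0.01, seed=4)[0]
        a = augment_subsample(vol, sizes=[800, 850], seed=7)
        b = augment_subsample(vol, sizes=[800, 850], seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulateCorpus:
    def test_shapes_and_determinism(self, grid101):
        a = simulate_corpus(10, grid101, seed=1)
        b = simulate_corpus(10, grid101, seed=1)
        assert a.values.shape == (10, 101)
        np.testing.assert_array_equal(a.values, b.values)

    def test_spectra_are_diverse_and_physical(self, grid101):
        tab = simulate_corpus(20, grid101, seed=2)
        assert np.all(tab.values >= 0.0) and np.all(tab.values <= 1.0)
        assert np.std(tab.values, axis=0).max() > 0.01


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    amp=st.floats(0.0, 0.9),
    center=st.floats(-4.0, 4.0),
    fwhm=st.floats(0.2, 8.0),
)
def test_lorentzian_bounded_by_amplitude(amp, center, fwhm):
    grid = make_offset_grid(-5, 5, 0.1)
    vec = lorentzian_pool(grid, PoolSpec(amp, center, fwhm))
    assert np.all(vec >= 0.0) and np.all(vec <= amp + 1e-12)
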