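"""Spline-RMSE fitness, genetic-algorithm selection, and baseline selectors."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import make_interp_spline

from zspeed import (
    GAConfig,
    OffsetGrid,
    OffsetSubset,
    ZSpectrum,
    fitness,
    fixed_select,
    ga_select,
    make_offset_grid,
    prng_select,
    select_best_candidate,
    simulate_zspectrum,
    spline_reconstruct,
)
from zspeed.select import _crossover, _mutate


def brute_force_rmse(indices, offsets, values):
    """Independent oracle: B-spline interpolation + explicit RMSE formula."""
    idx = sorted(indices)
    x, y = offsets[idx], values[idx]
    spl = make_interp_spline(x, y, k=3)
    recon = spl(np.clip(offsets, x[0], x[-1]))
    return np.sqrt(np.sum((recon - values) ** 2) / len(values))


@pytest.fixture(scope="module")
def toy9():
    grid = make_offset_grid(0, 8, 1.0)
    values = np.array([1.0, 0.85, 0.4, 0.1, 0.05, 0.2, 0.6, 0.9, 0.95])
    return ZSpectrum(grid, values)


class TestSplineReconstruct:
    def test_full_subset_is_identity(self, brain_spectrum, grid101):
        full = OffsetSubset(grid101, tuple(range(101)))
        out = spline_reconstruct(full, brain_spectrum.values, grid101)
        np.testing.assert_allclose(out, brain_spectrum.values, atol=1e-10)

    def test_exact_at_sampled_offsets(self, brain_spectrum, grid101):
        sub = prng_select(grid101, 12, seed=4)
        out = spline_reconstruct(sub, brain_spectrum.values[list(sub.indices)],
                                 grid101)
        np.testing.assert_allclose(out[list(sub.indices)],
                                   brain_spectrum.values[list(sub.indices)],
                                   atol=1e-12)

    def test_recovers_cubic_polynomial_exactly(self, grid101):
        x = grid101.offsets
        dense = 0.5 + 0.01 * x - 0.002 * x**2 + 0.0005 * x**3
        sub = OffsetSubset(grid101, (0, 30, 70, 100))
        out = spline_reconstruct(sub, dense[[0, 30, 70, 100]], grid101)
        np.testing.assert_allclose(out, dense, atol=1e-12)

    def test_constant_extension_beyond_hull(self, brain_spectrum, grid101):
        sub = OffsetSubset(grid101, (10, 30, 60, 90))
        vals = brain_spectrum.values[[10, 30, 60, 90]]
        out = spline_reconstruct(sub, vals, grid101)
        assert np.all(out[:10] == out[10]) and np.all(out[90:] == out[90])

    def test_fewer_than_four_points_rejected(self, brain_spectrum, grid101):
        sub = OffsetSubset(grid101, (0, 50, 100))
        with pytest.raises(ValueError):
            spline_reconstruct(sub, brain_spectrum.values[[0, 50, 100]], grid101)


class TestFitness:
    def test_full_grid_fitness_zero(self, brain_spectrum, grid101):
        full = OffsetSubset(grid101, tuple(range(101)))
        assert fitness(full, brain_spectrum) == pytest.approx(0.0, abs=1e-10)

    def test_linear_ramp_any_subset_zero(self, grid101):
        ramp = ZSpectrum(grid101, np.linspace(0.2, 0.9, 101))
        sub = OffsetSubset(grid101, (0, 20, 55, 100))
        assert fitness(sub, ramp) == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_oracle_on_toy(self, toy9):
        offsets, values = toy9.grid.offsets, toy9.values
        for combo in itertools.combinations(range(9), 4):
            ours = fitness(OffsetSubset(toy9.grid, combo), toy9)
            assert ours == pytest.approx(
                brute_force_rmse(combo, offsets, values), abs=1e-10)


class TestGASelect:
    def test_subset_size_is_percent_of_grid(self, brain_spectrum):
        res = ga_select(brain_spectrum, 10,
                        GAConfig(seed=0, max_generations=5, population_size=20))
        assert len(res.best) == 10

    def test_attains_exhaustive_optimum_on_toy(self, toy9):
        best_brute = min(
            brute_force_rmse(c, toy9.grid.offsets, toy9.values)
            for c in itertools.combinations(range(9), 4)
        )
        res = ga_select(toy9, 4 / 9 * 100,
                        GAConfig(seed=1, population_size=40, max_generations=100))
        assert res.best.fitness == pytest.approx(best_brute, abs=1e-9)

    def test_history_non_increasing_with_elitism(self, brain_spectrum):
        res = ga_select(brain_spectrum, 10,
                        GAConfig(seed=2, max_generations=40, elitism=1))
        h = np.array(res.history)
        assert np.all(np.diff(h) <= 0)
        assert res.best.fitness == h[-1]

    def test_target_loss_termination(self, brain_spectrum):
        res = ga_select(brain_spectrum, 30,
                        GAConfig(seed=3, target_loss=0.05, max_generations=200))
        assert res.termination_reason == "target_reached"

    def test_stall_termination(self, toy9):
        res = ga_select(toy9, 4 / 9 * 100,
                        GAConfig(seed=4, patience=5, max_generations=500))
        assert res.termination_reason in ("stalled", "target_reached")
        assert res.generations_run < 500

    def test_seed_determinism(self, brain_spectrum):
        cfg = dict(seed=5, max_generations=15, population_size=20)
        a = ga_select(brain_spectrum, 10, GAConfig(**cfg))
        b = ga_select(brain_spectrum, 10, GAConfig(**cfg))
        assert a.best.indices == b.best.indices
        assert a.history == b.history

    def test_infeasible_budget_rejected(self, brain_spectrum):
        with pytest.raises(ValueError):
            ga_select(brain_spectrum, 1)  # k = 1 < 4


class TestOperators:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(4, 20))
    def test_crossover_and_mutation_preserve_cardinality(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 101
        a = np.sort(rng.choice(n, size=k, replace=False))
        b = np.sort(rng.choice(n, size=k, replace=False))
        child = _crossover(a, b, k, rng)
        assert len(np.unique(child)) == k
        assert set(child) <= (set(a) | set(b))
        mutated = _mutate(child, n, 0.5, rng)
        assert len(np.unique(mutated)) == k
        assert mutated.min() >= 0 and mutated.max() < n


class TestSelectBestCandidate:
    def test_single_candidate_returned(self, brain_spectrum, grid101):
        sub = prng_select(grid101, 10, seed=0)
        best = select_best_candidate([sub], [brain_spectrum], mode="own")
        assert best is sub

    def test_own_mode_is_argmin_of_fitness(self, grid101, brain_spectrum):
        subs = [
            OffsetSubset(grid101, prng_select(grid101, 10, seed=s).indices,
                         fitness=f)
            for s, f in zip(range(3), [0.012, 0.009, 0.015])
        ]
        best = select_best_candidate(subs, [brain_spectrum] * 3, mode="own")
        assert best.fitness == 0.009

    def test_cross_mean_matches_direct_evaluation(self, grid101):
        rng = np.random.default_rng(0)
        spectra = [
            simulate_zspectrum(grid101, b0_shift=sh, noise_sd=0.0)
            for sh in (-0.2, 0.0, 0.2)
        ]
        cands = [prng_select(grid101, 12, seed=s) for s in range(4)]
        means = [np.mean([fitness(c, sp) for sp in spectra]) for c in cands]
        best = select_best_candidate(cands, spectra, mode="cross-mean")
        assert best is cands[int(np.argmin(means))]

    def test_empty_candidates_rejected(self, brain_spectrum):
        with pytest.raises(ValueError):
            select_best_candidate([], [brain_spectrum])


class TestBaselineSelectors:
    def test_prng_draws_distinct_reproducible(self, grid101):
        a = prng_select(grid101, 10, seed=6)
        b = prng_select(grid101, 10, seed=6)
        assert len(set(a.indices)) == 10
        assert a.indices == b.indices

    def test_prng_full_grid(self, grid101):
        sub = prng_select(grid101, 101, seed=0)
        assert sub.indices == tuple(range(101))

    def test_prng_oversized_rejected(self, grid101):
        with pytest.raises(ValueError):
            prng_select(grid101, 102, seed=0)

    def test_fixed_select_published_ten_percent_set(self, grid101):
        ppm = [-4.8, -3.8, -3.2, -0.7, -0.1, 0.0, 0.1, 1.1, 3.5, 4.5]
        sub = fixed_select(grid101, ppm)
        assert len(sub) == 10
        np.testing.assert_allclose(sub.ppm, sorted(ppm), atol=1e-9)

    def test_fixed_select_empty_rejected(self, grid101):
        with pytest.raises(ValueError):
            fixed_select(grid101, [])

    def test_fixed_select_off_grid_ppm_rejected(self, grid101):
        with pytest.raises(ValueError):
            fixed_select(grid101, [0.25])
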