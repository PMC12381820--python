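"""Sparse frequency-offset selection.

The scan time of a CEST acquisition is proportional to the number of
saturation offsets, so the goal is to find the subset F_selected of the
dense offset grid F_N, of fixed size k = round(p% * N), that minimizes the
loss L(F_selected) — the RMSE between the dense Z-spectrum and its cubic-
spline reconstruction from only the selected offsets:

    F_optimal = argmin_{F_selected subset of F_N} L(F_selected)

The search is a genetic algorithm over fixed-cardinality index sets
(tournament selection, union-then-subsample crossover, replacement
mutation, optional elitism).  Baseline selectors — uniform pseudo-random
subsets and user-supplied fixed ppm lists — support method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core import OffsetGrid, ZSpectrum

__all__ = [
    "OffsetSubset",
    "GAConfig",
    "GAResult",
    "spline_reconstruct",
    "fitness",
    "ga_select",
    "select_best_candidate",
    "prng_select",
    "fixed_select",
]

MIN_SUBSET = 4  # cubic spline needs at least four support points


@dataclass(frozen=True)
class OffsetSubset:
    """A sparse subset of an offset grid, identified by sorted indices."""

    grid: OffsetGrid
    indices: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(set(idx)) != len(idx):
            raise ValueError("subset indices must be distinct")
        if not idx:
            raise ValueError("subset must be non-empty")
        if idx[0] < 0 or idx[-1] >= len(self.grid):
            raise ValueError("subset index out of grid range")
        object.__setattr__(self, "indices", idx)

    @property
    def ppm(self) -> np.ndarray:
        """Selected offsets in ppm (derived from indices)."""
        return self.grid.offsets[list(self.indices)]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    The defaults follow a small-search-space regime (N = 101 offsets):
    modest population, per-gene replacement mutation, and a stall criterion
    that stops when the best loss no longer improves.
    """

    population_size: int = 60
    mutation_rate: float = 0.1
    max_generations: int = 300
    target_loss: float | None = None
    patience: int = 20
    elitism: int = 1
    tournament_size: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass
class GAResult:
    """Outcome of one GA run: best subset, loss trace and termination cause."""

    best: OffsetSubset
    history: list[float]
    generations_run: int
    termination_reason: Literal["target_reached", "stalled", "max_generations"]


def spline_reconstruct(
    subset: OffsetSubset, sparse_values: np.ndarray, full_grid: OffsetGrid
) -> np.ndarray:
    """Cubic-spline reconstruction of a dense spectrum from sparse samples.

    Interpolates ``sparse_values`` (aligned with ``subset``) onto
    ``full_grid``; beyond the extreme selected offsets the end values are
    extended as constants.  Exact at the selected offsets.
    """
    if len(subset) < MIN_SUBSET:
        raise ValueError(f"need >= {MIN_SUBSET} points for cubic-spline reconstruction")
    sparse_values = np.asarray(sparse_values, dtype=float)
    if sparse_values.shape != (len(subset),):
        raise ValueError("sparse_values must align with the subset")
    x = subset.ppm
    cs = CubicSpline(x, sparse_values)
    return cs(np.clip(full_grid.offsets, x[0], x[-1]))


def fitness(subset: OffsetSubset, dense: ZSpectrum) -> float:
    """Reconstruction loss of a subset: RMSE over all dense-grid offsets."""
    recon = spline_reconstruct(subset, dense.values[list(subset.indices)], dense.grid)
    return float(np.sqrt(np.mean((recon - dense.values) ** 2)))


def _fitness_indices(idx: np.ndarray, offs: np.ndarray, values: np.ndarray) -> float:
    # inner-loop variant of `fitness` operating on raw arrays
    x = offs[idx]
    cs = CubicSpline(x, values[idx])
    recon = cs(np.clip(offs, x[0], x[-1]))
    return float(np.sqrt(np.mean((recon - values) ** 2)))


def _crossover(a: np.ndarray, b: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Union-then-subsample: child draws k distinct genes from parents' union."""
    union = np.union1d(a, b)
    child = rng.choice(union, size=k, replace=False)
    return np.sort(child)


def _mutate(chrom: np.ndarray, n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each gene, with probability ``rate``, by an unselected index."""
    if rate <= 0.0:
        return chrom
    chrom = chrom.copy()
    hits = np.nonzero(rng.random(chrom.size) < rate)[0]
    if hits.size:
        selected = set(chrom.tolist())
        pool = np.array([i for i in range(n) if i not in selected])
        rng.shuffle(pool)
        for j, g in enumerate(hits[: pool.size]):
            old = chrom[g]
            chrom[g] = pool[j]
            selected.discard(old)
            selected.add(int(pool[j]))
    return np.sort(chrom)


def ga_select(dense: ZSpectrum, p: float, config: GAConfig | None = None) -> GAResult:
    """Evolve a k = round(p% * N) offset subset minimizing spline-RMSE.

    Termination: the target loss is reached, the best loss stalls
    (improvement below 1e-6 for ``patience`` consecutive generations), or
    ``max_generations`` elapse.  With ``elitism >= 1`` the per-generation
    best fitness is non-increasing.

    Parameters
    ----------
    dense : ZSpectrum
        The dense reference spectrum (fitness evaluates against it).
    p : float
        Selection budget as a percentage of the grid size (10 -> 10%).
    """
    config = config or GAConfig()
    n = len(dense.grid)
    k = int(round(p / 100.0 * n))
    if k < MIN_SUBSET:
        raise ValueError(f"budget p={p}% gives k={k} < {MIN_SUBSET} offsets")
    if k > n:
        raise ValueError("budget exceeds grid size")
    rng = np.random.default_rng(config.seed)
    offs, values = dense.grid.offsets, dense.values

    pop = np.stack([np.sort(rng.choice(n, size=k, replace=False))
                    for _ in range(config.population_size)])
    fits = np.array([_fitness_indices(c, offs, values) for c in pop])

    history: list[float] = []
    best_idx = pop[np.argmin(fits)].copy()
    best_fit = float(fits.min())
    stall = 0
    reason: str = "max_generations"
    gens = 0

    for gens in range(1, config.max_generations + 1):
        order = np.argsort(fits)
        elite = pop[order[: config.elitism]]
        children = [e.copy() for e in elite]
        while len(children) < config.population_size:
            pa = _tournament(pop, fits, config.tournament_size, rng)
            pb = _tournament(pop, fits, config.tournament_size, rng)
            child = _crossover(pa, pb, k, rng)
            child = _mutate(child, n, config.mutation_rate, rng)
            children.append(child)
        pop = np.stack(children)
        fits = np.array([_fitness_indices(c, offs, values) for c in pop])

        gen_best = float(fits.min())
        if gen_best < best_fit - 1e-6:
            best_fit = gen_best
            best_idx = pop[np.argmin(fits)].copy()
            stall = 0
        else:
            if gen_best < best_fit:  # tiny improvement still tracked
                best_fit = gen_best
                best_idx = pop[np.argmin(fits)].copy()
            stall += 1
        history.append(best_fit)

        if config.target_loss is not None and best_fit <= config.target_loss:
            reason = "target_reached"
            break
        if stall >= config.patience:
            reason = "stalled"
            break
    else:
        reason = "max_generations"

    best = OffsetSubset(dense.grid, tuple(int(i) for i in best_idx), fitness=best_fit)
    return GAResult(best=best, history=history, generations_run=gens,
                    termination_reason=reason)  # type: ignore[arg-type]


def _tournament(pop: np.ndarray, fits: np.ndarray, size: int,
                rng: np.random.Generator) -> np.ndarray:
    contenders = rng.integers(0, pop.shape[0], size=size)
    return pop[contenders[np.argmin(fits[contenders])]]


def select_best_candidate(
    candidates: Sequence[GAResult | OffsetSubset],
    spectra: Sequence[ZSpectrum],
    mode: Literal["own", "cross-mean"] = "own",
) -> OffsetSubset:
    """Pick the winning subset among per-spectrum GA candidates.

    ``"own"``: the candidate with the lowest fitness on its own source
    spectrum (requires one candidate per spectrum, ordered alike).
    ``"cross-mean"``: the candidate whose mean RMSE across *all* given
    spectra is lowest — a cross-spectrum robustness criterion.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    subsets = [c.best if isinstance(c, GAResult) else c for c in candidates]
    if mode == "own":
        if len(subsets) != len(spectra):
            raise ValueError("'own' mode needs one candidate per spectrum")
        fits = [s.fitness if s.fitness is not None else fitness(s, spectra[i])
                for i, s in enumerate(subsets)]
        return subsets[int(np.argmin(fits))]
    if mode == "cross-mean":
        means = [float(np.mean([fitness(s, sp) for sp in spectra])) for s in subsets]
        return subsets[int(np.argmin(means))]
    raise ValueError(f"unknown mode {mode!r}")


def prng_select(grid: OffsetGrid, k: int, seed: int | None = None) -> OffsetSubset:
    """Uniform random subset of ``k`` distinct offsets (baseline selector)."""
    n = len(grid)
    if k > n:
        raise ValueError(f"k={k} exceeds grid size {n}")
    if k < 1:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return OffsetSubset(grid, tuple(int(i) for i in idx))


def fixed_select(grid: OffsetGrid, ppm_list: Sequence[float]) -> OffsetSubset:
    """Subset at user-supplied ppm positions (each must match a grid point)."""
    if len(ppm_list) == 0:
        raise ValueError("empty ppm list")
    indices = tuple(grid.index_of(p) for p in ppm_list)
    return OffsetSubset(grid, indices)
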