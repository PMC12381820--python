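"""Synthetic Z-spectrum and phantom generation.

The generator emulates pulsed-saturation mouse-brain CEST data on the
-5..+5 ppm grid: a deep direct-water-saturation dip near 0 ppm, smaller
exchange dips (amide at +3.5 ppm, NOE at -3.5 ppm, a broad semi-solid MT
component and an amine pool), per-pixel B0 shifts, and additive Gaussian
noise on the normalized signal.  The spectral model is a sum of Lorentzian
lines subtracted from unity, Z(dw) = 1 - sum_i L_i(dw - b0); no
Bloch-McConnell exchange dynamics are simulated.

Also implements the two dataset augmentation schemes used to enlarge a
slice-average training corpus: replication with additive white Gaussian
noise, and without-replacement pixel sub-sampling of each slice.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import CESTVolume, OffsetGrid, PoolSpec, ZSpectrum, ZSpectrumTable

__all__ = [
    "DEFAULT_POOLS",
    "make_offset_grid",
    "lorentzian_pool",
    "simulate_zspectrum",
    "elliptical_mask",
    "simulate_phantom",
    "augment_gaussian",
    "augment_subsample",
]

#: Mouse-brain-like default pools.  Amplitudes sum to 1.0 so that noise-free
#: spectra stay in [0, 1].  Not calibrated to any in vivo dataset.
DEFAULT_POOLS: tuple[PoolSpec, ...] = (
    PoolSpec(0.80, 0.0, 1.4, name="water"),
    PoolSpec(0.05, 3.5, 1.0, name="amide"),
    PoolSpec(0.06, -3.5, 2.0, name="noe"),
    PoolSpec(0.06, -1.0, 8.0, name="mt"),
    PoolSpec(0.03, 2.0, 1.2, name="amine"),
)

#: Default acquisition noise on normalized values (also the augmentation sd).
DEFAULT_NOISE_SD = 0.01


def make_offset_grid(start: float, stop: float, step: float) -> OffsetGrid:
    """Uniform saturation-offset grid from ``start`` to ``stop`` inclusive.

    ``make_offset_grid(-5, 5, 0.2)`` gives the 51-point acquisition grid;
    ``make_offset_grid(-5, 5, 0.1)`` the 101-point dense analysis grid.
    """
    return OffsetGrid.from_range(start, stop, step)


def lorentzian_pool(grid: OffsetGrid, pool: PoolSpec) -> np.ndarray:
    """Saturation contribution of one pool at every grid offset.

    Standard Lorentzian lineshape A * (G/2)^2 / ((G/2)^2 + (dw - c)^2) with
    amplitude A, center c and FWHM G; peaks at exactly A when a grid point
    hits the center.
    """
    half = pool.fwhm / 2.0
    return pool.amplitude * half**2 / (half**2 + (grid.offsets - pool.center) ** 2)


def _check_amplitude_sum(pools: Sequence[PoolSpec]) -> None:
    total = sum(p.amplitude for p in pools)
    if total > 1.0 + 1e-12:
        raise ValueError(
            f"pool amplitudes sum to {total:.3f} > 1; spectrum would go negative"
        )


def simulate_zspectrum(
    grid: OffsetGrid,
    pools: Sequence[PoolSpec] = DEFAULT_POOLS,
    b0_shift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ZSpectrum:
    """Simulate one Z-spectrum: ``1 - sum of pools at (dw - b0_shift)`` + noise.

    A positive ``b0_shift`` moves the whole spectrum (water dip included)
    towards positive ppm, mimicking static-field inhomogeneity.  Noise is
    additive white Gaussian on the normalized signal, reproducible for a
    fixed integer seed.
    """
    _check_amplitude_sum(pools)
    shifted = OffsetGrid(grid.offsets - b0_shift) if b0_shift else grid
    values = np.ones(len(grid))
    for pool in pools:
        values -= lorentzian_pool(shifted, pool)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ZSpectrum(grid, np.clip(values, 0.0, 1.05))


def elliptical_mask(shape: tuple[int, int], fill: float = 0.9) -> np.ndarray:
    """Elliptical "brain" mask inscribed in ``shape``, axes scaled by ``fill``."""
    nx, ny = shape
    x = np.arange(nx)[:, None] - (nx - 1) / 2.0
    y = np.arange(ny)[None, :] - (ny - 1) / 2.0
    return (x / (fill * nx / 2)) ** 2 + (y / (fill * ny / 2)) ** 2 <= 1.0


def _smooth_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [-scale, scale]: low-order cosine mixture."""
    nx, ny = shape
    x = np.linspace(0, np.pi, nx)[:, None]
    y = np.linspace(0, np.pi, ny)[None, :]
    coeff = rng.normal(size=(2, 2))
    field = sum(
        coeff[i, j] * np.cos(i * x) * np.cos(j * y) for i in range(2) for j in range(2)
    )
    peak = np.abs(field).max()
    return scale * field / peak if peak > 0 else field


def simulate_phantom(
    n_subjects: int = 19,
    n_slices: int = 2,
    shape: tuple[int, int] = (48, 48),
    grid: OffsetGrid | None = None,
    pools: Sequence[PoolSpec] = DEFAULT_POOLS,
    amplitude_fields: Sequence[np.ndarray] | None = None,
    b0_field: np.ndarray | float | None = None,
    b0_scale: float = 0.2,
    noise_sd: float = DEFAULT_NOISE_SD,
    mask: np.ndarray | str | None = None,
    seed: int | None = None,
) -> list[CESTVolume]:
    """Simulate a cohort of 4D CEST volumes (one per subject).

    Each pixel's spectrum follows :func:`simulate_zspectrum` with per-pixel
    parameters.  ``amplitude_fields`` optionally scales each pool's amplitude
    per pixel (one 2D map per pool); ``b0_field`` fixes the per-pixel shift in
    ppm, otherwise a smooth random field within ``+-b0_scale`` ppm is drawn
    per slice.  ``mask`` may be a boolean map, ``"ellipse"``, or ``None``
    (full frame).  The default cohort mirrors a 19-subject, two-slice study.
    """
    if grid is None:
        grid = make_offset_grid(-5, 5, 0.2)
    _check_amplitude_sum(pools)
    if amplitude_fields is not None:
        if len(amplitude_fields) != len(pools):
            raise ValueError("need one amplitude field per pool")
        for f in amplitude_fields:
            if np.asarray(f).shape != shape:
                raise ValueError("amplitude field shape mismatch")
    if isinstance(mask, str):
        if mask != "ellipse":
            raise ValueError(f"unknown mask preset {mask!r}")
        mask2d = elliptical_mask(shape)
    elif mask is None:
        mask2d = np.ones(shape, dtype=bool)
    else:
        mask2d = np.asarray(mask, dtype=bool)
        if mask2d.shape != shape:
            raise ValueError("mask shape mismatch")

    if b0_field is not None and not np.isscalar(b0_field):
        b0_field = np.asarray(b0_field, dtype=float)
        if b0_field.shape != shape:
            raise ValueError("b0 field shape mismatch")

    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)
    nx, ny = shape
    offs = grid.offsets
    volumes: list[CESTVolume] = []
    for s in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        data = np.empty((nx, ny, n_slices, len(grid)))
        for sl in range(n_slices):
            if b0_field is None:
                b0 = _smooth_field(shape, b0_scale, rng)
            elif np.isscalar(b0_field):
                b0 = np.full(shape, float(b0_field))
            else:
                b0 = b0_field
            # vectorized over pixels: (nx*ny, n_offsets)
            dw = offs[None, :] - b0.reshape(-1, 1)
            z = np.ones((nx * ny, len(grid)))
            for p, pool in enumerate(pools):
                amp = (
                    pool.amplitude * np.asarray(amplitude_fields[p]).reshape(-1, 1)
                    if amplitude_fields is not None
                    else pool.amplitude
                )
                half = pool.fwhm / 2.0
                z -= amp * half**2 / (half**2 + (dw - pool.center) ** 2)
            if noise_sd > 0:
                z = z + rng.normal(0.0, noise_sd, size=z.shape)
            data[:, :, sl, :] = np.clip(z, 0.0, 1.05).reshape(nx, ny, len(grid))
        mask3d = np.repeat(mask2d[:, :, None], n_slices, axis=2)
        volumes.append(CESTVolume(data, grid, mask3d))
    return volumes


def simulate_corpus(
    n_spectra: int,
    grid: OffsetGrid | None = None,
    pools: Sequence[PoolSpec] = DEFAULT_POOLS,
    global_scale: tuple[float, float] = (0.75, 1.0),
    amplitude_jitter: tuple[float, float] = (0.7, 1.3),
    center_jitter: float = 0.2,
    width_jitter: tuple[float, float] = (0.8, 1.3),
    b0_range: float = 0.3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ZSpectrumTable:
    """A diverse corpus of simulated Z-spectra for training/evaluation.

    Each spectrum draws per-pool amplitude and width factors, exchange-pool
    center jitter (the water line stays at 0 ppm; B0 shifts move the whole
    spectrum instead), and a uniform B0 shift in ``+-b0_range`` ppm.  Pool
    amplitudes are capped at their base values so the noise-free spectrum
    stays within [0, 1].  The default variability spans a plausible range of
    tissue composition and shim quality; it is deliberately wide enough that
    a 10-offset sparse sampling no longer fully determines the spectrum.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    if grid is None:
        grid = make_offset_grid(-5, 5, 0.1)
    rng = np.random.default_rng(seed)
    rows = np.empty((n_spectra, len(grid)))
    for i in range(n_spectra):
        scale = rng.uniform(*global_scale)
        varied = []
        for p in pools:
            amp = min(p.amplitude * scale * rng.uniform(*amplitude_jitter),
                      p.amplitude)
            center = p.center
            if p.center != 0.0 and center_jitter > 0:
                center += rng.uniform(-center_jitter, center_jitter)
            fwhm = p.fwhm * rng.uniform(*width_jitter)
            varied.append(PoolSpec(amp, center, fwhm, p.name))
        b0 = rng.uniform(-b0_range, b0_range) if b0_range > 0 else 0.0
        noise_seed = int(rng.integers(0, 2**31)) if noise_sd > 0 else None
        rows[i] = simulate_zspectrum(grid, varied, b0_shift=b0,
                                     noise_sd=noise_sd, seed=noise_seed).values
    return ZSpectrumTable(grid, rows)


def augment_gaussian(
    spectra: ZSpectrumTable,
    n_copies: int = 100,
    noise_mean: float = 0.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    include_base: bool = False,
) -> ZSpectrumTable:
    """Replicate each spectrum ``n_copies`` times with additive Gaussian noise.

    30 base spectra with 100 copies give the 3000-row training corpus.  With
    ``noise_sd`` 0 the copies equal the base rows exactly.
    """
    if len(spectra) == 0:
        raise ValueError("empty input table")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    base = spectra.values
    reps = np.repeat(base, n_copies, axis=0)
    if noise_sd > 0:
        reps = reps + rng.normal(noise_mean, noise_sd, size=reps.shape)
    elif noise_mean:
        reps = reps + noise_mean
    reps = np.clip(reps, 0.0, 1.05)
    if include_base:
        reps = np.vstack([base, reps])
    return ZSpectrumTable(spectra.grid, reps)


def augment_subsample(
    volume: CESTVolume,
    sizes: Sequence[int] = tuple(range(800, 1551, 50)),
    seed: int | None = None,
) -> ZSpectrumTable:
    """Slice-wise pixel sub-sample averages: one spectrum per (slice, size).

    For every slice and every requested sub-sample size, draws that many
    in-mask pixels without replacement and averages their spectra at every
    offset.  The default size ladder 800..1550 by 50 yields 16 spectra per
    slice; over a 38-slice cohort that is the 608-spectrum corpus.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty size list")
    master = np.random.SeedSequence(seed)
    rows = []
    for sl in range(volume.n_slices):
        pix = volume.data[:, :, sl, :][volume.mask[:, :, sl]]  # (n_pix, n_offs)
        n_pix = pix.shape[0]
        slice_seeds = master.spawn(len(sizes))  # stateful: unique per (slice, size)
        for k, size in enumerate(sizes):
            if size > n_pix:
                raise ValueError(f"sub-sample size {size} exceeds {n_pix} in-mask pixels")
            rng = np.random.default_rng(slice_seeds[k])
            idx = rng.choice(n_pix, size=size, replace=False)
            rows.append(pix[idx].mean(axis=0))
    return ZSpectrumTable(volume.grid, np.vstack(rows))
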