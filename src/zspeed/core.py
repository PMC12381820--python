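"""Core data containers for CEST Z-spectrum processing.

A Z-spectrum is the normalized water signal S/S0 measured while an RF
saturation pulse is stepped over frequency offsets (in ppm relative to the
water resonance).  The containers here carry the offset grid, individual
spectra, tables of spectra, and 4D per-pixel volumes (x, y, slice, offset)
for a single subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "OffsetGrid",
    "PoolSpec",
    "ZSpectrum",
    "ZSpectrumTable",
    "CESTVolume",
    "B0Map",
]

#: tolerance on the upper bound of normalized values, allowing additive noise
VALUE_TOL = 0.05
_GRID_TOL = 1e-9


@dataclass(frozen=True)
class OffsetGrid:
    """Uniformly spaced, strictly ascending saturation offsets in ppm."""

    offsets: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("offset grid needs at least two 1D ppm values")
        diffs = np.diff(arr)
        if np.any(diffs <= 0):
            raise ValueError("offsets must be strictly ascending")
        if np.ptp(diffs) > _GRID_TOL:
            raise ValueError("offsets must be uniformly spaced")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "offsets", arr)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "OffsetGrid":
        """Build a grid from ``start`` to ``stop`` inclusive with spacing ``step``.

        The acquired mouse-brain protocol uses (-5, 5, 0.2) -> 51 offsets;
        the dense analysis grid is (-5, 5, 0.1) -> 101 offsets.
        """
        if step <= 0:
            raise ValueError(f"step must be positive, got {step}")
        if stop <= start:
            raise ValueError(f"stop ({stop}) must exceed start ({start})")
        n_steps = (stop - start) / step
        if abs(n_steps - round(n_steps)) > 1e-6:
            raise ValueError(
                f"range ({start}, {stop}) is not an integer multiple of step {step}"
            )
        n = int(round(n_steps)) + 1
        return cls(np.linspace(start, stop, n))

    @property
    def step(self) -> float:
        return float(self.offsets[1] - self.offsets[0])

    @property
    def start(self) -> float:
        return float(self.offsets[0])

    @property
    def stop(self) -> float:
        return float(self.offsets[-1])

    def __len__(self) -> int:
        return self.offsets.size

    def index_of(self, ppm: float, tol: float = 1e-6) -> int:
        """Index of the grid point matching ``ppm`` within ``tol``."""
        idx = int(np.argmin(np.abs(self.offsets - ppm)))
        if abs(self.offsets[idx] - ppm) > tol:
            raise ValueError(f"{ppm} ppm does not match any grid offset")
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OffsetGrid):
            return NotImplemented
        return self.offsets.shape == other.offsets.shape and bool(
            np.allclose(self.offsets, other.offsets, atol=_GRID_TOL)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.offsets.size, self.start, self.stop))


@dataclass(frozen=True)
class PoolSpec:
    """One Lorentzian saturation pool.

    amplitude : unitless peak depth in [0, 1]
    center    : chemical shift of the pool, ppm from water
    fwhm      : full width at half maximum, ppm
    """

    amplitude: float
    center: float
    fwhm: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("pool amplitude must be non-negative")
        if self.fwhm <= 0:
            raise ValueError("pool fwhm must be positive")


@dataclass
class ZSpectrum:
    """A normalized Z-spectrum: S/S0 values on an :class:`OffsetGrid`."""

    grid: OffsetGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ValueError(
                f"values shape {vals.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("Z-spectrum values must be finite")
        if vals.min() < -VALUE_TOL or vals.max() > 1.0 + VALUE_TOL:
            raise ValueError("Z-spectrum values must lie in [0, 1] up to noise tolerance")
        self.values = vals

    def __len__(self) -> int:
        return len(self.grid)


@dataclass
class ZSpectrumTable:
    """A stack of Z-spectra sharing one grid (rows = spectra)."""

    grid: OffsetGrid
    values: np.ndarray  # shape (n_spectra, n_offsets)

    def __post_init__(self) -> None:
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape[1] != len(self.grid):
            raise ValueError("table width must equal grid length")
        self.values = vals

    @classmethod
    def from_spectra(cls, spectra: Sequence[ZSpectrum]) -> "ZSpectrumTable":
        if not spectra:
            raise ValueError("empty spectrum list")
        grid = spectra[0].grid
        for s in spectra[1:]:
            if s.grid != grid:
                raise ValueError("all spectra must share one grid")
        return cls(grid, np.stack([s.values for s in spectra]))

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> ZSpectrum:
        return ZSpectrum(self.grid, self.values[i])

    def __iter__(self) -> Iterator[ZSpectrum]:
        for i in range(len(self)):
            yield self[i]


@dataclass
class CESTVolume:
    """Per-pixel Z-spectra for the slices of one subject.

    ``data[x, y, slice, offset]`` is the normalized pixel intensity
    P(alpha, beta, gamma, phi); ``mask`` flags in-tissue pixels per slice.
    """

    data: np.ndarray  # (nx, ny, n_slices, n_offsets)
    grid: OffsetGrid
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError("CEST volume must be 4D (x, y, slice, offset)")
        if data.shape[3] != len(self.grid):
            raise ValueError("4th axis length must equal grid length")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        if self.mask is None:
            mask = np.ones(data.shape[:3], dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:3]:
                raise ValueError("mask shape must match spatial dims")
        self.data = data
        self.mask = mask

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class B0Map:
    """Per-pixel water-center shift in ppm (one value per pixel and slice)."""

    shifts: np.ndarray
    validity_bound: float = 1.0

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        if not np.all(np.isfinite(shifts)):
            raise ValueError("B0 shifts must be finite")
        if np.any(np.abs(shifts) > self.validity_bound):
            raise ValueError(
                f"|B0 shift| exceeds validity bound {self.validity_bound} ppm"
            )
        self.shifts = shifts
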