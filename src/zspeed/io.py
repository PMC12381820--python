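"""File formats: Z-spectrum CSV tables and NIfTI volumes with ppm sidecars.

CSV layout: the header row holds the ppm offsets (ascending, '.' decimal);
every subsequent row is one spectrum.  4D volumes are NIfTI-1 with the
offset index on the 4th axis and a JSON sidecar carrying the ppm list, the
mask, and optional provenance (seed, config hash).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CESTVolume, OffsetGrid, ZSpectrumTable

__all__ = [
    "read_zspectra_csv",
    "write_zspectra_csv",
    "read_volume",
    "write_volume",
]


def write_zspectra_csv(table: ZSpectrumTable, path: str | Path) -> None:
    """Write a spectrum table: header = ppm offsets, one spectrum per row."""
    df = pd.DataFrame(table.values,
                      columns=[repr(float(v)) for v in table.grid.offsets])
    df.to_csv(path, index=False)


def read_zspectra_csv(path: str | Path) -> ZSpectrumTable:
    """Read a spectrum table; the header must parse as ascending ppm values."""
    df = pd.read_csv(path)
    try:
        offsets = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric ppm header in {path}") from exc
    if np.any(np.diff(offsets) <= 0):
        raise ValueError(f"header offsets not strictly ascending in {path}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-numeric or missing cells in {path}")
    return ZSpectrumTable(OffsetGrid(offsets), values)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: CESTVolume, path: str | Path,
                 seed: int | None = None, config_hash: str | None = None) -> None:
    """Write a 4D CEST volume as NIfTI-1 plus a JSON ppm/mask sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = {
        "offsets_ppm": [float(v) for v in volume.grid.offsets],
        "mask": volume.mask.astype(int).tolist(),
        "axes": ["x", "y", "slice", "offset"],
    }
    if seed is not None:
        sidecar["seed"] = seed
    if config_hash is not None:
        sidecar["config_hash"] = config_hash
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_volume(path: str | Path) -> CESTVolume:
    """Read a volume written by :func:`write_volume`.

    The sidecar ppm list must match the 4th-axis length.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    offsets = np.array(sidecar["offsets_ppm"], dtype=float)
    if data.ndim != 4 or data.shape[3] != offsets.size:
        raise ValueError(
            f"sidecar lists {offsets.size} offsets but volume has "
            f"{data.shape[3] if data.ndim == 4 else '?'} frames"
        )
    mask = np.array(sidecar["mask"], dtype=bool) if "mask" in sidecar else None
    return CESTVolume(data, OffsetGrid(offsets), mask)
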