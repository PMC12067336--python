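"""Disk formats: 32-bit TIFF stacks for volumes, HDF5 for sinogram stacks,
CSV for lacuna tables, JSON for reports and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .forward_model import Sinogram

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "write_sinograms",
    "read_sinograms",
    "write_lacuna_table",
    "read_lacuna_table",
    "write_json",
]


def write_tiff_stack(path: str | Path, volume: np.ndarray) -> None:
    """Multi-page TIFF; float volumes are written as 32-bit grayscale."""
    volume = np.asarray(volume)
    if volume.dtype.kind == "f":
        volume = volume.astype(np.float32)
    tifffile.imwrite(str(path), volume)


def read_tiff_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_sinograms(path: str | Path, sinos: list[Sinogram]) -> None:
    with h5py.File(path, "w") as fh:
        for s in sinos:
            g = fh.create_group(f"slice_{s.slice_index:05d}")
            g.create_dataset("data", data=s.data)
            g.create_dataset("angles", data=s.angles)
            g.attrs["photons_per_pixel"] = s.photons_per_pixel
            g.attrs["slice_index"] = s.slice_index
            g.attrs["pixel_size_um"] = s.pixel_size_um


def read_sinograms(path: str | Path) -> list[Sinogram]:
    sinos = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            sinos.append(
                Sinogram(
                    data=g["data"][()],
                    angles=g["angles"][()],
                    photons_per_pixel=float(g.attrs["photons_per_pixel"]),
                    slice_index=int(g.attrs["slice_index"]),
                    pixel_size_um=float(g.attrs["pixel_size_um"]),
                )
            )
    return sinos


def write_lacuna_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_lacuna_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
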