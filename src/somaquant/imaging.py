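"""Multi-channel stack container and TIFF/CSV input-output.

The four channels are named for the markers they image:

- ``neurotrace`` — fluorescent Nissl counterstain (neuronal somata, some glia)
- ``neun``       — NeuN/RbFox3 immunolabel (most neurons)
- ``pcjun``      — phospho-c-Jun (Ser63) immunolabel (axotomized neurons)
- ``draq5``      — DNA dye (all nuclei; the segmentation seed channel)

Stacks round-trip through OME-TIFF with voxel sizes in the metadata; label
volumes round-trip as integer TIFF; cell tables as CSV with a stable,
documented column order (:data:`somaquant.quantify.CELL_TABLE_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import RoiSpec, VoxelGrid

__all__ = [
    "CHANNEL_NAMES",
    "MultiChannelStack",
    "read_stack",
    "write_stack",
    "extract_roi",
    "read_label_volume",
    "write_label_volume",
    "read_cell_table",
    "write_cell_table",
]

#: Canonical channel order used for on-disk channel axes.
CHANNEL_NAMES = ("neurotrace", "neun", "pcjun", "draq5")


@dataclass
class MultiChannelStack:
    """A 3D voxel grid with four named non-negative intensity channels."""

    grid: VoxelGrid
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel name {name!r}")
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} != grid {self.grid.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def replace_channels(self, channels: dict[str, np.ndarray]) -> "MultiChannelStack":
        return MultiChannelStack(self.grid, channels)


def write_stack(stack: MultiChannelStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with CZYX axes and physical voxel sizes."""
    data = np.stack([stack.channels[c] for c in CHANNEL_NAMES], axis=0)
    g = stack.grid
    tifffile.imwrite(
        Path(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": g.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": g.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": g.dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(CHANNEL_NAMES)},
        },
    )


def _voxel_size_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if tif.ome_metadata is None:
        return None
    meta = tifffile.xml2dict(tif.ome_metadata)
    try:
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        px = image["Pixels"]
        return (
            float(px["PhysicalSizeZ"]),
            float(px["PhysicalSizeY"]),
            float(px["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> MultiChannelStack:
    """Read a multi-channel TIFF/OME-TIFF stack.

    Parameters
    ----------
    path : path
        TIFF/OME-TIFF file with a channel axis of at least four planes.
    channel_map : dict, optional
        Channel name → index along the channel axis.  Defaults to the
        canonical order :data:`CHANNEL_NAMES`.
    voxel_size_um : (dz, dy, dx), optional
        Explicit voxel size override.  If omitted, voxel sizes must be present
        in the OME metadata; missing metadata with no override is an error
        rather than a silent default.
    """
    path = Path(path)
    channel_map = channel_map or {c: i for i, c in enumerate(CHANNEL_NAMES)}
    with tifffile.TiffFile(path) as tif:
        data = tif.series[0].asarray()
        meta_size = _voxel_size_from_ome(tif)
    if data.ndim == 3:  # single channel stored as ZYX
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected a 4D CZYX stack, got shape {data.shape}")
    n_chan = data.shape[0]
    needed = max(channel_map.values()) + 1
    if n_chan < needed:
        raise ValueError(
            f"file has {n_chan} channels but channel_map needs {needed}"
        )
    size = voxel_size_um if voxel_size_um is not None else meta_size
    if size is None:
        raise ValueError(
            f"{path}: no voxel size metadata; pass voxel_size_um explicitly"
        )
    dz, dy, dx = size
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel sizes must be strictly positive")
    nz, ny, nx = data.shape[1:]
    grid = VoxelGrid(nz, ny, nx, dz, dy, dx)
    channels = {
        name: np.ascontiguousarray(data[idx]) for name, idx in channel_map.items()
    }
    return MultiChannelStack(grid, channels)


def extract_roi(stack: MultiChannelStack, roi: RoiSpec) -> MultiChannelStack:
    """Crop the XY analysis rectangle; full depth, intensities untouched."""
    ys, xs = roi.voxel_bounds(stack.grid)
    grid = stack.grid.with_shape(
        stack.grid.nz, ys.stop - ys.start, xs.stop - xs.start
    )
    channels = {name: arr[:, ys, xs].copy() for name, arr in stack.channels.items()}
    return MultiChannelStack(grid, channels)


def write_label_volume(
    labels: np.ndarray, path: str | Path, grid: VoxelGrid | None = None
) -> None:
    """Write an integer label volume as (OME-)TIFF."""
    labels = np.asarray(labels)
    if labels.ndim != 3 or not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label volume must be a 3D integer array")
    meta = {"axes": "ZYX"}
    if grid is not None:
        meta.update(
            PhysicalSizeX=grid.dx, PhysicalSizeY=grid.dy, PhysicalSizeZ=grid.dz
        )
    tifffile.imwrite(Path(path), labels.astype(np.uint32), ome=True, metadata=meta)


def read_label_volume(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(Path(path))
    if labels.ndim != 3:
        raise ValueError(f"expected 3D label volume, got shape {labels.shape}")
    return labels.astype(np.int64)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a cell table as CSV with the documented stable column order."""
    from .quantify import CELL_TABLE_COLUMNS

    cols = [c for c in CELL_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(Path(path), index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    from .quantify import BOOL_COLUMNS

    table = pd.read_csv(Path(path), float_precision="round_trip")
    for c in BOOL_COLUMNS:
        if c in table.columns:
            table[c] = table[c].astype(bool)
    return table
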