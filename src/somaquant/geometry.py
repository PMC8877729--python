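"""Voxel geometry: grids, physical units and rectangular analysis ROIs.

All label volumes and channel arrays in this package live on a
:class:`VoxelGrid` with axis order ``(z, y, x)``, 0-based voxel indices and
voxel-center physical coordinates.  The grid is the single source of the
voxel-volume conversion used by every downstream volume measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VoxelGrid", "RoiSpec", "DEFAULT_VOXEL_SIZE_UM"]

#: Spinning-disk acquisition default voxel edge lengths (dz, dy, dx) in µm.
DEFAULT_VOXEL_SIZE_UM = (0.44, 0.67, 0.67)


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and physical voxel size of a 3D stack.

    Parameters
    ----------
    nz, ny, nx : int
        Voxel counts along z, y, x.  Strictly positive.
    dz, dy, dx : float
        Voxel edge lengths in µm.  Strictly positive.  The defaults are the
        0.67 × 0.67 µm lateral / 0.44 µm axial sampling of a 20x spinning-disk
        acquisition.
    """

    nz: int
    ny: int
    nx: int
    dz: float = DEFAULT_VOXEL_SIZE_UM[0]
    dy: float = DEFAULT_VOXEL_SIZE_UM[1]
    dx: float = DEFAULT_VOXEL_SIZE_UM[2]

    def __post_init__(self) -> None:
        if min(self.nz, self.ny, self.nx) <= 0:
            raise ValueError("voxel counts must be positive")
        if min(self.dz, self.dy, self.dx) <= 0:
            raise ValueError("voxel edge lengths must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³ (product of the configured edges).

        Note the widely used rounded figure 0.196 µm³ for 0.67 × 0.67 × 0.44 µm
        voxels; the exact product is ≈0.1975 µm³ and this package always uses
        the product of the configured edges, never a rounded constant.
        """
        return self.dx * self.dy * self.dz

    def with_shape(self, nz: int, ny: int, nx: int) -> "VoxelGrid":
        return VoxelGrid(nz, ny, nx, self.dz, self.dy, self.dx)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular XY analysis region, full stack depth.

    The quantification region is a 630 × 200 µm rectangle placed with its long
    axis parallel to the cortical laminae in layer V/VI.  Placement is manual
    in practice (guided by the NeuN channel); here the offsets are explicit
    configuration.

    Parameters
    ----------
    width_um, height_um : float
        XY extent in µm (width along x, height along y).
    origin_x_um, origin_y_um : float
        Offset of the ROI's (y, x) origin from the stack origin, in µm.
    orientation_note : str
        Free-text placement note carried into run manifests.
    """

    width_um: float = 630.0
    height_um: float = 200.0
    origin_x_um: float = 0.0
    origin_y_um: float = 0.0
    orientation_note: str = "long axis parallel to cortical laminae"

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI extent must be positive")
        if self.origin_x_um < 0 or self.origin_y_um < 0:
            raise ValueError("ROI origin offsets must be non-negative")

    def voxel_bounds(self, grid: VoxelGrid) -> tuple[slice, slice]:
        """(y, x) slices of the ROI on ``grid``; raises if out of bounds."""
        x0 = round(self.origin_x_um / grid.dx)
        y0 = round(self.origin_y_um / grid.dy)
        w = round(self.width_um / grid.dx)
        h = round(self.height_um / grid.dy)
        if x0 + w > grid.nx or y0 + h > grid.ny:
            raise ValueError(
                f"ROI {w}x{h} vox at ({y0},{x0}) exceeds stack XY extent "
                f"{grid.ny}x{grid.nx}"
            )
        return slice(y0, y0 + h), slice(x0, x0 + w)
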