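"""The :class:`VoxelGrid` container: a 3D (optionally multi-channel)
intensity volume with physical voxel sizes, plus TIFF/OME-TIFF I/O.

Axis order is ``(C, Z, Y, X)`` for multi-channel data and ``(Z, Y, X)`` for
a single channel; voxel sizes are given in nanometres per axis, ``(z, y, x)``.

Coordinate convention (fixed package-wide): voxel indices are 0-based and
the physical position of voxel ``(k, j, i)`` is its **centre**,
``((k + 0.5) * dz, (j + 0.5) * dy, (i + 0.5) * dx)`` in nm, with the origin
at the image corner.  Point coordinates throughout the package are stored
``(z, y, x)`` in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .units import ExmError

__all__ = ["VoxelGrid", "read_volume", "write_volume"]


@dataclass
class VoxelGrid:
    """A physical intensity volume.

    Parameters
    ----------
    data:
        Array of shape ``(Z, Y, X)`` or ``(C, Z, Y, X)``.
    voxel_size:
        ``(dz, dy, dx)`` in nm.
    channels:
        Channel names, required iff ``data`` is 4-D.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: tuple[str, ...] | None = None
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin_nm = tuple(float(v) for v in self.origin_nm)
        if len(self.voxel_size) not in (2, 3) or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive (z,)y,x nm values, got {self.voxel_size}")
        if self.data.ndim == 2:
            if len(self.voxel_size) != 2:
                raise ValueError("2-D images take a 2-value (y, x) pixel size")
            if self.channels is not None and len(self.channels) != 1:
                raise ValueError("2-D data carries at most one channel name")
        elif self.data.ndim == 3:
            if self.channels is not None and len(self.channels) != 1:
                raise ValueError("3-D data carries at most one channel name")
        elif self.data.ndim == 4:
            if self.channels is None or len(self.channels) != self.data.shape[0]:
                raise ValueError("4-D data requires one channel name per leading axis entry")
            self.channels = tuple(self.channels)
        else:
            raise ValueError(
                f"data must be 2-D (Y,X), 3-D (Z,Y,X) or 4-D (C,Z,Y,X), got ndim={self.data.ndim}"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) of the volume in nm."""
        return tuple(n * v for n, v in zip(self.spatial_shape, self.voxel_size))

    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str) -> "VoxelGrid":
        """Single-channel view (shares memory with the parent)."""
        if self.data.ndim == 3:
            if self.channels and name != self.channels[0]:
                raise KeyError(name)
            return self
        if self.channels is None or name not in self.channels:
            raise KeyError(name)
        idx = self.channels.index(name)
        return VoxelGrid(self.data[idx], self.voxel_size, (name,), self.origin_nm)

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Voxel indices (z,y,x) -> physical nm coordinates of voxel centres."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_nm) + (idx + 0.5) * np.asarray(self.voxel_size)

    def physical_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Physical nm coordinates -> fractional voxel indices (z,y,x)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        return (pos - np.asarray(self.origin_nm)) / np.asarray(self.voxel_size) - 0.5

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of points lying inside the physical bounds."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        origin = np.asarray(self.origin_nm)
        extent = np.asarray(self.physical_extent)
        return np.all((pos >= origin) & (pos < origin + extent), axis=1)


def write_volume(path, grid: VoxelGrid) -> None:
    """Write a :class:`VoxelGrid` as a TIFF stack with voxel-size metadata.

    Voxel sizes are stored in the ImageJ-compatible resolution fields (in µm)
    and the full metadata (sizes in nm, channel names) additionally as JSON
    in the image description, so a round trip is lossless.
    """
    dz, dy, dx = grid.voxel_size
    meta = {
        "voxel_size_nm": [dz, dy, dx],
        "channels": list(grid.channels) if grid.channels else None,
        "axes": "CZYX" if grid.data.ndim == 4 else "ZYX",
    }
    tifffile.imwrite(
        str(path),
        np.asarray(grid.data, dtype=np.float32),
        resolution=(1e3 / dx, 1e3 / dy),
        metadata=None,
        description=json.dumps(meta),
    )


def read_volume(path) -> VoxelGrid:
    """Read a TIFF written by :func:`write_volume` (or any TIFF with the
    JSON voxel-size description)."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        meta = json.loads(desc)
        voxel = tuple(meta["voxel_size_nm"])
        channels = tuple(meta["channels"]) if meta.get("channels") else None
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ExmError(f"{path}: missing voxel-size metadata required to interpret the stack") from exc
    if meta.get("axes") == "CZYX" and channels is not None and data.ndim == 3:
        # pages flatten C and Z; restore the channel axis
        data = data.reshape(len(channels), -1, *data.shape[-2:])
    return VoxelGrid(data, voxel, channels)
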