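"""Core image containers: multichannel voxel images and labeled region masks.

All pipeline stages operate on :class:`VoxelImage` (a ``channel x Z x Y x X``
intensity grid with physical voxel size) and :class:`RegionMask` (a boolean
grid aligned to an image, labeled by what it delineates: nucleus, Xi
territory, control ROI, nuclear scaffold, halo...).  2D images are stored
with a singleton Z axis so every operation can assume four axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["VoxelImage", "RegionMask", "read_image", "write_image"]

#: Region labels with defined semantics in this package.
REGION_LABELS = (
    "nucleus",
    "xi",
    "control_roi",
    "scaffold",
    "total",
    "halo",
    "chromocenter",
)


@dataclass
class VoxelImage:
    """Multichannel 2D/3D fluorescence image with physical voxel size.

    Parameters
    ----------
    data
        Intensity array of shape ``(C, Z, Y, X)``.  A ``(C, Y, X)`` array is
        promoted to a singleton Z axis.  Intensities must be finite and
        non-negative (fluorescence counts).
    channel_names
        One unique label per channel, e.g. ``("DAPI", "H3K27me3", "EdU")``.
    voxel_size
        Physical voxel extent ``(z, y, x)`` in micrometres, all positive.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:  # (C, Y, X) -> (C, 1, Y, X)
            arr = arr[:, None, :, :]
        if arr.ndim != 4:
            raise ValueError(
                f"expected (C, Z, Y, X) or (C, Y, X) data, got shape {arr.shape}"
            )
        if arr.size == 0:
            raise ValueError("image has zero voxels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.data = arr
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != arr.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive numbers, got {vs}")
        self.voxel_size = vs

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(Z, Y, X)``."""
        return self.data.shape[1:]

    @property
    def is_2d(self) -> bool:
        return self.data.shape[1] == 1

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size
        return z * y * x

    @property
    def pixel_area_um2(self) -> float:
        _, y, x = self.voxel_size
        return y * x

    # -- access -------------------------------------------------------------

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` array for one channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def max_projection(self, name: str) -> np.ndarray:
        """Maximum-intensity Z-projection of one channel, shape ``(Y, X)``."""
        return self.channel(name).max(axis=0)


@dataclass
class RegionMask:
    """Boolean region aligned to a :class:`VoxelImage`.

    The physical size (``area_or_volume``) is derived exactly from the voxel
    count: ``n_true * voxel volume`` for 3D masks, ``n_true * pixel area``
    for single-slice masks.
    """

    mask: np.ndarray
    label: str
    voxel_size: tuple[float, float, float]
    area_or_volume: float = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim == 2:
            m = m[None, :, :]
        if m.ndim != 3:
            raise ValueError(f"mask must be 2D or 3D, got shape {m.shape}")
        self.mask = m
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = vs
        n = int(m.sum())
        if m.shape[0] == 1:
            self.area_or_volume = n * vs[1] * vs[2]
        else:
            self.area_or_volume = n * vs[0] * vs[1] * vs[2]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def check_alignment(self, image: VoxelImage) -> None:
        if self.mask.shape != image.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image spatial "
                f"shape {image.shape}"
            )

    def projected(self) -> "RegionMask":
        """2D footprint of the mask (any over Z), as a single-slice mask.
        The footprint is the region a 2D ROI drawn on a maximum-intensity
        projection would cover."""
        return RegionMask(self.mask.any(axis=0)[None], self.label, self.voxel_size)

    def centroid_um(self) -> tuple[float, float, float]:
        """Centroid in physical (z, y, x) micrometres."""
        if self.is_empty:
            raise ValueError("empty mask has no centroid")
        idx = np.argwhere(self.mask).mean(axis=0)
        return tuple(float(i * v) for i, v in zip(idx, self.voxel_size))


# -- I/O ---------------------------------------------------------------------


def write_image(path: str | Path, image: VoxelImage) -> None:
    """Write a multichannel TIFF with voxel size and channel names in metadata."""
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "channel_names": list(image.channel_names),
        "voxel_size_um_zyx": list(image.voxel_size),
    }
    tifffile.imwrite(path, image.data, metadata=meta, photometric="minisblack")


def read_image(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    voxel_size: Sequence[float] | None = None,
) -> VoxelImage:
    """Read a TIFF written by :func:`write_image` (or any CZYX/CYX stack).

    ``channel_names`` and ``voxel_size`` override metadata when the file
    carries none (e.g. stacks exported from other software).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = channel_names or meta.get("channel_names")
    vs = voxel_size or meta.get("voxel_size_um_zyx")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3 and names is not None and data.shape[0] == len(names):
        data = data[:, None]
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if vs is None:
        raise ValueError(f"{path}: no voxel size in metadata; pass voxel_size=")
    return VoxelImage(data, tuple(names), tuple(vs))


def write_ground_truth(path: str | Path, payload: dict) -> None:
    """Write a JSON side-car (ground truth, run configs)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
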