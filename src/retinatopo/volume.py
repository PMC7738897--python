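"""Voxel-grid containers for 3-D vascular stacks.

Arrays are indexed ``[z][y][x]``; world coordinates are ``(x, y, z)`` in µm.
The world position of voxel ``(iz, iy, ix)`` is
``origin_um + (ix + 0.5, iy + 0.5, iz + 0.5) * voxel_size_um`` — i.e. the
origin is the world position of the corner of voxel (0, 0, 0).

Volumes are written as multi-page TIFF z-stacks with a JSON metadata sidecar
(``{voxel_size_um, origin_um, kind, ...}``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

#: Label codes used throughout the package.
BACKGROUND = 0
PLEXUS = 1
SPROUT = 2
LABEL_NAMES = {BACKGROUND: "background", PLEXUS: "plexus", SPROUT: "sprout"}


class GridError(ValueError):
    """Two volumes do not share a voxel grid."""


@dataclasses.dataclass
class VolumeImage:
    """A 3-D scalar or binary image with µm voxel size and world origin."""

    data: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3, dtype=float)
    )
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin_um = np.asarray(self.origin_um, dtype=float).reshape(3)

    # ---- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def voxel_centers(self, indices_zyx: np.ndarray) -> np.ndarray:
        """World ``(x, y, z)`` centers of voxels given as an ``(n, 3)`` zyx array."""
        idx = np.atleast_2d(np.asarray(indices_zyx))
        xyz = idx[:, ::-1].astype(float) + 0.5
        return self.origin_um + xyz * self.voxel_size_um

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.data != 0)

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.voxel_size_um, other.voxel_size_um)
            and np.allclose(self.origin_um, other.origin_um)
        )

    # ---- I/O ------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        write_volume(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        return _read(path, cls)


@dataclasses.dataclass
class LabelVolume(VolumeImage):
    """Same grid as a :class:`VolumeImage`, voxels classed background/plexus/sprout."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.uint8, copy=False)

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.data, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def foreground_count(self) -> int:
        return int((self.data != BACKGROUND).sum())

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        return _read(path, cls)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a multi-page TIFF z-stack plus JSON metadata sidecar."""
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data)
    meta = {
        "voxel_size_um": float(vol.voxel_size_um),
        "origin_um": [float(v) for v in vol.origin_um],
        "kind": "labels" if isinstance(vol, LabelVolume) else "volume",
    }
    meta.update(vol.meta)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read(path: str | Path, cls):
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:  # single-page stack
        data = data[None]
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    voxel = float(meta.pop("voxel_size_um", 1.0))
    origin = np.asarray(meta.pop("origin_um", (0.0, 0.0, 0.0)), dtype=float)
    meta.pop("kind", None)
    return cls(data=data, voxel_size_um=voxel, origin_um=origin, meta=meta)


def read_volume(path: str | Path) -> VolumeImage:
    return VolumeImage.load(path)


def read_labels(path: str | Path) -> LabelVolume:
    return LabelVolume.load(path)
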