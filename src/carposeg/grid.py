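"""Voxel-grid containers shared by the phantom and segmentation stages.

Arrays are indexed ``(i, j, k)`` along the physical ``(x, y, z)`` axes, with
an affine index->physical mapping ``p = origin + index * spacing``.  The grid
is always axis-aligned; anisotropy lives entirely in ``spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk


class GridError(ValueError):
    """Raised for inconsistent grid geometry."""


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GridError(f"spacing must be three positive floats, got {spacing!r}")
    return spacing


@dataclass
class ImageVolume:
    """A 3-D scalar CT-like volume in Hounsfield units.

    Parameters
    ----------
    data
        Scalar grid, shape ``(nx, ny, nz)``; stored as float32.
    spacing
        Physical voxel spacing in mm per axis, ``(sx, sy, sz)``.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GridError(f"volume must be 3-D with >=1 voxel per axis, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to physical mm coordinates."""
        return np.asarray(index, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        return (np.asarray(point, dtype=float) - np.array(self.origin)) / np.array(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            np.arange(n) * s + o
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing, self.origin)

    def to_sitk(self) -> sitk.Image:
        """Convert to a SimpleITK image (which indexes arrays z, y, x)."""
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            data=sitk.GetArrayFromImage(img).T,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )


@dataclass
class LabelMask:
    """Binary voxel mask congruent with a source :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise GridError(f"mask must be 3-D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, other) -> None:
        if self.shape != other.shape or not np.allclose(self.spacing, other.spacing):
            raise GridError(
                f"grids not congruent: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}"
            )


@dataclass
class LevelSetImage:
    """Scalar level-set field on an image grid; negative inside the object."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise GridError(f"level set must be 3-D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def has_both_signs(self) -> bool:
        return bool((self.data < 0).any() and (self.data > 0).any())

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img
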