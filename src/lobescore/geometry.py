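"""Voxel-grid geometry and conversions to/from SimpleITK and NIfTI affines.

Arrays are indexed ``(i0, i1, i2)`` (numpy order).  A :class:`ViewGeometry`
maps array indices to physical millimetre coordinates via

    x_mm = origin + direction @ (spacing * index)

where ``direction[:, a]`` is the world-space unit vector of array axis ``a``.
All cross-view operations (mask resampling, dual-view rendering) go through
this physical space, so anisotropic, differently-oriented acquisitions of the
same anatomy line up exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["ViewGeometry", "to_sitk", "from_sitk", "affine_from_geometry"]


@dataclass(frozen=True)
class ViewGeometry:
    """Origin / spacing / orientation of one acquired view.

    Parameters
    ----------
    origin : (3,) float
        Physical coordinate (mm) of the voxel with index (0, 0, 0).
    spacing : (3,) float
        Millimetres per voxel along each *array* axis; strictly positive.
    direction : (3, 3) float
        Orthonormal matrix whose column ``a`` is the physical direction of
        array axis ``a``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    direction: tuple[float, ...] = field(
        default=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    )

    def __post_init__(self) -> None:
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        R = self.direction_matrix
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal (atol 1e-6)")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) array indices (may be fractional) to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        return np.asarray(self.origin) + (idx * sp) @ self.direction_matrix.T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) mm coordinates to fractional array indices."""
        pts = np.asarray(pts, dtype=float)
        rel = (pts - np.asarray(self.origin)) @ self.direction_matrix
        return rel / np.asarray(self.spacing)

    def grid_physical(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Physical coordinates of every voxel centre: (*shape, 3) array."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)


def to_sitk(volume: np.ndarray, geom: ViewGeometry) -> sitk.Image:
    """Wrap a numpy volume + geometry as a SimpleITK image.

    SimpleITK indexes (x, y, z) = reversed numpy order, so spacing is
    reversed and direction columns are flipped accordingly.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume))
    img.SetSpacing(tuple(float(s) for s in geom.spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in geom.origin))
    img.SetDirection(tuple(geom.direction_matrix[:, ::-1].ravel()))
    return img


def from_sitk(img: sitk.Image) -> tuple[np.ndarray, ViewGeometry]:
    """Inverse of :func:`to_sitk`."""
    vol = sitk.GetArrayFromImage(img)
    D = np.asarray(img.GetDirection()).reshape(3, 3)
    geom = ViewGeometry(
        origin=tuple(img.GetOrigin()),
        spacing=tuple(img.GetSpacing()[::-1]),
        direction=tuple(D[:, ::-1].ravel()),
    )
    return vol, geom


def affine_from_geometry(geom: ViewGeometry) -> np.ndarray:
    """4x4 NIfTI-style affine mapping array indices to mm."""
    aff = np.eye(4)
    aff[:3, :3] = geom.direction_matrix @ np.diag(geom.spacing)
    aff[:3, 3] = geom.origin
    return aff
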