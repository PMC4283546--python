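"""Volumetric image container.

A 3-D scalar lattice with a world affine is the currency every stage of the
pipeline trades in: T1 and Dixon renders, attenuation maps, reconstructed
PET, perfusion maps and binary masks are all :class:`Image3D`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Image3D"]


class Image3D:
    """A scalar 3-D volume with voxel spacing and a world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  Finite everywhere unless an operation's contract
        explicitly produces masked (NaN) voxels.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world mapping.  Defaults to a diagonal affine built from
        ``spacing`` with the volume centre at the world origin.
    spacing : tuple of float, optional
        Voxel size in mm per axis; ignored when ``affine`` is given.
    """

    def __init__(self, data, affine=None, spacing=None):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"Image3D requires a 3-D array, got ndim={data.ndim}")
        self.data = data
        if affine is None:
            sp = np.asarray(spacing if spacing is not None else (1.0, 1.0, 1.0), float)
            if sp.size == 1:
                sp = np.repeat(sp, 3)
            affine = np.diag(np.append(sp, 1.0))
            # centre the volume on the world origin
            affine[:3, 3] = -sp * (np.asarray(data.shape) - 1) / 2.0
        self.affine = np.asarray(affine, float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "Image3D":
        """New image on the same grid carrying ``data``."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.data.shape}")
        return Image3D(data, affine=self.affine.copy())

    def same_grid(self, other: "Image3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sp = ", ".join(f"{s:g}" for s in self.spacing)
        return f"Image3D(shape={self.data.shape}, spacing=({sp}) mm)"


def require_same_grid(*images: Image3D) -> None:
    """Raise ValueError unless all images share one grid."""
    first = images[0]
    for im in images[1:]:
        if not first.same_grid(im):
            raise ValueError("images are not on the same grid")
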