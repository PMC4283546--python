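"""NIfTI-1 reading and writing for :class:`~dixbone.image.Image3D`."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .image import Image3D

__all__ = ["read_nifti", "write_nifti"]


def read_nifti(path) -> Image3D:
    """Load a 3-D NIfTI-1 volume.

    Raises
    ------
    ValueError
        If the file is not 3-D or its header carries non-positive zooms;
        the message names the offending field.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"header field dim: expected 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"header field pixdim: non-positive zooms {zooms}")
    return Image3D(np.asarray(data, dtype=np.float64), affine=img.affine)


def write_nifti(image: Image3D, path) -> None:
    """Write an image as NIfTI-1, preserving its affine (and hence spacing)."""
    nii = nib.Nifti1Image(np.asarray(image.data, dtype=np.float64), image.affine)
    nii.header.set_zooms(tuple(image.spacing))
    nib.save(nii, str(path))


def read_nifti_series(path) -> list[Image3D]:
    """Load a 4-D NIfTI as an ordered list of 3-D frames."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"header field dim: expected 4-D series, got shape {data.shape}")
    return [Image3D(np.asarray(data[..., t], float), affine=img.affine)
            for t in range(data.shape[3])]


def write_nifti_series(frames: list[Image3D], path) -> None:
    """Write an ordered list of same-grid frames as one 4-D NIfTI,
    preserving the frame dtype (ASL series are rendered float32)."""
    stack = np.stack([f.data for f in frames], axis=-1)
    nib.save(nib.Nifti1Image(stack, frames[0].affine), str(path))
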