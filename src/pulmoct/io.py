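"""Volume I/O in NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd) via SimpleITK.

Arrays are stored internally as (x, y, z); SimpleITK uses (z, y, x), so axes
are transposed at the boundary. Masks are written as 8-bit 0/1. Spacing and
origin are carried in the header in millimetres.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import BinaryMask, ImageVolume

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_path(path: Path):
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUFFIXES):
        raise ValueError(
            f"unsupported format {path.suffix!r}; use one of {_SUFFIXES}"
        )


def read_volume(path) -> ImageVolume:
    path = Path(path)
    _check_path(path)
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(values, img.GetSpacing(), img.GetOrigin())


def write_volume(volume: ImageVolume, path) -> None:
    path = Path(path)
    _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".nii.gz"))


def read_mask(path) -> BinaryMask:
    path = Path(path)
    _check_path(path)
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return BinaryMask(values != 0, img.GetSpacing(), img.GetOrigin())


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.values.transpose(2, 1, 0).astype(np.uint8))
    )
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".nii.gz"))
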