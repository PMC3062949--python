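"""Volume readers/writers and maximum-intensity projection.

Supported formats, chosen by extension: multi-page TIFF stacks
(``.tif``/``.tiff``, via tifffile, spacing stored as JSON in the image
description), NRRD (``.nrrd``) and MetaImage (``.mhd``/``.mha``) via
SimpleITK.  Arrays are (z, y, x); spacing metadata round-trips, and
intensities are preserved bit-exactly for integer types.
"""

from __future__ import annotations

import json
import os
from typing import Union

import numpy as np
import SimpleITK as sitk
import tifffile

from .errors import InvalidParameterError, VolumeFormatError
from .volume import Volume

__all__ = ["read_volume", "write_volume", "mip_project", "SUPPORTED_EXTENSIONS"]

SUPPORTED_EXTENSIONS = (".tif", ".tiff", ".nrrd", ".mhd", ".mha")

_DESCRIPTION_KEY = "tubeness"


def _ext(path: Union[str, os.PathLike]) -> str:
    return os.path.splitext(str(path))[1].lower()


def write_volume(vol: Volume, path: Union[str, os.PathLike]) -> None:
    """Write a volume; format chosen by extension."""
    ext = _ext(path)
    if ext in (".tif", ".tiff"):
        meta = {_DESCRIPTION_KEY: {"spacing": list(vol.spacing),
                                   "origin": list(vol.origin)}}
        tifffile.imwrite(str(path), vol.data, description=json.dumps(meta))
    elif ext in (".nrrd", ".mhd", ".mha"):
        img = sitk.GetImageFromArray(vol.data)
        img.SetSpacing(tuple(reversed(vol.spacing)))  # sitk order is (x, y, z)
        img.SetOrigin(tuple(reversed(vol.origin)))
        sitk.WriteImage(img, str(path))
    else:
        raise VolumeFormatError(
            f"unsupported extension {ext!r} for {path!s}; "
            f"supported: {', '.join(SUPPORTED_EXTENSIONS)}"
        )


def read_volume(path: Union[str, os.PathLike]) -> Volume:
    """Read a volume; format chosen by extension."""
    path = str(path)
    ext = _ext(path)
    if ext not in SUPPORTED_EXTENSIONS:
        raise VolumeFormatError(
            f"unsupported extension {ext!r} for {path}; "
            f"supported: {', '.join(SUPPORTED_EXTENSIONS)}"
        )
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    if ext == ".mhd" :
        raw = os.path.splitext(path)[0] + ".raw"
        zraw = os.path.splitext(path)[0] + ".zraw"
        if not (os.path.exists(raw) or os.path.exists(zraw)):
            raise VolumeFormatError(
                f"MetaImage header {path} has no companion .raw/.zraw file"
            )
    try:
        if ext in (".tif", ".tiff"):
            return _read_tiff(path)
        return _read_sitk(path)
    except VolumeFormatError:
        raise
    except Exception as exc:  # truncated/corrupt files
        raise VolumeFormatError(f"failed to read {path}: {exc}") from exc


def _read_tiff(path: str) -> Volume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    if data.ndim == 2:
        data = data[None]
    spacing = (1.0, 1.0, 1.0)
    origin = (0.0, 0.0, 0.0)
    try:
        meta = json.loads(desc).get(_DESCRIPTION_KEY, {})
        spacing = tuple(meta.get("spacing", spacing))
        origin = tuple(meta.get("origin", origin))
    except (json.JSONDecodeError, AttributeError):
        pass  # foreign TIFF without our metadata: unit spacing
    return Volume(data, spacing, origin)


def _read_sitk(path: str) -> Volume:
    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img)
    if data.ndim == 2:
        data = data[None]
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if len(spacing) != 3:
        spacing, origin = (1.0,) + tuple(spacing), (0.0,) + tuple(origin)
    return Volume(data, spacing, origin)


def mip_project(vol: Volume, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection: per-ray maximum along one axis."""
    if axis not in (0, 1, 2):
        raise InvalidParameterError(f"axis must be 0, 1 or 2, got {axis}")
    return np.max(vol.data, axis=axis)
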