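"""Readers and writers for label volumes and cue maps.

Supported formats (chosen by file suffix):

* HDF5 (``.h5``, ``.hdf5``, ``.hdf``) — labels in an integer dataset
  (default name ``"labels"``), cues in a float32 dataset (default
  ``"probabilities"``) stored channels-last.
* TIFF (``.tif``, ``.tiff``) — 3D volumes page-ordered z; multi-channel
  cues channels-last.
* PNG (``.png``) — 2D labels only, ids up to 65535 (uint16).

Arrays are indexed (z, )y, x with 0-based coordinates.  Labels round-trip
exactly; cues round-trip at float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InputError

__all__ = [
    "read_labels",
    "write_labels",
    "read_cues",
    "write_cues",
    "write_json",
]

_HDF5 = {".h5", ".hdf5", ".hdf"}
_TIFF = {".tif", ".tiff"}


def _suffix(path) -> str:
    return Path(path).suffix.lower()


def read_labels(path, dataset: str = "labels") -> np.ndarray:
    suffix = _suffix(path)
    if suffix in _HDF5:
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise InputError(f"dataset {dataset!r} not found in {path}")
            arr = fh[dataset][()]
    elif suffix in _TIFF:
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        raise InputError(f"unsupported label format {suffix!r} ({path})")
    if not np.issubdtype(arr.dtype, np.integer):
        raise InputError(f"label volume in {path} is not integer-typed")
    return arr


def write_labels(path, labels: np.ndarray, dataset: str = "labels", attrs: dict | None = None) -> None:
    labels = np.asarray(labels)
    suffix = _suffix(path)
    if suffix in _HDF5:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(dataset, data=labels)
            for k, v in (attrs or {}).items():
                ds.attrs[k] = v
    elif suffix in _TIFF:
        tifffile.imwrite(path, labels)
    elif suffix == ".png":
        if labels.ndim != 2:
            raise InputError("PNG supports 2D labels only")
        if labels.max() > 65535 or labels.min() < 0:
            raise InputError("PNG labels must fit in uint16")
        iio.imwrite(path, labels.astype(np.uint16))
    else:
        raise InputError(f"unsupported label format {suffix!r} ({path})")


def read_cues(path, dataset: str = "probabilities") -> list[np.ndarray]:
    """Read cue channels (channels-last in the file); returns a list of maps.

    Files written by :func:`write_cues` carry an explicit channels-last
    marker (HDF5 attribute).  For foreign files the layout is inferred: a 2D
    array is one channel; a 3D array whose last axis has at most 8 entries
    is treated as 2D multi-channel, otherwise as a single 3D volume; a 4D
    array is 3D multi-channel.
    """
    suffix = _suffix(path)
    channels_last = None
    if suffix in _HDF5:
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise InputError(f"dataset {dataset!r} not found in {path}")
            arr = fh[dataset][()]
            channels_last = bool(fh[dataset].attrs.get("channels_last", False)) or None
    elif suffix in _TIFF:
        arr = tifffile.imread(path)
    else:
        raise InputError(f"unsupported cue format {suffix!r} ({path})")
    arr = np.asarray(arr, dtype=np.float64)
    if channels_last is None:
        if arr.ndim == 2:
            return [arr]
        if arr.ndim == 3 and arr.shape[-1] > 8:
            return [arr]
        if arr.ndim not in (3, 4):
            raise InputError(f"cannot interpret cue array of shape {arr.shape}")
    return [arr[..., c] for c in range(arr.shape[-1])]


def write_cues(path, cues, dataset: str = "probabilities", attrs: dict | None = None) -> None:
    cues = [np.asarray(c, dtype=np.float32) for c in cues]
    stacked = np.stack(cues, axis=-1)
    suffix = _suffix(path)
    if suffix in _HDF5:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(dataset, data=stacked)
            ds.attrs["channels_last"] = True
            for k, v in (attrs or {}).items():
                ds.attrs[k] = v
    elif suffix in _TIFF:
        tifffile.imwrite(path, stacked)
    else:
        raise InputError(f"unsupported cue format {suffix!r} ({path})")


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
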