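"""Frame-stream I/O: multi-page TIFF and HDF5 containers."""

from __future__ import annotations

import h5py
import numpy as np
import tifffile

__all__ = [
    "write_stream_tiff",
    "read_stream_tiff",
    "write_stream_hdf5",
    "read_stream_hdf5",
]


def write_stream_tiff(path, stream: np.ndarray) -> None:
    """One TIFF page per frame, in acquisition order."""
    tifffile.imwrite(path, np.asarray(stream, dtype=np.float32))


def read_stream_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_stream_hdf5(path, stream: np.ndarray, n_planes: int, frame_rate: float) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("stream", data=np.asarray(stream, dtype=np.float32))
        d.attrs["n_planes"] = n_planes
        d.attrs["frame_rate"] = frame_rate


def read_stream_hdf5(path) -> tuple[np.ndarray, int, float]:
    with h5py.File(path, "r") as f:
        d = f["stream"]
        return d[...].astype(float), int(d.attrs["n_planes"]), float(d.attrs["frame_rate"])
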