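"""Shared containers and kernels used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["TraceMatrix", "exp_kernel"]


def exp_kernel(tau: float, rate: float, normalization: str = "sum", tol: float = 1e-8) -> np.ndarray:
    """Causal exponentially decaying kernel ``h[k] = exp(-k / (tau * rate))``.

    Parameters
    ----------
    tau : float
        Decay time constant in seconds. Must be positive.
    rate : float
        Sampling rate in Hz. Must be positive.
    normalization : {"sum", "peak"}
        ``"sum"`` rescales the kernel to unit area (so convolution preserves
        the area of the input waveform); ``"peak"`` leaves the peak at 1.
    tol : float
        The kernel is truncated once it decays below ``tol`` of its peak.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    n = int(np.ceil(-np.log(tol) * tau * rate)) + 1
    h = np.exp(-np.arange(n) / (tau * rate))
    if normalization == "sum":
        h = h / h.sum()
    elif normalization != "peak":
        raise ValueError(f"unknown normalization {normalization!r}")
    return h


@dataclass
class TraceMatrix:
    """Fluorescence time series, one row per ROI (or pixel).

    Attributes
    ----------
    data : ndarray, shape (n_traces, n_samples)
    rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    ids : ndarray or None
        Optional per-trace identifiers (defaults to the row index).
    """

    data: np.ndarray
    rate: float
    t0: float = 0.0
    ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trace data must be 2-D (n_traces, n_samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.ids is None:
            self.ids = np.arange(self.data.shape[0])
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.data.shape[0]:
                raise ValueError("ids length must match the number of traces")

    @property
    def n_traces(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=self.data)
            d.attrs["rate"] = self.rate
            d.attrs["t0"] = self.t0
            f.create_dataset("ids", data=np.asarray(self.ids))

    @classmethod
    def from_hdf5(cls, path) -> "TraceMatrix":
        with h5py.File(path, "r") as f:
            d = f["traces"]
            return cls(
                data=d[...],
                rate=float(d.attrs["rate"]),
                t0=float(d.attrs.get("t0", 0.0)),
                ids=f["ids"][...] if "ids" in f else None,
            )
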