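"""Frame-stream preprocessing: de-interleaving, rigid motion correction,
temporal smoothing and noise-floor estimation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

__all__ = [
    "PlaneSeries",
    "deinterleave",
    "reinterleave",
    "motion_correct",
    "running_average",
    "noise_floor",
]

log = logging.getLogger(__name__)


@dataclass
class PlaneSeries:
    """Time series of frames belonging to one plane of the scanned volume.

    ``applied_shifts`` records the rigid ``(dy, dx)`` px correction applied
    to each frame (zeros before motion correction).
    """

    plane_index: int
    frames: np.ndarray  # (t, y, x)
    timestamps: np.ndarray  # s, strictly increasing
    applied_shifts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (t, y, x)")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape[0] != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if (np.diff(self.timestamps) <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if self.applied_shifts is None:
            self.applied_shifts = np.zeros((self.frames.shape[0], 2))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.timestamps))) if self.n_frames > 1 else np.nan

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("frames", data=self.frames)
            d.attrs["plane_index"] = self.plane_index
            f.create_dataset("timestamps", data=self.timestamps)
            f.create_dataset("applied_shifts", data=self.applied_shifts)

    @classmethod
    def from_hdf5(cls, path) -> "PlaneSeries":
        with h5py.File(path, "r") as f:
            return cls(
                plane_index=int(f["frames"].attrs["plane_index"]),
                frames=f["frames"][...],
                timestamps=f["timestamps"][...],
                applied_shifts=f["applied_shifts"][...],
            )


def deinterleave(
    stream: np.ndarray,
    n_planes: int,
    frame_rate: float = 30.0,
    discard_initial: float = 0.0,
) -> list[PlaneSeries]:
    """Split an interleaved stream into one series per plane.

    Frame ``k`` of the stream belongs to plane ``k mod n_planes``. The first
    ``discard_initial`` seconds are dropped (rounded up to whole volumes so
    plane phase is preserved — early acquisition drifts with lens warm-up),
    as is any incomplete trailing volume.
    """
    if n_planes <= 0:
        raise ValueError("n_planes must be positive")
    stream = np.asarray(stream)
    if stream.shape[0] < n_planes:
        raise ValueError(f"stream of {stream.shape[0]} frames is shorter than one volume")
    skip_volumes = int(np.ceil(discard_initial * frame_rate / n_planes)) if discard_initial else 0
    first = skip_volumes * n_planes
    n_volumes = (stream.shape[0] - first) // n_planes
    if n_volumes < 1:
        raise ValueError("nothing left after discarding the initial interval")
    dropped = stream.shape[0] - first - n_volumes * n_planes
    if dropped:
        log.info("dropping %d trailing frames (incomplete volume)", dropped)

    out = []
    for p in range(n_planes):
        idx = first + p + n_planes * np.arange(n_volumes)
        out.append(
            PlaneSeries(
                plane_index=p,
                frames=stream[idx],
                timestamps=idx / frame_rate,
            )
        )
    return out


def reinterleave(series: list[PlaneSeries]) -> np.ndarray:
    """Inverse of :func:`deinterleave` over the retained volumes."""
    n_planes = len(series)
    n_volumes = series[0].n_frames
    shape = series[0].frames.shape[1:]
    out = np.empty((n_planes * n_volumes, *shape), dtype=series[0].frames.dtype)
    for p, s in enumerate(series):
        out[p::n_planes] = s.frames
    return out


def motion_correct(
    series: PlaneSeries,
    reference: str = "mean",
    upsample_factor: int = 10,
) -> PlaneSeries:
    """Rigid in-plane registration by phase cross-correlation.

    Each frame's ``(dy, dx)`` shift against the reference image (temporal
    mean by default, or the first frame) is estimated at subpixel precision
    (``upsample_factor`` 10 gives 0.1 px) and applied via Fourier shift.
    Returns a new PlaneSeries with the applied shifts recorded.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames to motion correct")
    if not np.isfinite(series.frames).all() or np.ptp(series.frames) == 0:
        raise ValueError("frames are empty or degenerate; cannot register")
    if reference == "mean":
        ref = series.frames.mean(axis=0)
    elif reference == "first":
        ref = series.frames[0]
    else:
        raise ValueError(f"unknown reference {reference!r}")

    corrected = np.empty_like(series.frames)
    shifts = np.empty((series.n_frames, 2))
    for k in range(series.n_frames):
        shift, _err, _phase = phase_cross_correlation(
            ref, series.frames[k], upsample_factor=upsample_factor, normalization=None
        )
        shifts[k] = shift
        corrected[k] = np.fft.ifftn(fourier_shift(np.fft.fftn(series.frames[k]), shift)).real
    return PlaneSeries(
        plane_index=series.plane_index,
        frames=corrected,
        timestamps=series.timestamps.copy(),
        applied_shifts=shifts,
    )


def running_average(data, window: int = 3, axis: int = -1):
    """Centered moving mean with shrunken windows at the edges.

    ``window`` must be odd so the filter is centered (default 3 frames).
    Accepts a plain array (smoothed along ``axis``) or a PlaneSeries
    (smoothed along time). ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if isinstance(data, PlaneSeries):
        return PlaneSeries(
            plane_index=data.plane_index,
            frames=running_average(data.frames, window=window, axis=0),
            timestamps=data.timestamps.copy(),
            applied_shifts=data.applied_shifts.copy(),
        )
    x = np.asarray(data, dtype=float)
    if window == 1:
        return x.copy()
    n = x.shape[axis]
    kernel = np.ones(window)
    counts = np.convolve(np.ones(n), kernel, mode="same")

    def smooth_1d(v):
        return np.convolve(v, kernel, mode="same") / counts

    return np.apply_along_axis(smooth_1d, axis, x)


def noise_floor(trace: np.ndarray, segments: list[tuple[int, int]]) -> float:
    """Noise estimate: mean over pre-stimulus segments of the per-segment SD.

    ``segments`` are ``(start, stop)`` sample-index intervals (stop
    exclusive), each at least 2 samples long; the canonical protocol uses 16
    pre-stimulus segments.
    """
    trace = np.asarray(trace, dtype=float)
    if not segments:
        raise ValueError("need at least one segment")
    sds = []
    for start, stop in segments:
        if stop - start < 2:
            raise ValueError(f"segment ({start}, {stop}) has fewer than 2 samples")
        if start < 0 or stop > trace.shape[0]:
            raise ValueError(f"segment ({start}, {stop}) outside the trace")
        sds.append(trace[start:stop].std(ddof=1))
    return float(np.mean(sds))
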