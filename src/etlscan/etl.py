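"""Remote-focus calibration and scheduling for an electrically tunable lens.

The focus position at the sample is controlled by the ETL drive current. A
calibration maps measured ``(current, focal shift)`` pairs to a degree-5
polynomial of the current against the normalized depth ``z*`` in [0, 1]; a
sawtooth schedule then sweeps ``z*`` linearly across a fixed number of frames
per volume, so that every frame is a shallow inclined plane: rows scanned
later in a frame sit deeper in the sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "LUTCalibration",
    "SawtoothSchedule",
    "fit_lut",
    "current_at",
    "generate_sawtooth",
    "row_z",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical extent and sampling grid of the scanned volume.

    Defaults correspond to the whole-brain configuration: 800 x 400 x 180 um
    sampled as 30 planes of 1024 x 512 px at 30 frames/s (1 volume/s).
    """

    fov_x: float = 800.0
    fov_y: float = 400.0
    z_range: float = 180.0
    n_x: int = 1024
    n_y: int = 512
    n_planes: int = 30
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if min(self.fov_x, self.fov_y, self.z_range) <= 0:
            raise ValueError("volume extent must be positive")
        if min(self.n_x, self.n_y, self.n_planes) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def volume_rate(self) -> float:
        """Volumes per second (frame rate divided by plane count)."""
        return self.frame_rate / self.n_planes

    @property
    def pixel_pitch_x(self) -> float:
        return self.fov_x / self.n_x

    @property
    def pixel_pitch_y(self) -> float:
        return self.fov_y / self.n_y


@dataclass
class LUTCalibration:
    """Fitted mapping from normalized depth ``z*`` to ETL drive current.

    ``coefficients`` are the polynomial coefficients ``p0..p_degree`` in
    increasing order, i.e. ``I(z*) = p0 + p1 z* + ... + p_d z*^d``.
    """

    points: np.ndarray  # (n, 2) columns (I mA, z um)
    z_min: float
    z_max: float
    i_min: float
    i_max: float
    coefficients: np.ndarray
    residual_rms: float
    degree: int = 5

    def z_star(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z, dtype=float) - self.z_min) / (self.z_max - self.z_min)

    def current_at(self, z_star) -> np.ndarray | float:
        return current_at(self, z_star)

    def to_json(self, path) -> None:
        payload = {
            "points": np.asarray(self.points).tolist(),
            "z_min": self.z_min,
            "z_max": self.z_max,
            "i_min": self.i_min,
            "i_max": self.i_max,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "residual_rms": self.residual_rms,
            "degree": self.degree,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "LUTCalibration":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            points=np.asarray(payload["points"], dtype=float),
            z_min=payload["z_min"],
            z_max=payload["z_max"],
            i_min=payload["i_min"],
            i_max=payload["i_max"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            residual_rms=payload["residual_rms"],
            degree=payload.get("degree", 5),
        )


def fit_lut(points, degree: int = 5) -> LUTCalibration:
    """Least-squares polynomial fit of drive current against normalized depth.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        Measured ``(current mA, focal shift um)`` pairs. At least
        ``degree + 2`` points are required (one more than an exact fit, so the
        residual carries information).
    degree : int
        Polynomial degree (default 5).

    Returns
    -------
    LUTCalibration
        Fit result; ``residual_rms`` is the RMS residual of the current in mA.

    Raises
    ------
    ValueError
        If too few points are given, all depths coincide, or duplicated
        normalized depths make the design rank-deficient.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (current, z) pairs")
    if pts.shape[0] < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} calibration points for a degree-{degree} "
            f"fit, got {pts.shape[0]}"
        )
    current, z = pts[:, 0], pts[:, 1]
    z_min, z_max = float(z.min()), float(z.max())
    if z_max == z_min:
        raise ValueError("all z values are equal; cannot normalize depth")
    z_star = (z - z_min) / (z_max - z_min)

    uniq, counts = np.unique(np.round(z_star, 12), return_counts=True)
    if (counts > 1).any():
        dupes = uniq[counts > 1] * (z_max - z_min) + z_min
        raise ValueError(
            "duplicated depth values make the fit rank-deficient: "
            + ", ".join(f"{d:g} um" for d in dupes)
        )

    design = np.vander(z_star, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, current, rcond=None)
    residuals = current - design @ coeffs
    residual_rms = float(np.sqrt(np.mean(residuals**2)))

    order = np.argsort(z)
    i_min = float(current[order[0]])
    i_max = float(current[order[-1]])

    # Warn when the fitted curve is not monotone even though the input is.
    if _is_monotone(current[order]):
        grid = np.linspace(0.0, 1.0, 501)
        fitted = np.vander(grid, degree + 1, increasing=True) @ coeffs
        if not _is_monotone(fitted):
            warnings.warn(
                "fitted LUT polynomial is not monotone on [0, 1] although the "
                "calibration points are; check calibration quality",
                stacklevel=2,
            )

    return LUTCalibration(
        points=pts,
        z_min=z_min,
        z_max=z_max,
        i_min=i_min,
        i_max=i_max,
        coefficients=coeffs,
        residual_rms=residual_rms,
        degree=degree,
    )


def _is_monotone(values: np.ndarray) -> bool:
    d = np.diff(values)
    return bool((d >= 0).all() or (d <= 0).all())


def current_at(cal: LUTCalibration, z_star):
    """Evaluate the calibration polynomial at normalized depth ``z_star``.

    ``z_star`` must lie in [0, 1]; the calibration is never extrapolated.
    """
    zs = np.asarray(z_star, dtype=float)
    if (zs < 0).any() or (zs > 1).any():
        raise ValueError(f"z_star must lie in [0, 1], got {z_star}")
    out = np.vander(np.atleast_1d(zs), cal.degree + 1, increasing=True) @ cal.coefficients
    return float(out[0]) if zs.ndim == 0 else out


@dataclass
class SawtoothSchedule:
    """One cycle of the linear focal ramp sampled at the driver update cadence.

    ``samples`` has columns ``(t s, z_star, current mA)``. The ramp spans
    ``z* = 0`` at the start of the cycle to ``z* -> 1`` at its end, with an
    instantaneous reset between cycles. If ``settling`` is set, samples
    falling inside the first frame of the cycle are flagged as settling time
    (the physical lens needs several ms after the reset).
    """

    frames_per_cycle: int
    frame_rate: float
    update_interval: float
    samples: np.ndarray
    settling: np.ndarray | None = field(default=None)

    @property
    def cycle_duration(self) -> float:
        return self.frames_per_cycle / self.frame_rate

    @property
    def t(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def z_star(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def current(self) -> np.ndarray:
        return self.samples[:, 2]

    def to_csv(self, path) -> None:
        header = "t_s,z_star,current_mA"
        np.savetxt(path, self.samples, delimiter=",", header=header, comments="")


def generate_sawtooth(
    cal: LUTCalibration,
    frames_per_cycle: int = 30,
    frame_rate: float = 30.0,
    update_interval: float = 0.003,
    mark_settling: bool = False,
) -> SawtoothSchedule:
    """Build one cycle of the sawtooth drive schedule.

    ``z*(t) = t / cycle_duration`` sampled every ``update_interval`` seconds;
    the current at each sample comes from the calibration polynomial. The
    number of samples is ``floor(cycle_duration / update_interval)`` — the
    sample at exactly one cycle belongs to the next cycle (where z* resets
    to 0).
    """
    if frames_per_cycle < 1:
        raise ValueError("frames_per_cycle must be >= 1")
    cycle = frames_per_cycle / frame_rate
    if update_interval <= 0 or update_interval >= cycle:
        raise ValueError("update_interval must be positive and shorter than the cycle")
    n = int(np.floor(cycle / update_interval))
    t = np.arange(n) * update_interval
    z_star = t / cycle
    current = current_at(cal, z_star)
    samples = np.column_stack([t, z_star, current])
    settling = None
    if mark_settling:
        settling = t < 1.0 / frame_rate
    return SawtoothSchedule(
        frames_per_cycle=frames_per_cycle,
        frame_rate=frame_rate,
        update_interval=update_interval,
        samples=samples,
        settling=settling,
    )


def row_z(geometry: AcquisitionGeometry, frame_index: int, row_index) -> float | np.ndarray:
    """Depth (um) sampled at a given row of a given frame within one cycle.

    Because the focus ramps continuously during the frame, rows scanned later
    sit deeper: ``z = z_range * (frame + row / n_y) / n_planes``. With the
    whole-brain defaults the last row of a frame is ~6 um deeper than its
    first row.
    """
    if not 0 <= frame_index < geometry.n_planes:
        raise ValueError(
            f"frame_index {frame_index} out of range [0, {geometry.n_planes})"
        )
    rows = np.asarray(row_index)
    if (rows < 0).any() or (rows >= geometry.n_y).any():
        raise ValueError(f"row_index {row_index} out of range [0, {geometry.n_y})")
    z = geometry.z_range * (frame_index + rows / geometry.n_y) / geometry.n_planes
    return float(z) if np.ndim(row_index) == 0 else z
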