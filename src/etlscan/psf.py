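"""PSF and field-of-view metrology from fluorescent bead stacks.

Measurement chain: reslice the stack along the axis of interest, average-
project over the other two axes within a crop around the bead, take the
intensity profile, and report the full width at half maximum as
``FWHM = 2 sqrt(2 ln 2) * sigma`` where sigma is the standard deviation of
the background-subtracted profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Profile",
    "PSFMeasurement",
    "FWHM_FACTOR",
    "profile_from_stack",
    "measure_fwhm",
    "measure_fov",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass
class Profile:
    """1-D intensity profile in physical coordinates (um)."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "z"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same shape")


@dataclass
class PSFMeasurement:
    axis: str
    sigma: float  # um
    fwhm: float  # um
    profile: Profile
    bead_position: float = np.nan  # um along the measured axis
    etl_z_setting: float = np.nan  # um


def profile_from_stack(
    stack: np.ndarray,
    axis: str,
    bead_center: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    window: int | tuple[int, int, int] = 21,
) -> Profile:
    """Average-projected intensity profile through a bead.

    The stack (``(z, y, x)`` order) is cropped to ``window`` voxels around
    ``bead_center`` on every axis, then averaged over the two axes not
    selected, leaving the profile along ``axis`` with physical coordinates.

    ``window`` may be a single odd size or one odd size per axis; it must
    fit inside the stack, otherwise the bead is too close to the border and
    an error asks for more padding.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    windows = (window,) * 3 if np.isscalar(window) else tuple(window)
    slices = []
    for a in range(3):
        w = int(windows[a])
        if w < 1 or w % 2 == 0:
            raise ValueError("window sizes must be odd and >= 1")
        half = w // 2
        c = int(bead_center[a])
        if c - half < 0 or c + half >= stack.shape[a]:
            raise ValueError(
                f"bead at {bead_center} is too close to the stack border on axis {a} "
                f"for a {w}-voxel window; acquire with larger padding or shrink the window"
            )
        slices.append(slice(c - half, c + half + 1))
    crop = stack[tuple(slices)]

    ax = _AXES[axis]
    others = tuple(a for a in range(3) if a != ax)
    values = crop.mean(axis=others)
    idx = np.arange(slices[ax].start, slices[ax].stop)
    positions = (idx + 0.5) * voxel_size[ax]
    return Profile(positions=positions, values=values, axis=axis)


def _gauss(x, amp, mu, sigma, offset):
    return offset + amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def measure_fwhm(
    profile: Profile,
    method: str = "moment",
    tail_fraction: float = 0.2,
    clip_fraction: float = 0.02,
) -> PSFMeasurement:
    """Sigma and FWHM of a bead profile.

    Default estimator: subtract the background (median of the outer
    ``tail_fraction`` of samples on each side), zero values below
    ``clip_fraction`` of the peak (suppresses noise bias in the tails), and
    take sigma as the intensity-weighted standard deviation of position.
    ``method="fit"`` cross-checks with a least-squares Gaussian fit.

    FWHM is always the closed form ``2 sqrt(2 ln 2) * sigma``.
    """
    x, v = profile.positions, profile.values
    if v.size < 3:
        raise ValueError("profile too short")
    if np.ptp(v) == 0:
        raise ValueError("constant profile; no peak to measure")

    n_tail = max(1, int(round(tail_fraction * v.size / 2)))
    background = float(np.median(np.concatenate([v[:n_tail], v[-n_tail:]])))
    w = np.clip(v - background, 0.0, None)
    if w.max() > 0 and clip_fraction > 0:
        w = np.where(w >= clip_fraction * w.max(), w, 0.0)
    if w.sum() == 0:
        raise ValueError("profile has no mass above background")

    if method == "moment":
        mu = float((w * x).sum() / w.sum())
        sigma = float(np.sqrt((w * (x - mu) ** 2).sum() / w.sum()))
    elif method == "fit":
        mu0 = float((w * x).sum() / w.sum())
        s0 = float(np.sqrt((w * (x - mu0) ** 2).sum() / w.sum())) or (x[1] - x[0])
        popt, _ = curve_fit(
            _gauss, x, v, p0=[float(v.max() - background), mu0, s0, background], maxfev=10000
        )
        mu, sigma = float(popt[1]), float(abs(popt[2]))
    else:
        raise ValueError(f"unknown method {method!r}")
    if sigma <= 0:
        raise ValueError("degenerate profile: sigma is zero")
    return PSFMeasurement(
        axis=profile.axis,
        sigma=sigma,
        fwhm=FWHM_FACTOR * sigma,
        profile=profile,
        bead_position=mu,
    )


def measure_fov(shift_record, n_pixels: int) -> float:
    """Field-of-view extent (um) from stage-travel vs bead-pixel records.

    ``shift_record`` holds ``(stage_travel_um, bead_pixel_position)`` pairs
    for one axis: translating the stage moves the bead across the sensor, so
    the slope of travel against pixel position is the pixel pitch, and the
    FOV is that pitch extrapolated over the full ``n_pixels`` axis.
    """
    rec = np.asarray(shift_record, dtype=float)
    if rec.ndim != 2 or rec.shape[1] != 2 or rec.shape[0] < 2:
        raise ValueError("need at least two (travel, pixel) records")
    travel, pixel = rec[:, 0], rec[:, 1]
    if np.ptp(pixel) == 0:
        raise ValueError("bead did not move across the sensor; cannot infer pixel pitch")
    slope = np.polyfit(pixel, travel, 1)[0]  # um per pixel
    return float(abs(slope) * n_pixels)
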