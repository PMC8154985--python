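"""Ground-truth generators for every input the pipeline consumes.

Produces synthetic brains (non-overlapping nuclear positions), calcium
activity with reporter kinetics and planted stimulus-locked responses,
rendered interleaved frame streams matching the ramping acquisition
geometry, fluorescent-bead z-stacks for PSF metrology, and noisy
calibration point sets for the LUT fit. Everything is deterministic given
its seed and records the truth needed to score recovery downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TraceMatrix, exp_kernel
from .etl import AcquisitionGeometry
from .responses import StimulusProtocol

__all__ = [
    "GroundTruth",
    "ActivityModel",
    "OpticsProfile",
    "ResponseMotif",
    "DEFAULT_MOTIFS",
    "generate_brain",
    "generate_activity",
    "render_acquisition",
    "generate_bead_stack",
    "generate_lut_points",
    "default_lut_curve",
]


@dataclass(frozen=True)
class ResponseMotif:
    """Kinetic recipe for one stimulus-response motif.

    Each presentation a responding cell fires ``n_events`` events starting
    ``latency`` seconds after stimulus onset, ``event_spacing`` seconds
    apart, with amplitude ``amplitude * trial_decay**presentation_index``
    relative to the cell's own response amplitude.
    """

    name: str
    latency: float
    amplitude: float
    trial_decay: float
    n_events: int = 1
    event_spacing: float = 0.0


#: Four default motifs: transient response that adapts over trials, a
#: sustained response with events spread through the epoch, a delayed
#: slow-rising response, and a strongly habituating one.
DEFAULT_MOTIFS: dict[int, ResponseMotif] = {
    1: ResponseMotif("fast_adapting", latency=0.0, amplitude=0.9, trial_decay=1.0, n_events=3, event_spacing=1.0),
    2: ResponseMotif("sustained", latency=0.0, amplitude=0.6, trial_decay=1.0, n_events=4, event_spacing=2.0),
    3: ResponseMotif("slow_rising", latency=3.0, amplitude=0.5, trial_decay=1.0, n_events=3, event_spacing=1.5),
    4: ResponseMotif("habituating", latency=0.0, amplitude=0.9, trial_decay=0.75, n_events=4, event_spacing=2.0),
}


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic brain — the recovery oracle.

    ``motif_labels`` is 0 for non-responsive cells and in ``1..K`` for
    responsive ones; ``response_amplitudes`` is NaN for non-responsive
    cells. ``spike_trains`` and ``stim_transients`` are filled in by
    :func:`generate_activity`; ``motion_shifts`` (per-frame ``(dy, dx)`` in
    px) by the caller or :func:`render_acquisition`.
    """

    cell_positions: np.ndarray  # (n, 3) columns (x, y, z) um
    responsive_flags: np.ndarray  # (n,) bool
    motif_labels: np.ndarray  # (n,) int, 0 where not responsive
    response_amplitudes: np.ndarray  # (n,) float, NaN where not responsive
    seed: int
    min_distance: float = 6.0
    spike_trains: list[np.ndarray] | None = field(default=None)
    stim_transients: list[np.ndarray] | None = field(default=None)
    motion_shifts: np.ndarray | None = field(default=None)

    @property
    def n_cells(self) -> int:
        return self.cell_positions.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "min_distance": self.min_distance,
            "cell_positions": self.cell_positions.tolist(),
            "responsive_flags": self.responsive_flags.astype(int).tolist(),
            "motif_labels": self.motif_labels.tolist(),
            "response_amplitudes": [
                None if np.isnan(a) else float(a) for a in self.response_amplitudes
            ],
            "spike_trains": None
            if self.spike_trains is None
            else [t.tolist() for t in self.spike_trains],
            "stim_transients": None
            if self.stim_transients is None
            else [t.tolist() for t in self.stim_transients],
            "motion_shifts": None if self.motion_shifts is None else self.motion_shifts.tolist(),
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            p = json.load(f)
        return cls(
            cell_positions=np.asarray(p["cell_positions"], dtype=float),
            responsive_flags=np.asarray(p["responsive_flags"], dtype=bool),
            motif_labels=np.asarray(p["motif_labels"], dtype=int),
            response_amplitudes=np.asarray(
                [np.nan if a is None else a for a in p["response_amplitudes"]], dtype=float
            ),
            seed=p["seed"],
            min_distance=p["min_distance"],
            spike_trains=None
            if p["spike_trains"] is None
            else [np.asarray(t) for t in p["spike_trains"]],
            stim_transients=None
            if p["stim_transients"] is None
            else [np.asarray(t) for t in p["stim_transients"]],
            motion_shifts=None
            if p["motion_shifts"] is None
            else np.asarray(p["motion_shifts"], dtype=float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_um": self.cell_positions[:, 0],
                "y_um": self.cell_positions[:, 1],
                "z_um": self.cell_positions[:, 2],
                "responsive": self.responsive_flags.astype(int),
                "motif": self.motif_labels,
                "amplitude": self.response_amplitudes,
            }
        ).to_csv(path, index_label="cell_id")


@dataclass
class ActivityModel:
    """Forward model of nuclear reporter fluorescence.

    ``F(t) = F0 + gain * (spike train (*) exp(-t / tau))`` plus shot noise.
    The decay constant defaults to 3.5 s (nuclear GCaMP6s range 3.5-4.1 s).
    """

    tau_decay: float = 3.5
    baseline_rate: float = 0.01
    stim_response_prob: float = 1.0
    photon_gain: float = 100.0
    baseline_f0: float = 100.0
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")
        if not 0 <= self.stim_response_prob <= 1:
            raise ValueError("stim_response_prob must lie in [0, 1]")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class OpticsProfile:
    """Gaussian PSF used when rendering cells into frames.

    ``z_broadening`` linearly scales both sigmas with depth:
    ``sigma(z) = sigma * (1 + z_broadening * z / z_ref)``.
    """

    sigma_xy: float = 0.5  # um
    sigma_z: float = 3.0  # um
    z_broadening: float = 0.0
    z_ref: float = 180.0

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("optics sigmas must be positive")

    def sigma_z_at(self, z: float) -> float:
        return self.sigma_z * (1.0 + self.z_broadening * z / self.z_ref)

    def sigma_xy_at(self, z: float) -> float:
        return self.sigma_xy * (1.0 + self.z_broadening * z / self.z_ref)


def generate_brain(
    geometry: AcquisitionGeometry,
    n_cells: int,
    seed: int,
    min_distance: float = 6.0,
    responsive_fraction: float = 0.05,
    n_motifs: int = 4,
    amplitude_range: tuple[float, float] = (0.8, 1.5),
    margin: float = 3.0,
    max_attempts_per_cell: int = 500,
) -> GroundTruth:
    """Place ``n_cells`` non-overlapping nuclei in the volume.

    Positions are drawn by rejection sampling under a minimum pairwise
    distance (default 6 um, one cell diameter) using a uniform grid for
    neighbour lookups, keeping ``margin`` um clear of the lateral borders.
    A ``responsive_fraction`` of cells is flagged responsive and assigned a
    motif label in ``1..n_motifs`` and a response amplitude.

    Raises ``RuntimeError`` (reporting the achievable count) if the volume
    cannot hold the requested density.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    lo = np.array([margin, margin, 0.0])
    hi = np.array([geometry.fov_x - margin, geometry.fov_y - margin, geometry.z_range])
    if (hi <= lo).any():
        raise ValueError("volume extent too small for the requested margin")

    cell = max(min_distance, 1e-6)
    grid_shape = np.maximum(((hi - lo) / cell).astype(int), 1)
    grid: dict[tuple[int, int, int], list[int]] = {}
    positions = np.empty((n_cells, 3))
    placed = 0
    attempts_left = max_attempts_per_cell * max(n_cells, 1)
    min_sq = min_distance**2

    while placed < n_cells:
        if attempts_left <= 0:
            raise RuntimeError(
                f"could not place {n_cells} cells at min distance {min_distance} um; "
                f"achieved {placed}"
            )
        attempts_left -= 1
        p = lo + rng.random(3) * (hi - lo)
        key = tuple(np.minimum(((p - lo) / cell).astype(int), grid_shape - 1))
        ok = True
        for dk in np.ndindex(3, 3, 3):
            nb = (key[0] + dk[0] - 1, key[1] + dk[1] - 1, key[2] + dk[2] - 1)
            for j in grid.get(nb, ()):
                d = positions[j] - p
                if d @ d < min_sq:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            positions[placed] = p
            grid.setdefault(key, []).append(placed)
            placed += 1

    responsive = np.zeros(n_cells, dtype=bool)
    n_resp = int(round(responsive_fraction * n_cells))
    if n_resp:
        responsive[rng.choice(n_cells, size=n_resp, replace=False)] = True
    motifs = np.zeros(n_cells, dtype=int)
    motifs[responsive] = rng.integers(1, n_motifs + 1, size=n_resp)
    amplitudes = np.full(n_cells, np.nan)
    amplitudes[responsive] = rng.uniform(*amplitude_range, size=n_resp)

    return GroundTruth(
        cell_positions=positions,
        responsive_flags=responsive,
        motif_labels=motifs,
        response_amplitudes=amplitudes,
        seed=seed,
        min_distance=min_distance,
    )


def generate_activity(
    truth: GroundTruth,
    protocol: StimulusProtocol,
    model: ActivityModel,
    duration: float,
    rate: float,
    seed: int,
    motifs: dict[int, ResponseMotif] | None = None,
) -> TraceMatrix:
    """Simulate per-cell fluorescence traces.

    Each cell carries spontaneous Poisson events at ``model.baseline_rate``;
    responsive cells additionally respond to each presentation with
    probability ``model.stim_response_prob``, placing events according to
    their motif. Event trains are convolved with a unit-peak exponential
    kernel (decay ``model.tau_decay``), scaled by ``model.photon_gain``, and
    offset by ``model.baseline_f0`` before noise is applied.

    Side effect: fills ``truth.spike_trains`` (all event times per cell) and
    ``truth.stim_transients`` (onsets of presentations the cell responded
    to), which the recovery tests use as oracle.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if protocol.presentations and duration < protocol.duration:
        raise ValueError(
            f"duration {duration} s does not cover the protocol (ends {protocol.duration} s)"
        )
    motifs = DEFAULT_MOTIFS if motifs is None else motifs
    rng = np.random.default_rng(seed)
    n_t = int(round(duration * rate))
    kernel = exp_kernel(model.tau_decay, rate, normalization="peak")

    data = np.empty((truth.n_cells, n_t))
    spike_trains: list[np.ndarray] = []
    stim_transients: list[np.ndarray] = []

    for i in range(truth.n_cells):
        ev_t: list[float] = []
        ev_a: list[float] = []
        n_spont = rng.poisson(model.baseline_rate * duration)
        for t in np.sort(rng.random(n_spont) * duration):
            ev_t.append(float(t))
            ev_a.append(1.0)
        responded: list[float] = []
        if truth.responsive_flags[i]:
            m = motifs[int(truth.motif_labels[i])]
            amp = float(truth.response_amplitudes[i])
            for k, (onset, _offset) in enumerate(protocol.presentations):
                if rng.random() < model.stim_response_prob:
                    responded.append(onset)
                    a = amp * m.amplitude * m.trial_decay**k
                    for j in range(m.n_events):
                        t = onset + m.latency + j * m.event_spacing
                        if t < duration:
                            ev_t.append(t)
                            ev_a.append(a)
        spike_trains.append(np.asarray(sorted(ev_t)))
        stim_transients.append(np.asarray(responded))

        train = np.zeros(n_t)
        for t, a in zip(ev_t, ev_a):
            idx = int(round(t * rate))
            if 0 <= idx < n_t:
                train[idx] += a
        f = model.baseline_f0 + model.photon_gain * np.convolve(train, kernel)[:n_t]
        data[i] = f

    if model.noise_model == "poisson":
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    elif model.noise_model == "gaussian":
        data = data + rng.normal(0.0, model.noise_sigma, size=data.shape)

    truth.spike_trains = spike_trains
    truth.stim_transients = stim_transients
    return TraceMatrix(data=data, rate=rate)


def _add_spot(img: np.ndarray, cy: float, cx: float, amp: float, sy: float, sx: float) -> None:
    """Accumulate a unit-peak 2-D Gaussian times ``amp`` into ``img`` in place."""
    ny, nx = img.shape
    ry, rx = int(np.ceil(4 * sy)), int(np.ceil(4 * sx))
    y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 1)
    x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1) - cy
    xx = np.arange(x0, x1) - cx
    gy = np.exp(-(yy**2) / (2 * sy**2))
    gx = np.exp(-(xx**2) / (2 * sx**2))
    img[y0:y1, x0:x1] += amp * np.outer(gy, gx)


def render_acquisition(
    truth: GroundTruth,
    geometry: AcquisitionGeometry,
    traces: TraceMatrix,
    optics: OpticsProfile,
    seed: int,
    background: float = 10.0,
    noise: str = "poisson",
    z_weight_cutoff: float = 1e-3,
) -> np.ndarray:
    """Render the interleaved frame stream of the ramping acquisition.

    Returns an array of shape ``(n_frames, n_y, n_x)``; frames are
    plane-major within each volume cycle (frame ``v * n_planes + p`` is
    plane ``p`` of volume ``v``). Rows of a frame sample the tilted depth of
    :func:`etlscan.etl.row_z`; each cell contributes a lateral Gaussian spot
    whose peak is its trace value weighted by a Gaussian of the optics'
    axial sigma at the cell's distance from the sampled focus. Planted
    ``truth.motion_shifts`` (per-frame ``(dy, dx)`` px) displace the cells;
    Poisson noise is applied on top of ``background``.
    """
    if traces.rate < geometry.volume_rate - 1e-9:
        raise ValueError("traces must be sampled at or above the volume rate")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    n_volumes = int(np.floor(traces.n_samples * geometry.volume_rate / traces.rate))
    if n_volumes < 1:
        raise ValueError("traces too short for a single volume")
    n_frames = n_volumes * geometry.n_planes

    shifts = truth.motion_shifts
    if shifts is None:
        shifts = np.zeros((n_frames, 2))
    elif shifts.shape[0] < n_frames:
        raise ValueError("motion_shifts shorter than the rendered stream")

    ppx, ppy = geometry.pixel_pitch_x, geometry.pixel_pitch_y
    pos = truth.cell_positions
    frames = np.full((n_frames, geometry.n_y, geometry.n_x), float(background))
    dz_frame = geometry.z_range / geometry.n_planes

    for v in range(n_volumes):
        t_idx = min(int(round(v / geometry.volume_rate * traces.rate)), traces.n_samples - 1)
        values = traces.data[:, t_idx]
        for p in range(geometry.n_planes):
            f = v * geometry.n_planes + p
            dy, dx = shifts[f]
            img = frames[f]
            for i in range(truth.n_cells):
                x, y, z = pos[i]
                cy = y / ppy + dy
                cx = x / ppx + dx
                # depth sampled at the cell's (shifted) row within this frame
                row_frac = np.clip(cy, 0, geometry.n_y - 1) / geometry.n_y
                z_row = dz_frame * (p + row_frac)
                sz = optics.sigma_z_at(z)
                w = np.exp(-((z - z_row) ** 2) / (2 * sz**2))
                if w < z_weight_cutoff:
                    continue
                sxy_px_y = optics.sigma_xy_at(z) / ppy
                sxy_px_x = optics.sigma_xy_at(z) / ppx
                _add_spot(img, cy, cx, values[i] * w, sxy_px_y, sxy_px_x)

    if noise == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if truth.motion_shifts is None:
        truth.motion_shifts = shifts
    return frames


def generate_bead_stack(
    sigma_xy: float,
    sigma_z: float,
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1),
    extent: tuple[float, float, float] = (30.0, 10.0, 10.0),
    n_beads: int = 1,
    seed: int = 0,
    amplitude: float = 1000.0,
    background: float = 0.0,
    noise_sigma: float = 0.0,
    margin_sigmas: float = 5.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize a z-stack of point-like fluorescent beads.

    Beads are separable 3-D Gaussians (sub-resolution beads are effectively
    point sources, so the imaged spot is the PSF itself) at uniformly random
    positions kept ``margin_sigmas`` * sigma away from the stack borders.

    Returns ``(stack, truth)`` where ``stack`` has shape (nz, ny, nx) and
    ``truth`` lists per-bead positions (um and voxel), sigmas and amplitude.
    """
    if sigma_xy <= 0 or sigma_z <= 0:
        raise ValueError("sigmas must be positive")
    vz, vy, vx = voxel_size
    ez, ey, ex = extent
    shape = (int(round(ez / vz)), int(round(ey / vy)), int(round(ex / vx)))
    rng = np.random.default_rng(seed)

    margins = np.array([margin_sigmas * sigma_z, margin_sigmas * sigma_xy, margin_sigmas * sigma_xy])
    lo = margins
    hi = np.array([ez, ey, ex]) - margins
    if (hi <= lo).any():
        raise ValueError("extent too small for the requested sigma margins")

    stack = np.full(shape, float(background))
    rows = []
    zc = (np.arange(shape[0]) + 0.5) * vz
    yc = (np.arange(shape[1]) + 0.5) * vy
    xc = (np.arange(shape[2]) + 0.5) * vx
    for b in range(n_beads):
        pz, py, px = lo + rng.random(3) * (hi - lo)
        gz = np.exp(-((zc - pz) ** 2) / (2 * sigma_z**2))
        gy = np.exp(-((yc - py) ** 2) / (2 * sigma_xy**2))
        gx = np.exp(-((xc - px) ** 2) / (2 * sigma_xy**2))
        stack += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        rows.append(
            {
                "bead_id": b,
                "z_um": pz,
                "y_um": py,
                "x_um": px,
                "z_vox": pz / vz - 0.5,
                "y_vox": py / vy - 0.5,
                "x_vox": px / vx - 0.5,
                "sigma_xy_um": sigma_xy,
                "sigma_z_um": sigma_z,
                "amplitude": amplitude,
            }
        )
    if noise_sigma > 0:
        stack = stack + rng.normal(0.0, noise_sigma, size=stack.shape)
    return stack, pd.DataFrame(rows)


def default_lut_curve(z):
    """Smooth monotone nonlinear current-vs-depth curve (mA for z in um)."""
    z = np.asarray(z, dtype=float)
    return 30.0 + 0.6 * z + 8e-4 * z**2 - 1.2e-6 * z**3


def generate_lut_points(
    true_curve=default_lut_curve,
    z_range: tuple[float, float] = (0.0, 233.0),
    n_points: int = 8,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sample a calibration point set ``(I mA, z um)`` on a known curve.

    Depths are evenly spaced over ``z_range`` (default eight positions over
    0-233 um); Gaussian noise of SD ``noise_sigma`` mA is added to the
    currents. At least 7 points are required — a degree-5 fit needs 6 and a
    meaningful residual needs one more.
    """
    if n_points < 7:
        raise ValueError(f"need at least 7 calibration points, got {n_points}")
    rng = np.random.default_rng(seed)
    z = np.linspace(z_range[0], z_range[1], n_points)
    current = np.asarray(true_curve(z), dtype=float)
    if noise_sigma > 0:
        current = current + rng.normal(0.0, noise_sigma, size=n_points)
    return np.column_stack([current, z])
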