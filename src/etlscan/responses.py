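"""Stimulus regressors, trace scoring, responsive-cell selection and events.

The expected stimulus-evoked fluorescence is modelled by convolving binary
stimulus-epoch waveforms with a normalized exponentially decaying reporter
kernel. Each trace is fit by ordinary least squares against that design; the
regression coefficient divided by the mean squared error of the fit ranks how
strongly and cleanly the trace follows the stimulus, and the top quantile of
that score distribution is flagged responsive. The same machinery applies to
ROI traces and to raw per-pixel traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from .core import TraceMatrix, exp_kernel

__all__ = [
    "StimulusProtocol",
    "RegressorBasis",
    "ScoreTable",
    "EventTable",
    "loom_angle",
    "build_regressors",
    "fit_traces",
    "select_responsive",
    "zscore_events",
]


def loom_angle(diameter: float, screen_distance: float) -> float:
    """Full visual angle (degrees) of a dot of given diameter on a screen.

    ``theta = 2 * atan((diameter / 2) / distance)``. Units of diameter and
    distance must match (mm here by convention).
    """
    if screen_distance <= 0:
        raise ValueError("screen distance must be positive")
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return math.degrees(2.0 * math.atan((diameter / 2.0) / screen_distance))


@dataclass
class StimulusProtocol:
    """Timing and geometry of a looming-dot presentation protocol.

    ``presentations`` is a sorted list of non-overlapping ``(onset, offset)``
    intervals in seconds. The dot geometry fields describe the expanding disk:
    it grows from zero diameter to ``final_diameter_mm`` over each
    presentation, on a screen ``screen_distance_mm`` from the subject.
    """

    presentations: list[tuple[float, float]]
    screen_distance_mm: float = 30.0
    final_diameter_mm: float = 50.0
    size_to_speed_s: float | None = None

    def __post_init__(self) -> None:
        pres = [(float(a), float(b)) for a, b in self.presentations]
        for onset, offset in pres:
            if offset <= onset:
                raise ValueError(f"presentation ({onset}, {offset}) has non-positive duration")
        pres.sort()
        for (_, off_a), (on_b, _) in zip(pres, pres[1:]):
            if on_b < off_a:
                raise ValueError("presentations overlap")
        self.presentations = pres

    @property
    def final_angle_deg(self) -> float:
        return loom_angle(self.final_diameter_mm, self.screen_distance_mm)

    def mean_expansion_rate(self) -> float:
        """Mean angular expansion rate (deg/s): final angle over duration."""
        if not self.presentations:
            raise ValueError("protocol has no presentations")
        onset, offset = self.presentations[0]
        return self.final_angle_deg / (offset - onset)

    def angle_at(self, t_in_presentation: float) -> float:
        """Visual angle (degrees) at a time offset into a presentation,
        assuming the diameter grows linearly from 0 to the final diameter."""
        onset, offset = self.presentations[0]
        frac = np.clip(t_in_presentation / (offset - onset), 0.0, 1.0)
        return loom_angle(frac * self.final_diameter_mm, self.screen_distance_mm)

    @property
    def duration(self) -> float:
        """End time of the last presentation (s)."""
        return self.presentations[-1][1] if self.presentations else 0.0

    @classmethod
    def looming(
        cls,
        n_presentations: int = 10,
        interval: float = 150.0,
        stim_duration: float = 17.0,
        first_onset: float = 30.0,
        screen_distance_mm: float = 30.0,
        final_diameter_mm: float = 50.0,
        size_to_speed_s: float | None = 8.3,
    ) -> "StimulusProtocol":
        """Regularly repeated looming presentations (default: 10 every 150 s)."""
        pres = [
            (first_onset + k * interval, first_onset + k * interval + stim_duration)
            for k in range(n_presentations)
        ]
        return cls(pres, screen_distance_mm, final_diameter_mm, size_to_speed_s)

    def to_yaml(self, path) -> None:
        payload = {
            "presentations": [[a, b] for a, b in self.presentations],
            "screen_distance_mm": self.screen_distance_mm,
            "final_diameter_mm": self.final_diameter_mm,
            "size_to_speed_s": self.size_to_speed_s,
        }
        with open(path, "w") as f:
            yaml.safe_dump(payload, f)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as f:
            payload = yaml.safe_load(f)
        return cls(
            presentations=[tuple(p) for p in payload["presentations"]],
            screen_distance_mm=payload.get("screen_distance_mm", 30.0),
            final_diameter_mm=payload.get("final_diameter_mm", 50.0),
            size_to_speed_s=payload.get("size_to_speed_s"),
        )


@dataclass
class RegressorBasis:
    """Design matrix of reporter-convolved stimulus regressors.

    ``binary`` holds the pre-convolution epoch waveforms (regressors x time);
    for disjoint epochs these are mutually orthogonal. ``design`` is the
    time x (n_regressors + 1) matrix handed to the least-squares fit, with
    the intercept as the last column.
    """

    rate: float
    tau: float
    binary: np.ndarray
    design: np.ndarray
    names: list[str] = field(default_factory=list)
    mode: str = "pooled"

    @property
    def n_regressors(self) -> int:
        return self.binary.shape[0]

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    def to_csv(self, path) -> None:
        cols = self.names + ["intercept"]
        pd.DataFrame(self.design, columns=cols).to_csv(path, index=False)


def build_regressors(
    protocol: StimulusProtocol,
    rate: float,
    tau: float = 3.5,
    mode: str = "pooled",
    n_samples: int | None = None,
    t0: float = 0.0,
    kernel_normalization: str = "sum",
) -> RegressorBasis:
    """Build stimulus regressors with reporter kinetics.

    Binary waveforms are 1 during each stimulus epoch and 0 elsewhere,
    sampled at ``rate``; each is causally convolved with
    ``h[k] ~ exp(-k / (tau * rate))`` normalized to unit sum (so the
    convolved regressor keeps the area of its binary waveform).

    ``mode="pooled"`` merges all presentations into a single regressor;
    ``mode="per_presentation"`` keeps one regressor per presentation.
    An intercept column is always appended.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if mode not in ("pooled", "per_presentation"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_samples is None:
        pad = 5.0 * tau
        n_samples = int(np.ceil((protocol.duration - t0 + pad) * rate)) if protocol.presentations else int(rate)
    times = t0 + np.arange(n_samples) / rate
    for onset, offset in protocol.presentations:
        if onset < times[0] - 0.5 / rate or onset > times[-1] + 0.5 / rate:
            raise ValueError(
                f"presentation onset {onset} s lies outside the sampled "
                f"interval [{times[0]}, {times[-1]}] s"
            )

    if protocol.presentations:
        waves = np.zeros((len(protocol.presentations), n_samples))
        for i, (onset, offset) in enumerate(protocol.presentations):
            waves[i] = (times >= onset) & (times < offset)
        if mode == "pooled":
            binary = waves.sum(axis=0, keepdims=True)
            names = ["stimulus"]
        else:
            binary = waves
            names = [f"presentation_{i}" for i in range(len(protocol.presentations))]
    else:
        binary = np.zeros((0, n_samples))
        names = []

    h = exp_kernel(tau, rate, normalization=kernel_normalization)
    convolved = np.empty_like(binary)
    for i in range(binary.shape[0]):
        convolved[i] = np.convolve(binary[i], h)[:n_samples]

    design = np.column_stack([convolved.T, np.ones(n_samples)]) if binary.shape[0] else np.ones((n_samples, 1))
    return RegressorBasis(rate=rate, tau=tau, binary=binary, design=design, names=names, mode=mode)


@dataclass
class ScoreTable:
    """Per-trace regression results.

    ``table`` columns: one ``beta_*`` per regressor, ``intercept``, ``mse``
    (mean squared residual), ``score`` and a boolean ``responsive`` flag.
    The score is ``beta / mse`` for a pooled single-regressor design and
    ``max_j beta_j / mse`` otherwise; a perfect fit (``mse == 0``) scores
    ``+inf`` and is always selected.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    @property
    def responsive_ids(self) -> np.ndarray:
        return self.table.index[self.table["responsive"]].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="trace_id")

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path, index_col="trace_id"))


def fit_traces(traces: TraceMatrix, basis: RegressorBasis) -> ScoreTable:
    """Ordinary least squares of every trace against the regressor design."""
    if traces.n_samples != basis.n_samples:
        raise ValueError(
            f"trace length {traces.n_samples} does not match design length {basis.n_samples}"
        )
    X = basis.design
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix; regressors are collinear")

    Y = traces.data.T  # (T, n_traces)
    coefs, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ coefs
    mse = np.mean(residuals**2, axis=0)

    n_reg = basis.n_regressors
    betas = coefs[:n_reg].T  # (n_traces, n_reg)
    intercept = coefs[-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        if n_reg == 0:
            score = np.zeros(traces.n_traces)
        elif n_reg == 1:
            score = betas[:, 0] / mse
        else:
            score = (betas / mse[:, None]).max(axis=1)
    score = np.where(mse == 0, np.inf, score)

    data = {f"beta_{name}": betas[:, j] for j, name in enumerate(basis.names)}
    data["intercept"] = intercept
    data["mse"] = mse
    data["score"] = score
    data["responsive"] = False
    table = pd.DataFrame(data, index=pd.Index(np.asarray(traces.ids), name="trace_id"))
    return ScoreTable(table)


def select_responsive(scores: ScoreTable, fraction: float = 0.05) -> ScoreTable:
    """Flag the top-``fraction`` scoring traces as responsive.

    Exactly ``ceil(fraction * N)`` traces are selected; ties at the cut are
    broken deterministically by trace position (earlier rows win). Returns a
    new ScoreTable restricted to the selected traces; the input table's
    ``responsive`` column is updated in place as well.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(scores)
    if n < 1:
        raise ValueError("need at least one score")
    n_sel = int(math.ceil(fraction * n))
    order = np.argsort(-scores.scores, kind="stable")
    selected = order[:n_sel]
    flags = np.zeros(n, dtype=bool)
    flags[selected] = True
    scores.table["responsive"] = flags
    return ScoreTable(scores.table.iloc[np.sort(selected)].copy())


@dataclass
class EventTable:
    """Suprathreshold fluorescence events per trace.

    ``indices`` / ``times`` / ``z_peaks`` are parallel lists (one entry per
    trace) of event sample indices, event times in seconds, and the z-scored
    peak amplitudes. Events are local maxima of the z-scored trace whose peak
    exceeds ``threshold`` baseline standard deviations.
    """

    indices: list[np.ndarray]
    times: list[np.ndarray]
    z_peaks: list[np.ndarray]
    threshold: float

    @property
    def n_events(self) -> int:
        return int(sum(len(ix) for ix in self.indices))


def zscore_events(
    traces: TraceMatrix,
    baseline_windows: list[tuple[int, int]],
    threshold: float = 5.0,
) -> EventTable:
    """Detect peaks exceeding ``threshold`` in baseline-z-scored traces.

    ``baseline_windows`` is a list of ``(start, stop)`` sample-index
    intervals (stop exclusive) pooled to estimate each trace's baseline mean
    and SD. A zero baseline SD is an error (the z-score is undefined).
    """
    if not baseline_windows:
        raise ValueError("need at least one baseline window")
    sel = np.concatenate([np.arange(a, b) for a, b in baseline_windows])
    if (sel < 0).any() or (sel >= traces.n_samples).any():
        raise ValueError("baseline windows fall outside the trace")
    base = traces.data[:, sel]
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = np.where(sd == 0)[0]
        raise ValueError(f"zero baseline SD for trace(s) {bad.tolist()}; z-score undefined")

    indices, times, z_peaks = [], [], []
    for i in range(traces.n_traces):
        z = (traces.data[i] - mu[i]) / sd[i]
        peaks, props = find_peaks(z, height=threshold)
        indices.append(peaks)
        times.append(traces.t0 + peaks / traces.rate)
        z_peaks.append(props["peak_heights"])
    return EventTable(indices=indices, times=times, z_peaks=z_peaks, threshold=threshold)
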