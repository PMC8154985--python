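"""Nuclear ROI detection on per-plane mean images and trace extraction.

Lightweight detector: local maxima of the Gaussian-smoothed temporal mean
image above a robust threshold, separated by at least one cell diameter;
each maximum claims a disk of one cell radius, with contested pixels going
to the nearest centroid. An import path for externally produced ROI tables
is provided so output of a full segmentation suite can be consumed instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .core import TraceMatrix
from .preprocess import PlaneSeries

__all__ = ["ROITable", "detect_rois", "extract_traces", "read_roi_csv"]

log = logging.getLogger(__name__)


@dataclass
class ROITable:
    """Detected ROIs on one plane.

    ``table`` columns: roi_id, plane, y, x (centroid px), area (px).
    ``pixel_sets[i]`` is the ``(rows, cols)`` index pair of ROI i's pixels;
    no two ROIs on the plane share a pixel.
    """

    table: pd.DataFrame
    pixel_sets: list[tuple[np.ndarray, np.ndarray]]
    plane_index: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_roi_csv(path, image_shape: tuple[int, int], radius_px: float) -> ROITable:
    """Load an externally produced ROI table (roi_id, plane, y, x columns)
    and rebuild disk pixel sets of the given radius."""
    df = pd.read_csv(path)
    centroids = df[["y", "x"]].to_numpy(dtype=float)
    pixel_sets = _disk_pixel_sets(centroids, image_shape, radius_px)
    df = df.assign(area=[len(r) for r, _ in pixel_sets])
    plane = int(df["plane"].iloc[0]) if len(df) else 0
    return ROITable(table=df, pixel_sets=pixel_sets, plane_index=plane)


def _disk_pixel_sets(
    centroids: np.ndarray, shape: tuple[int, int], radius: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disks around centroids; overlapping pixels go to the nearest centroid."""
    ny, nx = shape
    owner = np.full(shape, -1, dtype=int)
    best = np.full(shape, np.inf)
    r_int = int(np.ceil(radius))
    for i, (cy, cx) in enumerate(centroids):
        y0, y1 = max(0, int(cy) - r_int), min(ny, int(cy) + r_int + 1)
        x0, x1 = max(0, int(cx) - r_int), min(nx, int(cx) + r_int + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask = (d2 <= radius**2) & (d2 < best[y0:y1, x0:x1])
        owner[y0:y1, x0:x1][mask] = i
        best[y0:y1, x0:x1][mask] = d2[mask]
    return [tuple(np.nonzero(owner == i)) for i in range(len(centroids))]


def detect_rois(
    series: PlaneSeries | np.ndarray,
    cell_diameter: float = 6.0,
    pixel_pitch: float = 0.78125,
    threshold: float = 2.0,
    smooth_sigma_px: float | None = None,
) -> ROITable:
    """Detect nuclear ROIs on the temporal mean image of a plane.

    The mean image is Gaussian-smoothed (sigma = cell radius / 2 px by
    default), and local maxima exceeding ``median + threshold * SD`` with a
    minimum separation of one cell diameter become ROI centroids. Cells
    closer than the separation merge into a single ROI (logged). Zero
    detections is a valid outcome.
    """
    if cell_diameter <= 0 or pixel_pitch <= 0:
        raise ValueError("cell_diameter and pixel_pitch must be positive")
    if isinstance(series, PlaneSeries):
        mean_img = series.frames.mean(axis=0)
        plane = series.plane_index
    else:
        arr = np.asarray(series, dtype=float)
        mean_img = arr.mean(axis=0) if arr.ndim == 3 else arr
        plane = 0

    diameter_px = cell_diameter / pixel_pitch
    sigma = smooth_sigma_px if smooth_sigma_px is not None else diameter_px / 4.0
    smooth = gaussian_filter(mean_img, sigma)
    bg = float(np.median(smooth))
    sd = float(smooth.std())
    min_dist = max(1, int(round(diameter_px)))
    if sd == 0:
        coords = np.empty((0, 2))
    else:
        coords = peak_local_max(
            smooth,
            min_distance=min_dist,
            threshold_abs=bg + threshold * sd,
            exclude_border=False,
        ).astype(float)
    log.info("plane %d: %d ROI(s) detected (min separation %d px)", plane, len(coords), min_dist)

    pixel_sets = _disk_pixel_sets(coords, mean_img.shape, diameter_px / 2.0)
    table = pd.DataFrame(
        {
            "roi_id": np.arange(len(coords)),
            "plane": plane,
            "y": coords[:, 0] if len(coords) else np.array([]),
            "x": coords[:, 1] if len(coords) else np.array([]),
            "area": [len(r) for r, _ in pixel_sets],
        }
    )
    return ROITable(table=table, pixel_sets=pixel_sets, plane_index=plane)


def extract_traces(series: PlaneSeries, rois: ROITable) -> TraceMatrix:
    """Mean fluorescence over each ROI's pixel set, per frame."""
    if rois.plane_index != series.plane_index:
        raise ValueError(
            f"ROI table is for plane {rois.plane_index}, series is plane {series.plane_index}"
        )
    n_t = series.n_frames
    data = np.empty((len(rois), n_t))
    for i, (rows, cols) in enumerate(rois.pixel_sets):
        if rows.size == 0:
            raise ValueError(f"ROI {i} has an empty pixel set")
        data[i] = series.frames[:, rows, cols].mean(axis=1)
    rate = series.rate if n_t > 1 else 1.0
    return TraceMatrix(
        data=data,
        rate=rate,
        t0=float(series.timestamps[0]),
        ids=rois.table["roi_id"].to_numpy(),
    )
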