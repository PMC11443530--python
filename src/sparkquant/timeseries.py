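"""Per-cell dynamic readouts: intensity traces, formation latency,
washout dispersion, and heatmap normalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageStack, ROI


@dataclass
class CellTrace:
    """Per-cell, per-frame cluster count and fluorescence intensity."""

    cell_id: int
    time_s: np.ndarray
    count: np.ndarray
    intensity: np.ndarray
    stimulus_windows: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.count = np.asarray(self.count)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.time_s) == len(self.count) == len(self.intensity)):
            raise ValueError("time, count and intensity must have equal length")
        if (self.count < 0).any():
            raise ValueError("counts must be non-negative")


def gcamp_intensity_trace(
    movie: ImageStack, cell_mask: np.ndarray, background_roi: ROI
) -> np.ndarray:
    """Integrated (summed) background-subtracted intensity per frame.

    The per-frame background level is the mean inside the background
    ROI; the trace is the sum of (frame - background) over the cell
    mask. Integrated rather than mean intensity, so the trace scales
    with total reporter fluorescence (the Ca²⁺ readout in a dual
    reporter).
    """
    if movie.axes != "TYX":
        raise ValueError("gcamp_intensity_trace requires a TYX movie")
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != movie.frame_shape:
        raise ValueError("cell mask shape must match the movie frames")
    if not mask.any():
        raise ValueError("cell mask is empty")
    background_roi.check_bounds(movie.frame_shape)
    out = np.empty(movie.n_frames)
    for t, frame in enumerate(movie.iter_frames()):
        f = np.asarray(frame, dtype=float)
        bg = f[background_roi.mask].mean()
        out[t] = f[mask].sum() - bg * mask.sum()
    return out


NO_RESPONSE = float("nan")


def formation_latency(
    count: np.ndarray,
    onset_frame: int,
    frame_interval_s: float,
    k_min_clusters: int = 3,
    m_sustained_frames: int = 2,
) -> float:
    """Minutes from stimulus onset to a sustained condensate response.

    The response frame is the first frame at or after onset where the
    count is >= ``k_min_clusters`` for ``m_sustained_frames`` consecutive
    frames. Returns NaN (no response) when the criterion is never met —
    some cells genuinely do not respond.
    """
    c = np.asarray(count)
    if not (0 <= onset_frame < len(c)):
        raise ValueError("onset_frame outside the trace")
    if k_min_clusters < 1 or m_sustained_frames < 1:
        raise ValueError("k_min_clusters and m_sustained_frames must be >= 1")
    ok = c >= k_min_clusters
    for t in range(onset_frame, len(c) - m_sustained_frames + 1):
        if ok[t : t + m_sustained_frames].all():
            return (t - onset_frame) * frame_interval_s / 60.0
    return NO_RESPONSE


def dispersion_fraction(
    count: np.ndarray,
    peak_window: tuple[int, int],
    washout_window: tuple[int, int],
) -> float:
    """Percent of peak-window condensates lost by the washout window.

    100 x (max count in peak window - min count in washout window) /
    max count in peak window. Windows are half-open frame ranges
    ``[start, end)``; washout must follow the peak window. The washout
    minimum (not endpoint) makes the measure robust to re-nucleation
    blips. NaN when no condensates were present at peak.
    """
    c = np.asarray(count, dtype=float)
    p0, p1 = peak_window
    w0, w1 = washout_window
    if not (0 <= p0 < p1 <= len(c) and 0 <= w0 < w1 <= len(c)):
        raise ValueError("windows must be non-empty and inside the trace")
    if w0 < p1:
        raise ValueError("washout window must follow the peak window")
    peak = c[p0:p1].max()
    if peak <= 0:
        return float("nan")
    floor = c[w0:w1].min()
    return float(100.0 * (peak - floor) / peak)


def dispersion_summary(
    traces: list[CellTrace],
    peak_window: tuple[int, int],
    washout_window: tuple[int, int],
) -> dict:
    """Population mean ± SD of per-cell dispersion fractions."""
    vals = [
        dispersion_fraction(tr.count, peak_window, washout_window) for tr in traces
    ]
    arr = np.asarray(vals, dtype=float)
    defined = arr[~np.isnan(arr)]
    return {
        "per_cell_percent": vals,
        "n_defined": int(defined.size),
        "mean_percent": float(defined.mean()) if defined.size else float("nan"),
        "sd_percent": float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
    }


def normalize_for_heatmap(traces: list[CellTrace]) -> pd.DataFrame:
    """Normalize each cell's count and intensity to its own maximum.

    Returns a long-format table (cell, frame, time_s, count, intensity,
    count_norm, intensity_norm) with normalized values in [0, 1],
    suitable for heatmap rendering. An all-zero trace cannot be
    normalized and is passed through with a warning.
    """
    rows = []
    for tr in traces:
        cmax = tr.count.max() if len(tr.count) else 0
        imax = tr.intensity.max() if len(tr.intensity) else 0.0
        if cmax <= 0:
            warnings.warn(f"cell {tr.cell_id}: all-zero count trace left unnormalized")
        if imax <= 0:
            warnings.warn(
                f"cell {tr.cell_id}: non-positive intensity trace left unnormalized"
            )
        for t in range(len(tr.count)):
            rows.append(
                {
                    "cell": tr.cell_id,
                    "frame": t,
                    "time_s": float(tr.time_s[t]),
                    "count": int(tr.count[t]),
                    "intensity": float(tr.intensity[t]),
                    "count_norm": float(tr.count[t] / cmax) if cmax > 0 else float(tr.count[t]),
                    "intensity_norm": float(tr.intensity[t] / imax)
                    if imax > 0
                    else float(tr.intensity[t]),
                }
            )
    return pd.DataFrame(rows)
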