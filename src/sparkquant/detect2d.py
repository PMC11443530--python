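"""2D cluster detection: prominence-based maxima counting, Kapur
(maximum-entropy) thresholding, particle analysis, outlines, and the
dual-threshold single-channel counting procedure.

Maxima semantics
----------------
A maximum is a connected plateau of equal intensity with no higher
neighbour. Its *prominence* is the drop from the plateau value to the
highest level at which the plateau becomes connected (through pixels of
intensity >= that level) to a strictly brighter pixel; maxima never
connected to anything brighter (global maxima, possibly tied) take
``value - image minimum``. Plateaus count once and report their
centroid. Computed in one pass with a union-find over pixels sorted by
decreasing intensity (the persistence of superlevel-set components),
with lexicographic (row, column) tie-breaking for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .core import ImageStack

# 8-connectivity neighbourhood offsets, lexicographic order
_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class MaximaParams:
    """Parameters for maxima counting.

    prominence: minimum intensity drop separating a maximum from the
    ridge to any brighter maximum (must be > 0).
    abs_threshold: intensity floor; maxima below it are discarded.
    exclude_edges: drop maxima whose plateau touches the frame border.
    """

    prominence: float
    abs_threshold: float = 0.0
    exclude_edges: bool = False

    def __post_init__(self) -> None:
        if not self.prominence > 0:
            raise ValueError("prominence must be > 0")
        if self.abs_threshold < 0:
            raise ValueError("abs_threshold must be >= 0")


def _find_root(parent: dict, i: int) -> int:
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:  # path compression
        parent[i], i = root, parent[i]
    return root


def maxima_prominences(frame: np.ndarray) -> list[tuple[int, float, float]]:
    """All maxima of a 2D frame as ``(rep_index, value, prominence)``.

    ``rep_index`` is the flat index of the lexicographically first pixel
    of the maximum's plateau. Prominence 0 entries (shoulder plateaus)
    are included; callers filter.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("maxima detection requires a 2D frame")
    ny, nx = img.shape
    flat = img.ravel()
    n = flat.size
    rows, cols = np.unravel_index(np.arange(n), img.shape)
    # primary: descending value; then row, then column
    order = np.lexsort((cols, rows, -flat))

    parent: dict[int, int] = {}
    peak_val: dict[int, float] = {}  # root -> component peak value
    alive: dict[int, list[int]] = {}  # root -> alive maxima reps (peak level)
    prominences: dict[int, tuple[float, float]] = {}  # rep -> (value, prom)

    for idx in order:
        v = flat[idx]
        y, x = idx // nx, idx % nx
        roots = []
        for dy, dx in _NEIGHBOURS:
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx:
                j = yy * nx + xx
                if j in parent:
                    r = _find_root(parent, j)
                    if r not in roots:
                        roots.append(r)
        if not roots:
            parent[idx] = idx
            peak_val[idx] = v
            alive[idx] = [idx]
            continue
        # merge all neighbouring components plus this pixel
        vmax = max(peak_val[r] for r in roots)
        top = [r for r in roots if peak_val[r] == vmax]
        # winner: among equal-peak components, the one whose first alive
        # rep is lexicographically smallest (== earliest created)
        winner = min(top, key=lambda r: alive[r][0])
        for r in roots:
            if r is winner:
                continue
            if peak_val[r] < vmax:
                # component dies at the current level: record prominence
                for rep in alive[r]:
                    prominences[rep] = (peak_val[r], peak_val[r] - v)
            elif peak_val[r] == v:
                # merging at the peak level itself: same plateau — the
                # later-created reps were never separate maxima
                pass
            else:
                # distinct equal-height peaks joined below their level
                alive[winner].extend(alive[r])
            parent[r] = winner
            alive.pop(r, None)
            peak_val.pop(r, None)
        parent[idx] = winner

    gmin = float(flat.min())
    for root in list(alive):
        r = _find_root(parent, root)
        for rep in alive.get(root, []):
            prominences[rep] = (peak_val[r], peak_val[r] - gmin)
    out = sorted(prominences.items())
    return [(rep, val, prom) for rep, (val, prom) in out]


def _plateau_regions(img: np.ndarray, reps: list[int]) -> dict[int, np.ndarray]:
    """Map rep flat-index -> (k, 2) array of plateau pixel coords."""
    regions: dict[int, np.ndarray] = {}
    by_value: dict[float, list[int]] = {}
    flat = img.ravel()
    for rep in reps:
        by_value.setdefault(float(flat[rep]), []).append(rep)
    for value, vreps in by_value.items():
        lab = measure.label(img == value, connectivity=2)
        for rep in vreps:
            y, x = np.unravel_index(rep, img.shape)
            coords = np.argwhere(lab == lab[y, x])
            regions[rep] = coords
    return regions


def find_maxima_count(
    frame: np.ndarray, params: MaximaParams
) -> tuple[int, np.ndarray]:
    """Count local maxima with prominence and intensity filters.

    Returns ``(count, centroids)`` where centroids is an ``(n, 2)`` float
    array of (y, x) plateau centroids in lexicographic order.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("find_maxima_count requires a 2D frame")
    cands = [
        rep
        for rep, val, prom in maxima_prominences(img)
        if prom >= params.prominence and val >= params.abs_threshold
    ]
    if not cands:
        return 0, np.empty((0, 2))
    regions = _plateau_regions(img, cands)
    ny, nx = img.shape
    centroids = []
    for rep in cands:
        coords = regions[rep]
        if params.exclude_edges:
            if (
                (coords[:, 0] == 0).any()
                or (coords[:, 1] == 0).any()
                or (coords[:, 0] == ny - 1).any()
                or (coords[:, 1] == nx - 1).any()
            ):
                continue
        centroids.append(coords.mean(axis=0))
    if not centroids:
        return 0, np.empty((0, 2))
    cents = np.array(centroids)
    order = np.lexsort((cents[:, 1], cents[:, 0]))
    cents = cents[order]
    return len(cents), cents


# ---------------------------------------------------------------------
# Maximum-entropy (Kapur) thresholding
# ---------------------------------------------------------------------


def kapur_threshold_index(counts: np.ndarray) -> int:
    """Kapur maximum-entropy threshold on a histogram.

    Returns the bin index t maximizing the sum of Shannon entropies of
    the background (bins <= t) and foreground (bins > t) distributions;
    ties break to the lowest index. Requires mass on both sides of some
    split.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P0 = np.cumsum(p)
    S0 = np.cumsum(plogp)
    P1 = 1.0 - P0
    S1 = plogp.sum() - S0
    valid = (P0 > 0) & (P1 > 0)
    if not valid.any():
        raise ValueError("histogram has all mass in one bin")
    with np.errstate(divide="ignore", invalid="ignore"):
        Hb = np.log(P0) - S0 / P0
        Hf = np.log(P1) - S1 / P1
    obj = np.where(valid, Hb + Hf, -np.inf)
    return int(np.argmax(obj))  # argmax takes the first (lowest) maximizer


def max_entropy_threshold(frame: np.ndarray, nbins: int = 256) -> float:
    """Kapur threshold of a frame, returned on its intensity scale.

    Integer data with a modest range uses the exact integer histogram
    (making the threshold shift-equivariant); otherwise ``nbins`` equal
    bins span [min, max]. Pixels strictly above the returned value are
    foreground.
    """
    data = np.asarray(frame)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("constant frame has no threshold")
    if np.issubdtype(data.dtype, np.integer) and (hi - lo) <= 65535:
        values = np.arange(int(lo), int(hi) + 1)
        counts = np.bincount((data - int(lo)).ravel().astype(np.int64))
        idx = kapur_threshold_index(counts)
        return float(values[idx])
    counts, edges = np.histogram(data.ravel(), bins=nbins, range=(lo, hi))
    idx = kapur_threshold_index(counts)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[idx])


# ---------------------------------------------------------------------
# Particle analysis and outlines
# ---------------------------------------------------------------------


@dataclass
class Particle:
    """One connected component of a binary mask."""

    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    equivalent_diameter_um: float
    bbox: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))


def _check_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("input must be binary (values in {0, 1})")
    return arr.astype(bool)


def analyze_particles(
    mask: np.ndarray,
    min_area_px: int = 1,
    max_area_px: float = math.inf,
    connectivity: int = 2,
    pixel_size_um: float = 1.0,
) -> list[Particle]:
    """Connected components of a binary mask filtered by area.

    8-connectivity by default; labels are assigned in raster order, so
    output is deterministic. Equivalent diameter is that of the circle
    with the particle's area.
    """
    arr = _check_binary(mask)
    lab = measure.label(arr, connectivity=connectivity)
    out: list[Particle] = []
    for rp in measure.regionprops(lab):
        if not (min_area_px <= rp.area <= max_area_px):
            continue
        area_um2 = rp.area * pixel_size_um**2
        out.append(
            Particle(
                label=int(rp.label),
                area_px=int(rp.area),
                area_um2=float(area_um2),
                centroid=tuple(map(float, rp.centroid)),
                equivalent_diameter_um=float(2.0 * math.sqrt(area_um2 / math.pi)),
                bbox=tuple(map(int, rp.bbox)),
            )
        )
    return out


def binary_outline(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide boundary: mask minus its 3x3 erosion.

    Pixels on the frame border belong to the outline of any mask that
    touches the border.
    """
    arr = _check_binary(mask)
    eroded = ndi.binary_erosion(arr, structure=np.ones((3, 3)), border_value=0)
    return arr & ~eroded


# ---------------------------------------------------------------------
# Dual-threshold single-channel counting
# ---------------------------------------------------------------------


def dual_threshold_count(
    movie: ImageStack,
    cell_mask: np.ndarray,
    low_thr: float,
    high_thr: float,
    ca_gate: np.ndarray,
    prominence: float,
    exclude_edges: bool = False,
):
    """Per-frame cluster counts with a Ca²⁺-gated threshold switch.

    A dual-reporter channel mixes Ca²⁺-driven cytosolic brightness with
    condensate puncta. Counting uses the high intensity floor on frames
    where the Ca²⁺ gate is on (bright cytosol) and the low floor
    otherwise, then merges the two into a single trace — a deterministic
    automation of the usual manual merge. Both raw traces are returned
    for audit.

    Returns a DataFrame with columns ``frame, time_s, count_low,
    count_high, ca_gate, count_merged``.
    """
    import pandas as pd

    if movie.axes != "TYX":
        raise ValueError("dual_threshold_count requires a TYX movie")
    if not low_thr < high_thr:
        raise ValueError("low_thr must be below high_thr")
    gate = np.asarray(ca_gate, dtype=bool)
    if gate.shape != (movie.n_frames,):
        raise ValueError("ca_gate length must equal the number of frames")
    cmask = np.asarray(cell_mask, dtype=bool)
    if cmask.shape != movie.frame_shape:
        raise ValueError("cell mask shape must match the movie frames")

    dt = movie.frame_interval_s or 1.0
    rows = []
    for t, frame in enumerate(movie.iter_frames()):
        img = np.asarray(frame, dtype=float)
        maxima = maxima_prominences(img)
        flat_mask = cmask.ravel()
        counts = {}
        for name, thr in (("low", low_thr), ("high", high_thr)):
            reps = [
                rep
                for rep, val, prom in maxima
                if prom >= prominence and val >= thr and flat_mask[rep]
            ]
            if exclude_edges and reps:
                regions = _plateau_regions(img, reps)
                ny, nx = img.shape
                reps = [
                    rep
                    for rep in reps
                    if not (
                        (regions[rep][:, 0] == 0).any()
                        or (regions[rep][:, 1] == 0).any()
                        or (regions[rep][:, 0] == ny - 1).any()
                        or (regions[rep][:, 1] == nx - 1).any()
                    )
                ]
            counts[name] = len(reps)
        rows.append(
            {
                "frame": t,
                "time_s": t * dt,
                "count_low": counts["low"],
                "count_high": counts["high"],
                "ca_gate": bool(gate[t]),
                "count_merged": counts["high"] if gate[t] else counts["low"],
            }
        )
    return pd.DataFrame(rows)
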