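"""Independent brute-force oracles used to validate the fast
implementations. Deliberately naive: exhaustive scans, flood fills and
direct min/max sweeps with no shared code paths."""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi

_STRUCT8 = np.ones((3, 3), dtype=bool)


def prominence_maxima_oracle(img: np.ndarray) -> list[tuple[float, float]]:
    """All plateau maxima of a 2D image as (value, prominence).

    A plateau region is a maximum when no border pixel is strictly
    brighter. Its prominence is value minus the highest threshold t at
    which the connected component of {img >= t} containing the region
    reaches a strictly brighter pixel (value minus global minimum when
    it never does). Exhaustive scan over all unique intensity levels.
    """
    img = np.asarray(img, dtype=float)
    gmin = img.min()
    uniq = np.unique(img)[::-1]  # descending
    out: list[tuple[float, float]] = []
    for v in uniq:
        lab, n = ndi.label(img == v, structure=_STRUCT8)
        for k in range(1, n + 1):
            region = lab == k
            border = ndi.binary_dilation(region, structure=_STRUCT8) & ~region
            if (img[border] > v).any():
                continue  # strictly brighter neighbour: not a maximum
            prom = v - gmin
            for t in uniq[uniq <= v]:
                comp_lab, _ = ndi.label(img >= t, structure=_STRUCT8)
                cid = comp_lab[region][0]
                if (img[comp_lab == cid] > v).any():
                    prom = v - t
                    break
            out.append((float(v), float(prom)))
    return out


def kapur_scan_oracle(counts: np.ndarray) -> int:
    """Exhaustive scan of the Kapur entropy objective; lowest-index ties."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    best = -math.inf
    best_i = -1
    for t in range(len(p)):
        p0 = p[: t + 1].sum()
        p1 = p[t + 1 :].sum()
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = -sum(q / p0 * math.log(q / p0) for q in p[: t + 1] if q > 0)
        h1 = -sum(q / p1 * math.log(q / p1) for q in p[t + 1 :] if q > 0)
        if h0 + h1 > best + 1e-12:
            best = h0 + h1
            best_i = t
    return best_i


def triangle_scan_oracle(counts: np.ndarray) -> int:
    """Exhaustive scan of perpendicular point-to-chord distance."""
    h = np.asarray(counts, dtype=float)
    nz = np.nonzero(h)[0]
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(h))
    tail = last if (last - peak) >= (peak - first) else first
    p1 = np.array([peak, h[peak]])
    p2 = np.array([tail, h[tail]])
    d = p2 - p1
    best, best_i = -1.0, -1
    lo, hi = sorted((peak, tail))
    for i in range(lo, hi + 1):
        q = np.array([i, h[i]])
        # distance via rejection of the projection onto the chord
        t = np.dot(q - p1, d) / np.dot(d, d)
        dist = float(np.linalg.norm(q - p1 - t * d))
        if dist > best + 1e-12:
            best, best_i = dist, i
    return best_i


def flood_fill_count_oracle(mask: np.ndarray, connectivity: int = 2) -> list[int]:
    """Connected-component areas of a binary mask via explicit BFS."""
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    if connectivity == 2:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = np.zeros_like(mask)
    areas = []
    for y in range(ny):
        for x in range(nx):
            if not mask[y, x] or seen[y, x]:
                continue
            stack = [(y, x)]
            seen[y, x] = True
            area = 0
            while stack:
                cy, cx = stack.pop()
                area += 1
                for dy, dx in offs:
                    py, px = cy + dy, cx + dx
                    if 0 <= py < ny and 0 <= px < nx and mask[py, px] and not seen[py, px]:
                        seen[py, px] = True
                        stack.append((py, px))
            areas.append(area)
    return areas


def naive_ball_opening(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening by a non-flat ball via direct min/max sweeps."""
    n = int(math.floor(radius))
    offs = []
    for dy in range(-n, n + 1):
        for dx in range(-n, n + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offs.append((dy, dx, math.sqrt(radius * radius - d2)))
    ny, nx = img.shape
    padded = np.pad(img, n, mode="symmetric")
    eroded = np.empty_like(img, dtype=float)
    for y in range(ny):
        for x in range(nx):
            eroded[y, x] = min(
                padded[y + n + dy, x + n + dx] - h for dy, dx, h in offs
            )
    pe = np.pad(eroded, n, mode="symmetric")
    opened = np.empty_like(img, dtype=float)
    for y in range(ny):
        for x in range(nx):
            opened[y, x] = max(pe[y + n + dy, x + n + dx] + h for dy, dx, h in offs)
    return opened
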