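"""Cell typing by largest-condensate diameter and population summaries.

Cells are typed by the equivalent diameter of the largest condensate
observed in them: type 1 below 1.0 µm, type 2 from 1.0 to 3.6 µm
(boundaries inclusive), type 3 above 3.6 µm. Cells without any detected
condensate are reported separately, not typed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

TYPE_BOUNDARIES_UM: tuple[float, float] = (1.0, 3.6)


@dataclass
class CellTypeCall:
    cell_id: int
    largest_droplet_diameter_um: float | None
    type: int | None  # 1, 2, 3, or None when no clusters
    has_clusters: bool
    source: str = "2d"  # "2d" (area-derived) or "3d" (volume-derived)


def classify_cell(
    largest_d_um: float,
    boundaries_um: tuple[float, float] = TYPE_BOUNDARIES_UM,
) -> int:
    """Type a cell from its largest condensate's equivalent diameter (µm).

    d < b1 -> 1; b1 <= d <= b2 -> 2; d > b2 -> 3. The middle interval is
    closed on both sides; boundaries are configurable.
    """
    b1, b2 = boundaries_um
    if not (0 < b1 < b2):
        raise ValueError("boundaries must satisfy 0 < b1 < b2")
    if not (isinstance(largest_d_um, (int, float)) and math.isfinite(largest_d_um)):
        raise ValueError("diameter must be a finite number")
    if largest_d_um <= 0:
        raise ValueError("diameter must be positive")
    if largest_d_um < b1:
        return 1
    if largest_d_um <= b2:
        return 2
    return 3


def presence_summary(
    largest_diameters_um: Sequence[float | None],
    n_replicates: int | None = None,
    boundaries_um: tuple[float, float] = TYPE_BOUNDARIES_UM,
) -> dict:
    """Population summary over per-cell largest diameters.

    ``None`` or NaN marks a cell without detected condensates. Returns
    the cluster-positive fraction, the type distribution among positive
    cells, raw counts, and the ``n = X/x`` annotation (replicates/cells)
    when the number of replicates is given.
    """
    diam = list(largest_diameters_um)
    if len(diam) == 0:
        raise ValueError("need at least one cell")
    n_cells = len(diam)
    types = []
    for d in diam:
        if d is None or (isinstance(d, float) and math.isnan(d)):
            types.append(0)  # no clusters
        else:
            types.append(classify_cell(float(d), boundaries_um))
    types_arr = np.asarray(types)
    n_pos = int((types_arr > 0).sum())
    counts = {k: int((types_arr == k).sum()) for k in (0, 1, 2, 3)}
    type_dist = (
        tuple(counts[k] / n_pos for k in (1, 2, 3)) if n_pos else (0.0, 0.0, 0.0)
    )
    out = {
        "n_cells": n_cells,
        "n_with_clusters": n_pos,
        "fraction_with_clusters": n_pos / n_cells,
        "counts": counts,
        "type_distribution": type_dist,  # among cluster-positive cells
    }
    if n_replicates is not None:
        out["n_annotation"] = f"n = {n_replicates}/{n_cells}"
    return out
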