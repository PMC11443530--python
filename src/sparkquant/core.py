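"""Core containers: calibrated image stacks and regions of interest.

Axis convention is ``(T|Z, Y, X)`` with 0-based indices; physical
calibration is carried alongside the pixel data so that downstream
morphometry can report µm-scale quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.draw import polygon2mask

VALID_AXES = ("YX", "TYX", "ZYX")


@dataclass
class ImageStack:
    """An intensity grid (single frame, time series, or z-stack) with
    physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(Y, X)``, ``(T, Y, X)`` or ``(Z, Y, X)``.
    axes
        One of ``"YX"``, ``"TYX"``, ``"ZYX"``; names the leading axis.
    pixel_size_um
        Lateral pixel size in µm/px (> 0).
    z_step_um
        Axial spacing in µm per slice; required for ``"ZYX"`` data.
    frame_interval_s
        Acquisition interval in seconds; meaningful for ``"TYX"`` data.
    """

    data: np.ndarray
    axes: str
    pixel_size_um: float
    z_step_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.axes not in VALID_AXES:
            raise ValueError(f"axes must be one of {VALID_AXES}, got {self.axes!r}")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dims but axes {self.axes!r} "
                f"implies {len(self.axes)}"
            )
        if not (self.pixel_size_um is None or self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if np.issubdtype(self.data.dtype, np.integer) and self.data.size:
            if self.data.min() < 0:
                raise ValueError("integer-typed image data must be non-negative")

    # -- convenience -------------------------------------------------
    @property
    def n_frames(self) -> int:
        """Number of frames (T) or slices (Z); 1 for a bare 2D frame."""
        return 1 if self.axes == "YX" else self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self.data.shape[-2:])  # type: ignore[return-value]

    def frame(self, i: int) -> np.ndarray:
        if self.axes == "YX":
            if i != 0:
                raise IndexError("single-frame stack")
            return self.data
        return self.data[i]

    def iter_frames(self):
        if self.axes == "YX":
            yield self.data
        else:
            yield from self.data

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Return a copy carrying the same calibration but new pixel data."""
        return replace(self, data=np.asarray(data))

    def times_s(self) -> np.ndarray:
        """Frame times in seconds (movies only)."""
        if self.axes != "TYX" or self.frame_interval_s is None:
            raise ValueError("times_s requires a TYX stack with frame_interval_s")
        return np.arange(self.n_frames) * float(self.frame_interval_s)


@dataclass
class ROI:
    """A labelled pixel region ("cell" or "background") as a boolean mask."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in ("cell", "background"):
            raise ValueError("ROI label must be 'cell' or 'background'")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @classmethod
    def from_polygon(
        cls, label: str, vertices: Sequence[tuple[float, float]], shape: tuple[int, int]
    ) -> "ROI":
        """Build from (y, x) polygon vertices in pixel coordinates."""
        mask = polygon2mask(shape, np.asarray(vertices, dtype=float))
        return cls(label=label, mask=mask)

    @classmethod
    def from_box(
        cls, label: str, y0: int, x0: int, y1: int, x1: int, shape: tuple[int, int]
    ) -> "ROI":
        """Axis-aligned box ``[y0, y1) x [x0, x1)``."""
        mask = np.zeros(shape, dtype=bool)
        mask[y0:y1, x0:x1] = True
        return cls(label=label, mask=mask)

    def check_bounds(self, frame_shape: tuple[int, int]) -> None:
        if self.mask.shape != tuple(frame_shape):
            raise ValueError(
                f"ROI shape {self.mask.shape} does not match frame {frame_shape}"
            )
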