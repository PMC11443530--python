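"""Image conditioning: background subtraction, contrast boosting, rescaling.

All operations act frame-by-frame (per T or per Z) and return a new
:class:`~sparkquant.core.ImageStack` carrying the input calibration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .core import ImageStack, ROI


def _per_frame(stack: ImageStack, fn) -> ImageStack:
    if stack.axes == "YX":
        return stack.with_data(fn(np.asarray(stack.data, dtype=float)))
    out = np.stack([fn(np.asarray(f, dtype=float)) for f in stack.iter_frames()])
    return stack.with_data(out)


def subtract_background_roi(stack: ImageStack, roi: ROI) -> ImageStack:
    """Subtract, per frame, the mean intensity inside a background ROI.

    Output is real-valued and clamped at zero.
    """
    if roi.label != "background":
        raise ValueError("subtract_background_roi requires a background ROI")
    roi.check_bounds(stack.frame_shape)

    def fn(frame: np.ndarray) -> np.ndarray:
        bg = frame[roi.mask].mean()
        return np.clip(frame - bg, 0.0, None)

    return _per_frame(stack, fn)


def ball_structure(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Non-flat ball structuring element: (heights, footprint).

    Heights are ``sqrt(r^2 - d^2)`` inside the disc of radius *r* so that
    grayscale opening slides a sphere of that radius under the intensity
    surface (the classic rolling-ball background estimate).
    """
    r = float(radius_px)
    if r < 1:
        raise ValueError("radius_px must be >= 1")
    n = int(np.floor(r))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= r**2
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(r**2 - d2[footprint])
    return heights, footprint


def rolling_ball_subtract(stack: ImageStack, radius_px: float) -> ImageStack:
    """Rolling-ball background subtraction (per frame).

    The background is the grayscale opening of the frame by a ball-shaped
    structuring element (erosion then dilation); subtracting it keeps
    features narrower than the ball and removes smooth background. The
    result is non-negative by construction.
    """
    heights, footprint = ball_structure(radius_px)
    ny, nx = stack.frame_shape
    if heights.shape[0] > ny or heights.shape[1] > nx:
        raise ValueError("rolling-ball radius larger than the image")
    structure = np.where(footprint, heights, -np.inf)

    def fn(frame: np.ndarray) -> np.ndarray:
        eroded = ndi.grey_erosion(frame, structure=structure)
        background = ndi.grey_dilation(eroded, structure=structure)
        return np.clip(frame - background, 0.0, None)

    return _per_frame(stack, fn)


def self_multiply(stack: ImageStack) -> ImageStack:
    """Pixel-wise multiplication of each frame with itself (squaring).

    A monotone transform on non-negative data: it preserves intensity
    order while boosting the relative contrast of bright puncta over the
    diffuse background.
    """
    return _per_frame(stack, lambda f: f * f)


def rescale_to_8bit(
    stack: ImageStack, lo: float | None = None, hi: float | None = None
) -> ImageStack:
    """Linear rescale of ``[lo, hi]`` to ``[0, 255]`` (uint8, round half-up).

    Defaults map the global stack minimum/maximum; a constant stack with
    default limits is degenerate and raises.
    """
    data = np.asarray(stack.data, dtype=float)
    if lo is None:
        lo = float(data.min())
    if hi is None:
        hi = float(data.max())
    if not hi > lo:
        raise ValueError("degenerate intensity range: hi must exceed lo")
    scaled = (data - lo) / (hi - lo) * 255.0
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    # half-up rounding may push 254.5+0.5 over: clip again, then cast
    return stack.with_data(np.clip(out, 0, 255).astype(np.uint8))


def display_normalize_per_frame(stack: ImageStack) -> ImageStack:
    """Per-frame display normalization: [frame mean, frame max] -> [0, 1].

    Pixels at or below the frame mean map to 0. Intended to prepare
    frames for Max-Entropy thresholding or visualization — not for
    quantitative traces. A constant frame is set to zero with a warning.
    """

    def fn(frame: np.ndarray) -> np.ndarray:
        lo, hi = frame.mean(), frame.max()
        if hi <= lo:
            warnings.warn("constant frame in display normalization; set to 0")
            return np.zeros_like(frame)
        return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)

    return _per_frame(stack, fn)
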