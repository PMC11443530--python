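"""TIFF/OME-TIFF reading and writing with physical calibration, and
JSON ROI loading."""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile

from .core import ImageStack, ROI


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with µm/s calibration."""
    metadata: dict = {"axes": stack.axes}
    if stack.pixel_size_um is not None:
        metadata.update(
            PhysicalSizeX=stack.pixel_size_um,
            PhysicalSizeXUnit="µm",
            PhysicalSizeY=stack.pixel_size_um,
            PhysicalSizeYUnit="µm",
        )
    if stack.z_step_um is not None:
        metadata.update(PhysicalSizeZ=stack.z_step_um, PhysicalSizeZUnit="µm")
    if stack.frame_interval_s is not None:
        metadata.update(TimeIncrement=stack.frame_interval_s, TimeIncrementUnit="s")
    tifffile.imwrite(str(path), stack.data, ome=True, metadata=metadata)


def _ome_pixel_attrs(ome_xml: str) -> dict:
    """Extract Pixels attributes from OME-XML, namespace-agnostically."""
    root = ET.fromstring(ome_xml)
    for elem in root.iter():
        if elem.tag.rsplit("}", 1)[-1] == "Pixels":
            return dict(elem.attrib)
    return {}


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Axes and calibration are taken from OME metadata when present;
    explicit arguments override the file. Integer data is preserved
    losslessly. Raises when the pixel size is missing from both the
    file and the overrides, or when the axis layout is ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes
        attrs = _ome_pixel_attrs(tf.ome_metadata) if tf.ome_metadata else {}

    if axes is None:
        if file_axes in ("YX", "TYX", "ZYX"):
            axes = file_axes
        elif data.ndim == 2:
            axes = "YX"
        else:
            raise ValueError(
                f"ambiguous axis layout {file_axes!r} in {path.name}; "
                "pass axes='TYX' or 'ZYX' explicitly"
            )
    if data.ndim != len(axes):
        raise ValueError(f"data shape {data.shape} does not match axes {axes!r}")

    def _get(attr: str) -> float | None:
        v = attrs.get(attr)
        return float(v) if v is not None else None

    px = pixel_size_um if pixel_size_um is not None else _get("PhysicalSizeX")
    if px is None:
        raise ValueError(
            f"{path.name}: pixel size missing from metadata; pass pixel_size_um"
        )
    dz = z_step_um if z_step_um is not None else _get("PhysicalSizeZ")
    dt = frame_interval_s if frame_interval_s is not None else _get("TimeIncrement")
    if axes == "ZYX" and dz is None:
        raise ValueError(
            f"{path.name}: z spacing missing from metadata; pass z_step_um"
        )
    return ImageStack(
        data=data,
        axes=axes,
        pixel_size_um=px,
        z_step_um=dz if axes == "ZYX" else None,
        frame_interval_s=dt if axes == "TYX" else None,
    )


def read_rois(path: str | Path, frame_shape: tuple[int, int]) -> list[ROI]:
    """Load ROIs from a JSON list.

    Each entry is ``{"label": "cell"|"background", "polygon": [[y, x],
    ...]}`` or ``{"label": ..., "box": [y0, x0, y1, x1]}`` (half-open
    box) in pixel coordinates.
    """
    entries = json.loads(Path(path).read_text())
    rois = []
    for e in entries:
        if "polygon" in e:
            rois.append(ROI.from_polygon(e["label"], e["polygon"], frame_shape))
        elif "box" in e:
            y0, x0, y1, x1 = e["box"]
            rois.append(ROI.from_box(e["label"], y0, x0, y1, x1, frame_shape))
        else:
            raise ValueError("ROI entry needs a 'polygon' or 'box'")
    return rois
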