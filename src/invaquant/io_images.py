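"""TIFF / OME-TIFF reading and writing, calibration, and z-projection.

Physical pixel size resolves in priority order: an explicit override, a
JSON sidecar (``<image>.json``, written by this package alongside every
output), then OME-XML ``PhysicalSizeX``. An image without a pixel size
anywhere is an error — there is no sensible default, calibration is a
required input. Anisotropic x/y pixels are rejected because every metric
here is radial.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import tifffile

from .core import CalibratedImage, CalibrationError

__all__ = ["read_image", "write_image", "z_project"]

_UM_ALIASES = {"µm", "um", "micron", "microns", "micrometer", "micrometre", None, ""}


def _pixel_size_from_ome(tif: tifffile.TiffFile) -> Optional[float]:
    if not tif.is_ome or tif.ome_metadata is None:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        images = meta["OME"]["Image"]
        if isinstance(images, list):
            images = images[0]
        pix = images["Pixels"]
        sx = pix.get("PhysicalSizeX")
        sy = pix.get("PhysicalSizeY", sx)
        ux = pix.get("PhysicalSizeXUnit")
        if sx is None:
            return None
        if ux not in _UM_ALIASES:
            raise CalibrationError(f"unsupported pixel size unit {ux!r} (expected μm)")
        if sy is not None and not np.isclose(float(sx), float(sy), rtol=1e-6):
            raise CalibrationError(
                f"anisotropic pixels ({sx} × {sy} μm) are not supported"
            )
        return float(sx)
    except (KeyError, TypeError):
        return None


def _frame_interval_from_ome(tif: tifffile.TiffFile) -> Optional[float]:
    if not tif.is_ome or tif.ome_metadata is None:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        images = meta["OME"]["Image"]
        if isinstance(images, list):
            images = images[0]
        pix = images["Pixels"]
        ti = pix.get("TimeIncrement")
        unit = pix.get("TimeIncrementUnit", "s")
        if ti is None:
            return None
        scale = {"s": 1 / 60.0, "min": 1.0, "ms": 1 / 60000.0, "h": 60.0}.get(unit)
        if scale is None:
            return None
        return float(ti) * scale
    except (KeyError, TypeError):
        return None


def _sidecar_path(path: str) -> str:
    return str(path) + ".json"


def read_image(
    path,
    *,
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
    axes: Optional[str] = None,
) -> CalibratedImage:
    """Read a TIFF/OME-TIFF into a :class:`CalibratedImage`.

    ``pixel_size`` (μm/px), ``frame_interval`` (min) and ``axes`` (e.g.
    ``"tzyx"``) override anything found in metadata.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = series.axes.lower().replace("s", "c").replace("q", "z")
        ome_px = _pixel_size_from_ome(tif)
        ome_dt = _frame_interval_from_ome(tif)

    sidecar = {}
    if os.path.exists(_sidecar_path(path)):
        with open(_sidecar_path(path)) as fh:
            sidecar = json.load(fh)

    px = pixel_size if pixel_size is not None else sidecar.get("pixel_size_um", ome_px)
    dt = (
        frame_interval
        if frame_interval is not None
        else sidecar.get("frame_interval_min", ome_dt)
    )
    resolved_axes = (axes if axes is not None else sidecar.get("axes", file_axes)).lower()

    if px is None:
        raise CalibrationError(
            f"no pixel size for {path!r}: supply pixel_size= (μm/px) or store it "
            "in OME metadata / a JSON sidecar"
        )
    if len(resolved_axes) == data.ndim:
        # drop singleton non-spatial axes TIFF writers pad in (e.g. 1-channel C)
        keep = [
            i
            for i, (a, n) in enumerate(zip(resolved_axes, data.shape))
            if n > 1 or a in "yx"
        ]
        data = data.reshape([data.shape[i] for i in keep])
        resolved_axes = "".join(resolved_axes[i] for i in keep)
    else:
        raise CalibrationError(
            f"axes {resolved_axes!r} do not match array with {data.ndim} dimensions"
        )
    return CalibratedImage(
        pixels=data,
        pixel_size=float(px),
        axes=resolved_axes,
        frame_interval=float(dt) if dt is not None else None,
    )


def write_image(path, image: CalibratedImage) -> None:
    """Write an OME-TIFF plus a JSON calibration sidecar."""
    path = str(path)
    meta = {
        "axes": image.axes.upper(),
        "PhysicalSizeX": image.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": image.pixel_size,
        "PhysicalSizeYUnit": "µm",
    }
    data = image.pixels
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, ome=True, metadata=meta)
    sidecar = {
        "pixel_size_um": image.pixel_size,
        "axes": image.axes,
    }
    if image.frame_interval is not None:
        sidecar["frame_interval_min"] = image.frame_interval
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def z_project(image: CalibratedImage, method: str = "max") -> CalibratedImage:
    """Collapse the z axis per pixel (``"max"`` default, ``"mean"`` optional).

    Maximum projection guarantees every bright cell from any focal plane
    survives into the 2D image, which is what "include all cells"
    thresholding needs; mean projection is available for dense stacks
    where maximum noise accumulation matters.
    """
    if not image.has_axis("z"):
        raise ValueError(f"image has no z axis to project (axes={image.axes!r})")
    z_ax = image.axis_index("z")
    if method == "max":
        proj = image.pixels.max(axis=z_ax)
    elif method == "mean":
        proj = image.pixels.mean(axis=z_ax)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return CalibratedImage(
        pixels=proj,
        pixel_size=image.pixel_size,
        axes=image.axes.replace("z", ""),
        frame_interval=image.frame_interval,
        channel_labels=image.channel_labels,
    )


def z_project_max(image: CalibratedImage) -> CalibratedImage:
    """Maximum-intensity z-projection (see :func:`z_project`)."""
    return z_project(image, method="max")
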