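"""Cell segmentation on z-projections.

Produces the "all cells" binary mask used by every spatial metric. The
default threshold is Otsu's method on the projection — a reproducible
stand-in for interactively setting a threshold that includes all cells —
with a manual threshold override. Pixels inside the bead circle are always
removed: cells on the spheroid surface must not count as migrated at
distance zero, and the bead itself is bright in most stains.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects

from .core import BeadCircle, CalibratedImage, CellMask

__all__ = ["segment_cells", "flag_out_of_range", "SegmentationWarning"]


class SegmentationWarning(UserWarning):
    pass


def segment_cells(
    projection: CalibratedImage,
    bead: BeadCircle,
    *,
    method: str = "otsu",
    threshold: Optional[float] = None,
    min_object_area: float = 0.0,
) -> CellMask:
    """Threshold a 2D projection into a bead-excluded cell mask.

    Parameters
    ----------
    projection
        2D calibrated image (bright cells on dark background).
    bead
        The fitted bead circle; its interior is forced to background.
    method
        ``"otsu"`` (default) or ``"manual"`` (requires ``threshold``).
    threshold
        Manual intensity cutoff; pixels strictly above it are cells.
    min_object_area
        Connected components smaller than this (μm²) are discarded as
        debris. Default 0 keeps everything.
    """
    if projection.pixels.ndim != 2:
        raise ValueError("segment_cells expects a 2D projection; z-project first")
    img = np.asarray(projection.pixels, dtype=float)

    if method == "manual":
        if threshold is None:
            raise ValueError("manual thresholding requires a threshold value")
        thr = float(threshold)
    elif method == "otsu":
        if threshold is not None:
            thr = float(threshold)
        elif np.ptp(img) == 0:
            warnings.warn(
                "image is constant; returning an empty mask", SegmentationWarning
            )
            return CellMask(
                mask=np.zeros_like(img, dtype=bool),
                pixel_size=projection.pixel_size,
                bead=bead,
            )
        else:
            thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    binary = img > thr
    if not binary.any():
        warnings.warn(
            f"threshold {thr} lies above every pixel; mask is empty",
            SegmentationWarning,
        )

    if min_object_area > 0:
        min_px = int(np.ceil(min_object_area / projection.pixel_size ** 2))
        if min_px > 1:
            # drop components with fewer than min_px pixels
            binary = remove_small_objects(binary, max_size=min_px - 1)

    # CellMask construction enforces bead-interior exclusion
    return CellMask(mask=binary, pixel_size=projection.pixel_size, bead=bead)


def flag_out_of_range(mask: CellMask, profile_extent: float) -> CellMask:
    """Drop components lying wholly beyond the profiled extent.

    A component whose *every* pixel is farther than bead radius +
    ``profile_extent`` (μm) from the bead center is out of range of the
    ring analysis and excluded; components straddling the boundary are
    retained in full (per-pixel ring binning decides their contribution)
    and noted in the report attached as ``exclusions``.
    """
    d = mask.bead.distance_map(mask.mask.shape, mask.pixel_size)
    limit = mask.bead.radius + profile_extent
    labels = label(mask.mask, connectivity=2)
    excluded, straddling = [], []
    out = mask.mask.copy()
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        dmin = d[comp].min()
        dmax = d[comp].max()
        if dmin > limit:
            out[comp] = False
            excluded.append(lab)
        elif dmax > limit:
            straddling.append(lab)
    report = {
        "profile_extent_um": profile_extent,
        "n_components": int(labels.max()),
        "n_excluded": len(excluded),
        "n_straddling_retained": len(straddling),
    }
    return CellMask(
        mask=out, pixel_size=mask.pixel_size, bead=mask.bead, exclusions=report
    )
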