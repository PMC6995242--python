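"""Locating the microcarrier bead (the reference circle for all distances).

The protocol measures every distance from the circle matching the bead's
biggest diameter, found by browsing a z-stack. Here that manual step is
automated: per slice, edges are extracted with a Canny filter and a
circular Hough transform votes over a user-supplied radius range; the best
circle is refined by an algebraic least-squares fit on nearby edge pixels.
Across a stack the slice yielding the largest refined radius wins —
the equatorial section of the bead. A manual circle entry bypasses
detection entirely, mirroring the hand-drawn workflow.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .core import BeadCircle, CalibratedImage, DetectionError, GeometryError

__all__ = ["detect_bead_circle", "manual_bead_circle", "fit_circle_lsq"]


def fit_circle_lsq(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit; returns (cy, cx, r) in px."""
    A = np.column_stack([xs, ys, np.ones_like(xs, dtype=float)])
    b = xs.astype(float) ** 2 + ys.astype(float) ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r = np.sqrt(sol[2] + cx ** 2 + cy ** 2)
    return float(cy), float(cx), float(r)


def _detect_in_slice(
    img: np.ndarray,
    r_min_px: float,
    r_max_px: float,
    sigma: float,
) -> Optional[tuple[float, float, float, float]]:
    """Best circle in one 2D frame: (cy, cx, r) px + Hough accumulator score."""
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        return None
    edges = canny(img / np.ptp(img), sigma=sigma)
    if not edges.any():
        return None
    radii = np.arange(max(int(np.floor(r_min_px)), 3), int(np.ceil(r_max_px)) + 1)
    if len(radii) == 0:
        return None
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] <= 0:
        return None
    cy, cx, r = float(cys[0]), float(cxs[0]), float(rads[0])

    # refine on edge pixels within a band around the Hough circle
    ey, ex = np.nonzero(edges)
    d = np.hypot(ey - cy, ex - cx)
    band = np.abs(d - r) <= 3.0
    if band.sum() >= 6:
        cy, cx, r = fit_circle_lsq(ey[band], ex[band])
    # Edge pixels are the outermost pixels *inside* the bright disc, so a
    # circle through their centers understates the footprint by up to one
    # pixel. Matching the biggest diameter means taking the outer bound:
    # grow the radius by half a pixel.
    return cy, cx, r + 0.5, float(accums[0])


def detect_bead_circle(
    image: CalibratedImage,
    radius_range: tuple[float, float],
    *,
    sigma: float = 2.0,
) -> BeadCircle:
    """Find the bead circle, taking the biggest diameter across a z-stack.

    Parameters
    ----------
    image
        2D frame or z-stack (a single bead per field is assumed; the
        protocol images spheroids well separated from their neighbours).
    radius_range
        (min, max) expected bead radius in μm. Required — microcarrier
        beads vary in size and no universal default exists.
    sigma
        Gaussian smoothing of the Canny edge detector, in pixels.

    Returns
    -------
    BeadCircle
        Center and radius in μm. For stacks, the slice whose fitted circle
        has the largest radius provides the result.
    """
    r_min, r_max = radius_range
    if not (0 < r_min < r_max):
        raise ValueError(f"invalid radius range {radius_range!r}")
    px = image.pixel_size

    if image.has_axis("z"):
        z_ax = image.axis_index("z")
        slices = np.moveaxis(image.pixels, z_ax, 0)
    elif image.pixels.ndim == 2:
        slices = image.pixels[None]
    else:
        raise ValueError(
            "detect_bead_circle expects a 2D image or a z-stack; "
            f"got axes {image.axes!r}"
        )

    best: Optional[tuple[float, float, float]] = None
    for sl in slices:
        hit = _detect_in_slice(np.asarray(sl), r_min / px, r_max / px, sigma)
        if hit is None:
            continue
        cy, cx, r, _ = hit
        if not (r_min / px * 0.8 <= r <= r_max / px * 1.2):
            continue
        if best is None or r > best[2]:
            best = (cy, cx, r)

    if best is None:
        raise DetectionError(
            f"no circular object found within radius range {radius_range} μm; "
            "supply the bead manually (e.g. --bead-circle CX,CY,R)"
        )
    cy, cx, r = best
    circle = BeadCircle(center_x=cx * px, center_y=cy * px, radius=r * px)
    return circle.check_inside(image.shape_yx, px)


def manual_bead_circle(
    cx: float,
    cy: float,
    r: float,
    image: Optional[CalibratedImage] = None,
) -> BeadCircle:
    """Construct a bead circle from user-given μm coordinates, verbatim.

    If an image is given, the center must fall inside its extent.
    """
    if r <= 0:
        raise GeometryError(f"bead radius must be > 0, got {r!r}")
    circle = BeadCircle(center_x=cx, center_y=cy, radius=r)
    if image is not None:
        circle.check_inside(image.shape_yx, image.pixel_size)
    return circle
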