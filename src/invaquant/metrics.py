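"""Spatial invasion read-outs around a microcarrier bead.

Three complementary summaries of cell dispersion on a z-projection:

* **Maximum migrating distance** — the radius of the smallest bead-centered
  circle containing every cell pixel, minus the bead radius. Suited to
  cohesive fronts; a single far-flung cell dominates it.
* **Average maximum migrating distance** — the migration front is traced as
  a convex polygon and converted to an equivalent circle through its
  perimeter P: distance = P / (2π) − bead radius. Only a convex front is
  valid; concavities inflate the perimeter and overestimate the radius.
* **Ring profile and migration index** — cell area is binned into
  concentric annuli of width w (default 10 μm) around the bead, and the
  index Σᵢ w·i·Area(i) weights each ring's area by its outer-radius offset.
  Because cell area is proportional to cell number for similar-sized
  cells, the index approximates "number of migrating cells × distance",
  summed over all cells — robust to a few outliers, sensitive to the bulk.

Annuli are half-open (inner-exclusive, outer-inclusive): a pixel exactly on
circle i belongs to ring i, which reproduces exactly the nested-circle area
subtraction Area(i) = area(Circle_i) − area(Circle_{i−1}) measured on the
same mask.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon

from .core import CellMask, GeometryError, MigrationMetrics, RingProfile

__all__ = [
    "max_migration_distance",
    "avg_max_migration_distance",
    "ring_profile",
    "migration_index",
    "migration_index_pixel_oracle",
    "compute_metrics",
]


def _distances(mask: CellMask) -> np.ndarray:
    """μm distance from bead center for every cell pixel."""
    d = mask.bead.distance_map(mask.mask.shape, mask.pixel_size)
    return d[mask.mask]


def max_migration_distance(mask: CellMask) -> float:
    """Radius of the migrating-front circle minus the bead radius, in μm.

    The front circle is the smallest bead-centered circle enclosing all
    cell pixels. Returns 0.0 for an empty mask.
    """
    d = _distances(mask)
    if d.size == 0:
        return 0.0
    return float(max(d.max() - mask.bead.radius, 0.0))


def _require_convex(polygon: Polygon, tol: float = 1e-9) -> Polygon:
    if not polygon.is_valid:
        raise GeometryError("front polygon is invalid (self-intersecting?)")
    hull = polygon.convex_hull
    if polygon.length > hull.length * (1 + tol) or polygon.area < hull.area * (1 - 1e-6):
        raise GeometryError(
            "front polygon is concave; a concave front inflates the perimeter "
            "and overestimates the migration radius — supply a convex front"
        )
    return polygon


def avg_max_migration_distance(
    mask: CellMask, front: Optional[Sequence[tuple[float, float]]] = None
) -> float:
    """Perimeter-equivalent front radius minus the bead radius, in μm.

    The migration front is the convex hull of all cell pixels (or a
    user-supplied convex polygon in μm coordinates). With perimeter P the
    equivalent front circle has radius P / (2π).
    """
    if front is not None:
        poly = _require_convex(Polygon(front))
        perimeter = poly.length
    else:
        pts = mask.cell_coordinates_um()
        if len(pts) < 3:
            raise GeometryError(
                f"need >= 3 cell pixels outside the bead to trace a front, got {len(pts)}"
            )
        hull = MultiPoint(pts).convex_hull
        if hull.geom_type != "Polygon":
            raise GeometryError("cell pixels are collinear; the front is degenerate")
        perimeter = hull.length
    return float(perimeter / (2 * np.pi) - mask.bead.radius)


def ring_profile(mask: CellMask, ring_width: float = 10.0) -> RingProfile:
    """Bin cell area into concentric annuli of ``ring_width`` μm.

    Area(i) collects cell pixels with r + (i−1)·w < d ≤ r + i·w from the
    bead center. Rings are generated out to the image corner farthest from
    the bead; rings whose outer circle crosses the image border are flagged
    as truncated (the first ``n_complete`` rings lie fully in-frame).
    """
    if ring_width <= 0:
        raise ValueError(f"ring_width must be > 0, got {ring_width!r}")
    bead = mask.bead
    r = bead.radius
    ny, nx = mask.mask.shape
    px = mask.pixel_size
    w_um, h_um = (nx - 1) * px, (ny - 1) * px

    border = min(bead.center_x, w_um - bead.center_x, bead.center_y, h_um - bead.center_y)
    corners = [(0.0, 0.0), (w_um, 0.0), (0.0, h_um), (w_um, h_um)]
    d_corner = max(np.hypot(cx - bead.center_x, cy - bead.center_y) for cx, cy in corners)

    n_complete = max(int(np.floor((border - r) / ring_width)), 0)
    n_total = max(int(np.ceil((d_corner - r) / ring_width)), n_complete)

    d = bead.distance_map(mask.mask.shape, px)[mask.mask]
    outside = d > r
    rings = np.ceil((d[outside] - r) / ring_width).astype(int)
    counts = np.bincount(rings, minlength=n_total + 1)[1 : n_total + 1]
    areas = counts.astype(float) * mask.pixel_area
    truncated = tuple(range(n_complete + 1, n_total + 1))
    return RingProfile(
        ring_width=ring_width,
        areas=areas,
        bead_radius=r,
        n_complete=n_complete,
        truncated_rings=truncated,
    )


def migration_index(profile: RingProfile, complete_rings_only: bool = False) -> float:
    """Σᵢ w·i·Area(i): ring areas weighted by outer-radius offset, μm·μm².

    Truncated border rings contribute by default (with a warning when they
    hold area); ``complete_rings_only`` drops them.
    """
    idx = np.arange(1, profile.n + 1)
    areas = profile.areas
    if complete_rings_only:
        keep = ~np.isin(idx, profile.truncated_rings)
        idx, areas = idx[keep], areas[keep]
    elif profile.truncated_rings:
        trunc = np.isin(idx, profile.truncated_rings)
        if areas[trunc].sum() > 0:
            warnings.warn(
                "migration index includes area in rings truncated by the image "
                "border; pass complete_rings_only=True to drop them",
                stacklevel=2,
            )
    return float(np.sum(profile.ring_width * idx * areas))


def migration_index_pixel_oracle(mask: CellMask, ring_width: float = 10.0) -> float:
    """Per-pixel restatement of the migration index, as an independent check.

    Each cell pixel at distance d from the bead center contributes
    w · ⌈(d − r)/w⌉ · pixel_area; pixels at or inside the bead contribute
    nothing. Definitionally equal to ``migration_index(ring_profile(mask))``.
    """
    if ring_width <= 0:
        raise ValueError(f"ring_width must be > 0, got {ring_width!r}")
    d = _distances(mask)
    d = d[d > mask.bead.radius]
    if d.size == 0:
        return 0.0
    weights = np.ceil((d - mask.bead.radius) / ring_width)
    return float(np.sum(ring_width * weights) * mask.pixel_area)


def compute_metrics(
    mask: CellMask,
    ring_width: float = 10.0,
    front: Optional[Sequence[tuple[float, float]]] = None,
    complete_rings_only: bool = False,
) -> MigrationMetrics:
    """All three read-outs for one mask; avg-max is None if degenerate."""
    profile = ring_profile(mask, ring_width=ring_width)
    try:
        avg_max = avg_max_migration_distance(mask, front=front)
    except GeometryError:
        avg_max = None
    return MigrationMetrics(
        max_distance=max_migration_distance(mask),
        avg_max_distance=avg_max,
        migration_index=migration_index(profile, complete_rings_only=complete_rings_only),
        ring_profile=profile,
    )
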