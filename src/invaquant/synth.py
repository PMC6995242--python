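"""Synthetic bead + cell imagery with exact ground truth.

The generator emulates the geometry of a microcarrier invasion assay as it
appears on a maximum-intensity z-projection: one bright circular bead (the
microcarrier core), cell bodies dispersed radially as filled discs or
axis-aligned squares of constant intensity, an even background, optional
Gaussian noise, and time-lapse sequences in which every cell translates at
a constant velocity. Every rendered frame comes with a ``GroundTruth``
recording the analytic geometry (per-cell distances and areas, the rendered
mask, and the per-pixel ring assignment) so that all downstream metrics can
be tested without real microscopy data.

All randomness flows through one ``numpy`` generator seeded from
``SynthSpec.seed``; a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import BeadCircle, CalibratedImage, Track

__all__ = [
    "SynthError",
    "CellSpec",
    "SynthSpec",
    "GroundTruth",
    "generate_spheroid_image",
    "generate_timelapse",
    "random_cells",
]

DEFAULT_FRAME_INTERVAL_MIN = 30.0  # typical confocal time-lapse interval


class SynthError(ValueError):
    """Invalid synthetic scene specification."""


@dataclass(frozen=True)
class CellSpec:
    """One synthetic cell body.

    ``center`` is (x, y) μm; ``size`` is the disc radius or the square
    half-side in μm. ``velocity`` is (vx, vy) in μm/h, used only by
    time-lapse generation.
    """

    center: tuple[float, float]
    size: float = 5.0
    shape: str = "disc"  # "disc" or "square"
    intensity: float = 200.0
    velocity: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise SynthError("cell size must be > 0")
        if self.shape not in ("disc", "square"):
            raise SynthError(f"unknown cell shape {self.shape!r}")


@dataclass(frozen=True)
class SynthSpec:
    """Scene description for one synthetic spheroid.

    Defaults emulate a 10x field of view: 512×512 px at 1 μm/px, a 50 μm
    bead at the image center, cells of intensity 200 on background 10, and
    a 30 min frame interval for time-lapse sequences.
    """

    image_size: tuple[int, int] = (512, 512)  # (ny, nx) pixels
    pixel_size: float = 1.0  # μm per pixel
    bead_center: Optional[tuple[float, float]] = None  # (x, y) μm; None = center
    bead_radius: float = 50.0  # μm
    bead_intensity: float = 250.0
    background: float = 10.0
    cells: tuple[CellSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN  # minutes
    allow_bead_overlap: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise SynthError("pixel_size must be > 0")
        if self.bead_radius <= 0:
            raise SynthError("bead_radius must be > 0")
        object.__setattr__(self, "cells", tuple(self.cells))

    @property
    def bead(self) -> BeadCircle:
        cx, cy = self.resolved_bead_center
        return BeadCircle(cx, cy, self.bead_radius)

    @property
    def resolved_bead_center(self) -> tuple[float, float]:
        if self.bead_center is not None:
            return self.bead_center
        ny, nx = self.image_size
        return ((nx - 1) / 2 * self.pixel_size, (ny - 1) / 2 * self.pixel_size)


@dataclass
class CellTruth:
    """Analytic ground truth for one rendered cell."""

    center: tuple[float, float]  # (x, y) μm
    shape: str
    size: float  # μm (radius or half-side... see CellSpec)
    center_distance: float  # |center - bead_center| - bead_radius, μm
    edge_distance: float  # nearest rendered pixel distance - bead_radius, μm
    area: float  # rendered area, μm²
    n_pixels: int

    def to_dict(self) -> dict:
        return {
            "center_x_um": self.center[0],
            "center_y_um": self.center[1],
            "shape": self.shape,
            "size_um": self.size,
            "center_distance_um": self.center_distance,
            "edge_distance_um": self.edge_distance,
            "area_um2": self.area,
            "n_pixels": self.n_pixels,
        }


@dataclass
class GroundTruth:
    """Exact per-scene truth written alongside every synthetic image."""

    bead: BeadCircle
    pixel_size: float
    cells: list[CellTruth]
    cell_mask: np.ndarray  # bool, cell pixels only (bead excluded)
    ring_assignment: np.ndarray  # int, ring index per pixel (0 = at/inside bead)
    ring_width: float
    seed: int
    ambiguous_pairs: list[tuple[int, int, int]] = field(default_factory=list)
    # (frame, cell_i, cell_j) closer than the stated linking radius

    def ring_areas(self, n: int) -> np.ndarray:
        """True Area(1..n) in μm² from the per-pixel ring assignment."""
        rings = self.ring_assignment[self.cell_mask]
        counts = np.bincount(rings, minlength=n + 1)[1 : n + 1]
        return counts.astype(float) * self.pixel_size ** 2

    def max_distance(self) -> float:
        """True maximum migrating distance over rendered cell pixels, μm."""
        if not self.cell_mask.any():
            return 0.0
        d = self.bead.distance_map(self.cell_mask.shape, self.pixel_size)
        return float(d[self.cell_mask].max() - self.bead.radius)

    def to_json_dict(self) -> dict:
        return {
            "bead": {
                "center_x_um": self.bead.center_x,
                "center_y_um": self.bead.center_y,
                "radius_um": self.bead.radius,
            },
            "pixel_size_um": self.pixel_size,
            "ring_width_um": self.ring_width,
            "seed": self.seed,
            "cells": [c.to_dict() for c in self.cells],
            "ambiguous_pairs": [list(p) for p in self.ambiguous_pairs],
        }


def _pixel_grids(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = spec.image_size
    y = np.arange(ny)[:, None] * spec.pixel_size
    x = np.arange(nx)[None, :] * spec.pixel_size
    return y, x


def _render_cell(cell: CellSpec, spec: SynthSpec) -> np.ndarray:
    """Boolean footprint of one cell: pixel centers inside the shape.

    Squares use a half-open [lo, hi) rule so that a square of side s at a
    grid-aligned position covers exactly (s/px)² pixels.
    """
    y, x = _pixel_grids(spec)
    cx, cy = cell.center
    if cell.shape == "disc":
        return (x - cx) ** 2 + (y - cy) ** 2 <= cell.size ** 2
    lo_x, hi_x = cx - cell.size, cx + cell.size
    lo_y, hi_y = cy - cell.size, cy + cell.size
    return (x >= lo_x) & (x < hi_x) & (y >= lo_y) & (y < hi_y)


def _check_in_bounds(cell: CellSpec, spec: SynthSpec, frame: Optional[int] = None) -> None:
    w = (spec.image_size[1] - 1) * spec.pixel_size
    h = (spec.image_size[0] - 1) * spec.pixel_size
    cx, cy = cell.center
    s = cell.size
    if cx - s < 0 or cy - s < 0 or cx + s > w or cy + s > h:
        where = f" at frame {frame}" if frame is not None else ""
        raise SynthError(
            f"cell at ({cx:.1f}, {cy:.1f}) μm with size {s:.1f} μm extends outside "
            f"the {w:.0f}×{h:.0f} μm image{where}"
        )


def _ring_assignment(spec: SynthSpec, ring_width: float) -> np.ndarray:
    """Ring index per pixel: ceil((d - r)/w) for d > r, else 0."""
    bead = spec.bead
    d = bead.distance_map(spec.image_size, spec.pixel_size)
    out = np.zeros(spec.image_size, dtype=int)
    outside = d > bead.radius
    out[outside] = np.ceil((d[outside] - bead.radius) / ring_width).astype(int)
    return out


def generate_spheroid_image(
    spec: SynthSpec, *, ring_width: float = 10.0
) -> tuple[CalibratedImage, GroundTruth]:
    """Render one 2D bead+cells scene and its exact ground truth.

    The bead is a bright disc; each cell is a constant-intensity disc or
    square. Cells must lie fully inside the image and, unless
    ``allow_bead_overlap`` is set, clear of the bead interior.
    """
    rng = np.random.default_rng(spec.seed)
    bead = spec.bead
    d_map = bead.distance_map(spec.image_size, spec.pixel_size)

    img = np.full(spec.image_size, spec.background, dtype=float)
    img[d_map <= bead.radius] = spec.bead_intensity

    cell_mask = np.zeros(spec.image_size, dtype=bool)
    truths: list[CellTruth] = []
    for cell in spec.cells:
        _check_in_bounds(cell, spec)
        cx, cy = cell.center
        center_d = float(np.hypot(cx - bead.center_x, cy - bead.center_y) - bead.radius)
        if not spec.allow_bead_overlap and center_d - cell.size < 0:
            raise SynthError(
                f"cell at ({cx:.1f}, {cy:.1f}) μm overlaps the bead interior"
            )
        fp = _render_cell(cell, spec)
        fp &= d_map > bead.radius  # never attribute bead-interior pixels to cells
        img[fp] = cell.intensity
        cell_mask |= fp
        n_px = int(fp.sum())
        edge_d = float(d_map[fp].min() - bead.radius) if n_px else float("nan")
        truths.append(
            CellTruth(
                center=cell.center,
                shape=cell.shape,
                size=cell.size,
                center_distance=center_d,
                edge_distance=edge_d,
                area=n_px * spec.pixel_size ** 2,
                n_pixels=n_px,
            )
        )

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    image = CalibratedImage(
        pixels=img,
        pixel_size=spec.pixel_size,
        axes="yx",
        frame_interval=spec.frame_interval,
    )
    truth = GroundTruth(
        bead=bead,
        pixel_size=spec.pixel_size,
        cells=truths,
        cell_mask=cell_mask,
        ring_assignment=_ring_assignment(spec, ring_width),
        ring_width=ring_width,
        seed=spec.seed,
    )
    return image, truth


def generate_timelapse(
    spec: SynthSpec,
    n_frames: int,
    *,
    linking_radius: Optional[float] = None,
    ring_width: float = 10.0,
) -> tuple[CalibratedImage, list[Track], list[GroundTruth]]:
    """Render a time-lapse of cells translating at constant velocity.

    Positions advance by velocity · Δt per frame (Δt = ``frame_interval``
    minutes). Returns the stacked image (axes ``tyx``), the true tracks,
    and the per-frame ground truths. If ``linking_radius`` is given, cell
    pairs that approach within it in any frame are flagged as ambiguous
    for tracking in each frame's ground truth.
    """
    if n_frames < 2:
        raise SynthError("a time-lapse needs n_frames >= 2")
    dt_h = spec.frame_interval / 60.0

    frames: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    positions = np.array([c.center for c in spec.cells], dtype=float)
    velocities = np.array([c.velocity for c in spec.cells], dtype=float)
    if len(positions) == 0:
        positions = positions.reshape(0, 2)
        velocities = velocities.reshape(0, 2)

    for k in range(n_frames):
        centers_k = positions + velocities * (k * dt_h)
        cells_k = tuple(
            replace(c, center=(float(px), float(py)))
            for c, (px, py) in zip(spec.cells, centers_k)
        )
        for c in cells_k:
            _check_in_bounds(c, spec, frame=k)
        spec_k = replace(spec, cells=cells_k, seed=spec.seed + k)
        img_k, truth_k = generate_spheroid_image(spec_k, ring_width=ring_width)
        if linking_radius is not None and len(centers_k) > 1:
            from scipy.spatial.distance import pdist, squareform

            dm = squareform(pdist(centers_k))
            ii, jj = np.nonzero(np.triu(dm < linking_radius, k=1))
            truth_k.ambiguous_pairs = [(k, int(i), int(j)) for i, j in zip(ii, jj)]
        frames.append(img_k.pixels)
        truths.append(truth_k)

    stack = CalibratedImage(
        pixels=np.stack(frames),
        pixel_size=spec.pixel_size,
        axes="tyx",
        frame_interval=spec.frame_interval,
    )

    tracks: list[Track] = []
    from .tracking import track_statistics

    for i, (c, v) in enumerate(zip(spec.cells, velocities)):
        pos = np.array(
            [np.asarray(c.center, dtype=float) + v * (k * dt_h) for k in range(n_frames)]
        )
        tracks.append(
            track_statistics(
                Track(cell_id=i, frame_indices=np.arange(n_frames), positions=pos),
                frame_interval=spec.frame_interval,
            )
        )
    return stack, tracks, truths


def random_cells(
    n: int,
    spec: SynthSpec,
    *,
    rng: Optional[np.random.Generator] = None,
    size_range: tuple[float, float] = (3.0, 6.0),
    margin: float = 5.0,
    max_distance: Optional[float] = None,
    min_separation: float = 4.0,
    intensity: float = 200.0,
    max_tries: int = 10_000,
) -> tuple[CellSpec, ...]:
    """Place ``n`` non-overlapping disc cells uniformly around the bead.

    Cells land in the annulus from ``bead_radius + margin + size`` out to
    ``max_distance`` (default: the largest radius whose cells stay fully
    in-frame), separated center-to-center by at least the sum of radii plus
    ``min_separation``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    bead = spec.bead
    w = (spec.image_size[1] - 1) * spec.pixel_size
    h = (spec.image_size[0] - 1) * spec.pixel_size
    if max_distance is None:
        max_distance = (
            min(bead.center_x, w - bead.center_x, bead.center_y, h - bead.center_y)
            - size_range[1]
            - 1.0
        )
    placed: list[CellSpec] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise SynthError(f"could not place {n} non-overlapping cells")
        size = float(rng.uniform(*size_range))
        r = float(rng.uniform(bead.radius + margin + size, max_distance))
        theta = float(rng.uniform(0, 2 * np.pi))
        cx = bead.center_x + r * np.cos(theta)
        cy = bead.center_y + r * np.sin(theta)
        if not (size <= cx <= w - size and size <= cy <= h - size):
            continue
        ok = all(
            np.hypot(cx - p.center[0], cy - p.center[1]) >= size + p.size + min_separation
            for p in placed
        )
        if ok:
            placed.append(
                CellSpec(center=(cx, cy), size=size, shape="disc", intensity=intensity)
            )
    return tuple(placed)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the JSON sidecar for a synthetic scene."""
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
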