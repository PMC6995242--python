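"""Shared data model for spheroid invasion quantification.

All spatial quantities are carried in micrometres (μm); conversion from
pixels happens once, at construction, through the ``pixel_size`` of the
source image. Pixel centers sit on integer coordinates with the origin at
the top-left corner, x increasing rightward (columns) and y downward
(rows). Pixels are assumed isotropic in x/y because every read-out here is
radial around the microcarrier bead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "DetectionError",
    "GeometryError",
    "CalibratedImage",
    "BeadCircle",
    "CellMask",
    "RingProfile",
    "MigrationMetrics",
    "Track",
    "GelRecipe",
    "validate_calibration",
    "round_sig",
]


class CalibrationError(ValueError):
    """Missing or physically impossible calibration metadata."""


class DetectionError(RuntimeError):
    """Automatic bead detection failed; a manual circle can be supplied."""


class GeometryError(ValueError):
    """Degenerate or invalid geometry (too few points, concave front, ...)."""


_AXES_ORDER = "tzcyx"


@dataclass
class CalibratedImage:
    """An intensity image (2D frame, z-stack or time-lapse) with physical units.

    Parameters
    ----------
    pixels
        2D–4D array whose axes are named by ``axes`` (a subset of
        ``"tzcyx"`` in that order; ``"yx"`` always present and last).
    pixel_size
        Micrometres per pixel, isotropic in x/y.
    frame_interval
        Minutes between time points, required to convert tracking steps
        into velocities. Optional for still images.
    channel_labels
        Optional channel names when a ``c`` axis is present.
    """

    pixels: np.ndarray
    pixel_size: float
    axes: str = "yx"
    frame_interval: Optional[float] = None
    channel_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        validate_calibration(self)

    # -- axis helpers ------------------------------------------------------
    def axis_index(self, name: str) -> int:
        if name not in self.axes:
            raise ValueError(f"image has no {name!r} axis (axes={self.axes!r})")
        return self.axes.index(name)

    def has_axis(self, name: str) -> bool:
        return name in self.axes

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    # -- unit conversion ---------------------------------------------------
    def px_to_um(self, value):
        return np.asarray(value, dtype=float) * self.pixel_size

    def um_to_px(self, value):
        return np.asarray(value, dtype=float) / self.pixel_size

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) spanned by pixel centers, in μm."""
        ny, nx = self.shape_yx
        return (nx - 1) * self.pixel_size, (ny - 1) * self.pixel_size


def validate_calibration(image: CalibratedImage) -> CalibratedImage:
    """Check the calibration invariants and return the image unchanged."""
    if image.pixel_size is None or not np.isfinite(image.pixel_size) or image.pixel_size <= 0:
        raise CalibrationError(
            f"pixel_size must be a positive μm/pixel value, got {image.pixel_size!r}"
        )
    if image.frame_interval is not None and image.frame_interval <= 0:
        raise CalibrationError(
            f"frame_interval must be positive minutes, got {image.frame_interval!r}"
        )
    axes = image.axes
    if not axes.endswith("yx"):
        raise CalibrationError(f"axes must end with 'yx', got {axes!r}")
    if any(a not in _AXES_ORDER for a in axes) or len(set(axes)) != len(axes):
        raise CalibrationError(f"axes must be a subset of {_AXES_ORDER!r}, got {axes!r}")
    if "".join(a for a in _AXES_ORDER if a in axes) != axes:
        raise CalibrationError(f"axes must be ordered as in {_AXES_ORDER!r}, got {axes!r}")
    if image.pixels.ndim != len(axes):
        raise CalibrationError(
            f"pixels have {image.pixels.ndim} dimensions but axes={axes!r}"
        )
    if any(s < 1 for s in image.pixels.shape):
        raise CalibrationError("every axis must have length >= 1")
    return image


@dataclass(frozen=True)
class BeadCircle:
    """The microcarrier core fitted as a circle, in μm image coordinates.

    This is the reference for every distance: ring radii, migration
    distances and the migration front are all measured from its center.
    """

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise GeometryError(f"bead radius must be > 0, got {self.radius!r}")
        if self.center_x < 0 or self.center_y < 0:
            raise GeometryError(
                f"bead center ({self.center_x}, {self.center_y}) lies outside the image"
            )

    def distance_map(self, shape_yx: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Distance of every pixel center from the bead center, in μm."""
        ny, nx = shape_yx
        y = np.arange(ny) * pixel_size - self.center_y
        x = np.arange(nx) * pixel_size - self.center_x
        return np.hypot(y[:, None], x[None, :])

    def check_inside(self, shape_yx: tuple[int, int], pixel_size: float) -> "BeadCircle":
        w = (shape_yx[1] - 1) * pixel_size
        h = (shape_yx[0] - 1) * pixel_size
        if not (0 <= self.center_x <= w and 0 <= self.center_y <= h):
            raise GeometryError(
                f"bead center ({self.center_x:.1f}, {self.center_y:.1f}) μm "
                f"outside image extent {w:.1f}×{h:.1f} μm"
            )
        return self


@dataclass
class CellMask:
    """Binary mask of cell-positive pixels on a z-projection.

    Bead-interior pixels are always False: cells still sitting on the
    spheroid surface do not count as migrated at distance zero.
    """

    mask: np.ndarray
    pixel_size: float
    bead: BeadCircle
    exclusions: Optional[dict] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size <= 0:
            raise CalibrationError("pixel_size must be positive")
        # enforce the bead-exclusion invariant on construction
        d = self.bead.distance_map(self.mask.shape, self.pixel_size)
        self.mask = self.mask & (d > self.bead.radius)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in μm²."""
        return self.pixel_size ** 2

    def cell_coordinates_um(self) -> np.ndarray:
        """(N, 2) array of (x, y) μm positions of all cell pixels."""
        yy, xx = np.nonzero(self.mask)
        return np.column_stack([xx * self.pixel_size, yy * self.pixel_size])

    def total_area(self) -> float:
        return float(self.mask.sum()) * self.pixel_area


@dataclass
class RingProfile:
    """Cell areas in successive concentric annuli around the bead.

    ``areas[i-1]`` is Area(i): the μm² of cell pixels whose distance d from
    the bead center satisfies r + (i-1)·w < d <= r + i·w, for bead radius r
    and ring width w (default 10 μm). Rings are iterated until the outer
    circle leaves the image; rings clipped by the border are listed in
    ``truncated_rings`` (the first ``n_complete`` rings fit entirely).
    """

    ring_width: float
    areas: np.ndarray
    bead_radius: float
    n_complete: int
    truncated_rings: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ring_width <= 0:
            raise ValueError(f"ring_width must be > 0, got {self.ring_width!r}")
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas < 0).any():
            raise ValueError("ring areas must be non-negative")

    @property
    def n(self) -> int:
        return len(self.areas)

    def inner_radius(self, i: int) -> float:
        return self.bead_radius + (i - 1) * self.ring_width

    def outer_radius(self, i: int) -> float:
        return self.bead_radius + i * self.ring_width

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(1, self.n + 1)
        return pd.DataFrame(
            {
                "ring_index": idx,
                "inner_radius_um": self.bead_radius + (idx - 1) * self.ring_width,
                "outer_radius_um": self.bead_radius + idx * self.ring_width,
                "area_um2": self.areas,
                "truncated_flag": np.isin(idx, self.truncated_rings),
            }
        )

    def to_dict(self) -> dict:
        return {
            "ring_width": self.ring_width,
            "bead_radius": self.bead_radius,
            "n_complete": self.n_complete,
            "truncated_rings": list(self.truncated_rings),
            "areas": self.areas.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RingProfile":
        return cls(
            ring_width=d["ring_width"],
            areas=np.asarray(d["areas"], dtype=float),
            bead_radius=d["bead_radius"],
            n_complete=d["n_complete"],
            truncated_rings=tuple(d.get("truncated_rings", ())),
        )


@dataclass
class MigrationMetrics:
    """The three spatial invasion read-outs for one spheroid at one time.

    ``max_distance`` and ``avg_max_distance`` are in μm; the
    ``migration_index`` carries units μm·μm² (ring weight in μm times cell
    area in μm²) and is reported raw, without normalization.
    """

    max_distance: float
    avg_max_distance: Optional[float]
    migration_index: float
    ring_profile: RingProfile

    def __post_init__(self) -> None:
        if self.migration_index < 0:
            raise ValueError("migration index must be >= 0")

    def to_dict(self) -> dict:
        return {
            "max_distance_um": self.max_distance,
            "avg_max_distance_um": self.avg_max_distance,
            "migration_index_um_um2": self.migration_index,
            "ring_profile": self.ring_profile.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MigrationMetrics":
        return cls(
            max_distance=d["max_distance_um"],
            avg_max_distance=d["avg_max_distance_um"],
            migration_index=d["migration_index_um_um2"],
            ring_profile=RingProfile.from_dict(d["ring_profile"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "MigrationMetrics":
        return cls.from_dict(json.loads(s))


@dataclass
class Track:
    """Time-ordered centroid positions of one cell.

    ``positions`` is an (N, 2) array of (x, y) μm; ``frame_indices`` are the
    0-based frames in which the cell was detected. Per-step statistics are
    filled by :func:`invaquant.tracking.track_statistics` once the frame
    interval is known; velocities are expressed in μm/h.
    """

    cell_id: int
    frame_indices: np.ndarray
    positions: np.ndarray
    times: Optional[np.ndarray] = None  # minutes
    step_distances: Optional[np.ndarray] = None  # μm
    step_velocities: Optional[np.ndarray] = None  # μm/h
    total_path_length: Optional[float] = None
    net_displacement: Optional[float] = None

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.frame_indices) != len(self.positions):
            raise ValueError("frame_indices and positions must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        step = np.full(n, np.nan)
        vel = np.full(n, np.nan)
        if self.step_distances is not None:
            step[1:] = self.step_distances
        if self.step_velocities is not None:
            vel[1:] = self.step_velocities
        t = self.times if self.times is not None else np.full(n, np.nan)
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": self.frame_indices,
                "t_min": t,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "step_dist_um": step,
                "velocity_um_per_h": vel,
            }
        )


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Concatenate per-track step tables into one tracks CSV table."""
    if not tracks:
        return pd.DataFrame(
            columns=[
                "cell_id", "frame", "t_min", "x_um", "y_um",
                "step_dist_um", "velocity_um_per_h",
            ]
        )
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)


@dataclass(frozen=True)
class GelRecipe:
    """A matrix-gel dilution: stock concentration and the mixed volumes.

    ``final_concentration`` follows mass conservation:
    C_final = C_stock · V_stock / V_total with V_total = V_stock + Σ others.
    Units follow the stock (mg/ml for collagen/Matrigel, % w/v for agar).
    """

    name: str
    stock_concentration: float
    stock_volume: float
    other_volumes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.stock_volume <= 0:
            raise ValueError("stock_volume must be > 0")
        if any(v < 0 for _, v in self.other_volumes):
            raise ValueError("component volumes must be >= 0")

    @property
    def total_volume(self) -> float:
        return self.stock_volume + sum(v for _, v in self.other_volumes)

    @property
    def final_concentration(self) -> float:
        return self.stock_concentration * self.stock_volume / self.total_volume

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total_volume"] = self.total_volume
        d["final_concentration"] = self.final_concentration
        d["final_concentration_2sf"] = round_sig(self.final_concentration, 2)
        return d


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
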