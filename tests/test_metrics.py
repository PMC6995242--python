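"""Spatial read-outs: distances, front geometry, ring profile, index."""

import numpy as np
import pytest

from invaquant import (
    CellSpec,
    GeometryError,
    SynthSpec,
    avg_max_migration_distance,
    generate_spheroid_image,
    max_migration_distance,
    migration_index,
    migration_index_pixel_oracle,
    ring_profile,
)
from invaquant.core import BeadCircle, CellMask, RingProfile

from conftest import random_mask, truth_mask

CENTER = 256.0  # grid-aligned bead center for hand-built masks (1 μm/px)
SYNTH_CENTER = 255.5  # bead center of the default 512×512 synthetic scene


def make_mask(points_um, bead=None, shape=(512, 512), pixel_size=1.0):
    """Mask from explicit μm pixel positions (must be grid-aligned)."""
    bead = bead or BeadCircle(CENTER, CENTER, 50.0)
    m = np.zeros(shape, bool)
    for x, y in points_um:
        m[int(round(y / pixel_size)), int(round(x / pixel_size))] = True
    return CellMask(m, pixel_size=pixel_size, bead=bead)


def brute_force_max(mask):
    best = 0.0
    ny, nx = mask.mask.shape
    for j in range(ny):
        for i in range(nx):
            if mask.mask[j, i]:
                d = np.hypot(i * mask.pixel_size - mask.bead.center_x,
                             j * mask.pixel_size - mask.bead.center_y)
                best = max(best, d - mask.bead.radius)
    return best


def convex_hull_perimeter(points):
    """Andrew's monotone-chain hull perimeter — independent of shapely."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) < 3:
        raise ValueError("degenerate")

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    return sum(
        np.hypot(hull[k][0] - hull[k - 1][0], hull[k][1] - hull[k - 1][1])
        for k in range(len(hull))
    )


class TestMaxDistance:
    def test_single_pixel_at_known_distance(self):
        mask = make_mask([(CENTER + 150.0, CENTER)])
        assert max_migration_distance(mask) == pytest.approx(100.0)

    def test_empty_mask_is_zero(self):
        mask = make_mask([])
        assert max_migration_distance(mask) == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            mask = random_mask(rng, shape=(64, 64))
            assert max_migration_distance(mask) == pytest.approx(
                brute_force_max(mask), rel=1e-12
            )


class TestAvgMaxDistance:
    def test_circular_front_equals_radius_difference(self):
        # cells on a circle of radius 150 μm around a 50 μm bead
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = [(CENTER + 150 * np.cos(t), CENTER + 150 * np.sin(t)) for t in theta]
        mask = make_mask(pts)
        assert avg_max_migration_distance(mask) == pytest.approx(100.0, abs=1.0)
        assert max_migration_distance(mask) == pytest.approx(100.0, abs=1.0)

    def test_square_front_closed_form(self):
        # square of side 200 μm centered on the bead: avg-max = 2s/π − r
        s, half = 200.0, 100.0
        edges = np.linspace(-half, half, 201)
        pts = (
            [(CENTER + e, CENTER - half) for e in edges]
            + [(CENTER + e, CENTER + half) for e in edges]
            + [(CENTER - half, CENTER + e) for e in edges]
            + [(CENTER + half, CENTER + e) for e in edges]
        )
        mask = make_mask(pts)
        expected = 2 * s / np.pi - 50.0
        assert avg_max_migration_distance(mask) == pytest.approx(expected, abs=1.0)

    def test_matches_independent_hull_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            mask = random_mask(rng, shape=(80, 80), density=0.03)
            pts = mask.cell_coordinates_um()
            expected = convex_hull_perimeter(pts) / (2 * np.pi) - mask.bead.radius
            assert avg_max_migration_distance(mask) == pytest.approx(expected, rel=1e-9)

    def test_too_few_points_raises(self):
        mask = make_mask([(CENTER + 100, CENTER), (CENTER + 101, CENTER)])
        with pytest.raises(GeometryError, match=">= 3"):
            avg_max_migration_distance(mask)

    def test_collinear_points_raise(self):
        mask = make_mask([(CENTER + 100 + k, CENTER) for k in range(5)])
        with pytest.raises(GeometryError, match="collinear"):
            avg_max_migration_distance(mask)

    def test_user_polygon_convex_accepted_concave_rejected(self):
        mask = make_mask([(CENTER + 100, CENTER)])
        square = [(0, 0), (200, 0), (200, 200), (0, 200)]
        got = avg_max_migration_distance(mask, front=square)
        assert got == pytest.approx(800 / (2 * np.pi) - 50.0, rel=1e-9)
        concave = [(0, 0), (200, 0), (100, 50), (200, 200), (0, 200)]
        with pytest.raises(GeometryError, match="concave"):
            avg_max_migration_distance(mask, front=concave)


class TestRingProfile:
    def test_square_cell_wholly_in_ring_three(self):
        # 10×10 μm square at radial distance 75.5 μm from center: ring 3 covers
        # d ∈ (70, 80]; pixel distances span [70.6, 80.4]... place on the x axis
        spec = SynthSpec(
            seed=0, cells=(CellSpec(center=(SYNTH_CENTER + 75.0, SYNTH_CENTER),
                                    size=5.0, shape="square"),),
        )
        _, truth = generate_spheroid_image(spec)
        profile = ring_profile(truth_mask(truth))
        # pixels at x offsets 70.5..79.5, y offset −4.5..4.5 → d ∈ (70, 80]
        assert profile.areas[2] == 100.0
        assert profile.areas[:2].tolist() == [0.0, 0.0]
        assert profile.areas[3:].sum() == 0.0

    def test_empty_mask_all_zero(self):
        mask = make_mask([])
        profile = ring_profile(mask)
        assert profile.areas.sum() == 0.0
        assert profile.n > 0

    def test_dense_mask_total_area_and_per_ring_oracle(self):
        rng = np.random.default_rng(2)
        mask = random_mask(rng, shape=(100, 100), density=0.35)
        profile = ring_profile(mask)
        assert profile.areas.sum() == pytest.approx(mask.total_area(), rel=1e-12)
        # independent per-pixel binning
        expected = np.zeros(profile.n)
        for j, i in zip(*np.nonzero(mask.mask)):
            d = np.hypot(i - mask.bead.center_x, j - mask.bead.center_y)
            if d > mask.bead.radius:
                ring = int(np.ceil((d - mask.bead.radius) / 10.0))
                expected[ring - 1] += 1.0
        np.testing.assert_array_equal(profile.areas, expected)

    def test_area_bounded_by_annulus_geometry(self):
        rng = np.random.default_rng(3)
        mask = random_mask(rng, shape=(120, 120), density=1.0)  # fully cell-covered
        profile = ring_profile(mask)
        r, w = mask.bead.radius, profile.ring_width
        for i in range(1, profile.n_complete + 1):
            geometric = np.pi * ((r + w * i) ** 2 - (r + w * (i - 1)) ** 2)
            boundary_slack = 2 * np.pi * (r + w * i) * mask.pixel_size
            assert profile.areas[i - 1] <= geometric + boundary_slack

    def test_truncated_rings_flagged_beyond_border(self):
        mask = make_mask([], shape=(201, 201), bead=BeadCircle(100.0, 100.0, 50.0))
        profile = ring_profile(mask)
        # border at 100 μm → 5 complete rings; corners at ~141 μm → rings to 10
        assert profile.n_complete == 5
        assert profile.n == 10
        assert profile.truncated_rings == tuple(range(6, 11))

    def test_bad_ring_width_rejected(self):
        mask = make_mask([])
        with pytest.raises(ValueError):
            ring_profile(mask, ring_width=0.0)


class TestMigrationIndex:
    def _profile(self, areas):
        return RingProfile(ring_width=10.0, areas=np.asarray(areas, float),
                           bead_radius=50.0, n_complete=len(areas))

    def test_single_ring_term(self):
        assert migration_index(self._profile([0, 0, 100])) == 3000.0

    def test_empty_profile_zero(self):
        assert migration_index(self._profile([])) == 0.0

    def test_additive_over_rings(self):
        assert migration_index(self._profile([0, 100, 0, 0, 100])) == 7000.0

    def test_complete_rings_only_drops_truncated(self):
        p = RingProfile(ring_width=10.0, areas=np.array([100.0, 100.0]),
                        bead_radius=50.0, n_complete=1, truncated_rings=(2,))
        with pytest.warns(UserWarning, match="truncated"):
            assert migration_index(p) == 3000.0
        assert migration_index(p, complete_rings_only=True) == 1000.0

    def test_pixel_at_bead_edge_contributes_zero(self):
        mask = make_mask([(CENTER + 50.0, CENTER)])  # d exactly r
        assert migration_index_pixel_oracle(mask) == 0.0

    def test_pixel_mid_first_ring_contributes_one_weight(self):
        mask = make_mask([(CENTER + 55.0, CENTER)])  # d = r + 0.5·w
        assert migration_index_pixel_oracle(mask) == 10.0 * 1 * 1.0

    def test_ring_procedure_equals_pixel_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            mask = random_mask(rng)
            via_rings = migration_index(ring_profile(mask))
            assert via_rings == migration_index_pixel_oracle(mask)


class TestMetricInvariants:
    def test_avg_max_never_exceeds_max(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mask = random_mask(rng, density=0.05)
            if mask.mask.sum() < 3:
                continue
            assert avg_max_migration_distance(mask) <= max_migration_distance(mask) + 1e-9

    def test_index_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(6)
        bead = BeadCircle(48.0, 48.0, 10.0)
        a = rng.random((96, 96)) < 0.05
        b = (rng.random((96, 96)) < 0.05) & ~a
        idx = lambda m: migration_index(
            ring_profile(CellMask(m, pixel_size=1.0, bead=bead))
        )
        assert idx(a) + idx(b) == pytest.approx(idx(a | b), rel=1e-12)

    def test_index_increases_when_pixel_moves_outward(self):
        base = make_mask([(CENTER + 75.0, CENTER)])
        farther = make_mask([(CENTER + 95.0, CENTER)])
        assert migration_index(ring_profile(farther)) > migration_index(
            ring_profile(base)
        )

    def test_translation_invariance_of_all_metrics(self):
        rng = np.random.default_rng(7)
        bead = BeadCircle(40.0, 40.0, 10.0)
        m = np.zeros((128, 128), bool)
        m[30:60, 30:60] = rng.random((30, 30)) < 0.2
        mask = CellMask(m, pixel_size=1.0, bead=bead)
        dy, dx = 21, 13
        shifted = CellMask(
            np.roll(np.roll(m, dy, 0), dx, 1), pixel_size=1.0,
            bead=BeadCircle(40.0 + dx, 40.0 + dy, 10.0),
        )
        assert max_migration_distance(shifted) == pytest.approx(
            max_migration_distance(mask), rel=1e-12)
        assert avg_max_migration_distance(shifted) == pytest.approx(
            avg_max_migration_distance(mask), rel=1e-12)
        assert migration_index(ring_profile(shifted)) == pytest.approx(
            migration_index(ring_profile(mask)), rel=1e-12)

    def test_rotation_invariance_of_all_metrics(self):
        rng = np.random.default_rng(8)
        n = 127  # odd size → exact center pixel
        c = (n - 1) / 2.0
        bead = BeadCircle(c, c, 10.0)
        m = rng.random((n, n)) < 0.05
        mask = CellMask(m, pixel_size=1.0, bead=bead)
        rot = CellMask(np.rot90(m), pixel_size=1.0, bead=bead)
        assert max_migration_distance(rot) == pytest.approx(
            max_migration_distance(mask), rel=1e-12)
        assert avg_max_migration_distance(rot) == pytest.approx(
            avg_max_migration_distance(mask), rel=1e-12)
        assert migration_index(ring_profile(rot)) == pytest.approx(
            migration_index(ring_profile(mask)), rel=1e-12)
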