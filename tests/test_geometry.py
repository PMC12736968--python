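import math

import numpy as np
import pytest

from made import (
    MotionParameters,
    NoArtifactError,
    PSFSpec,
    estimate,
    orientation_error,
    render_object_trail,
)
from made.directions import DIRECTIONS
from made.geometry import (
    PointOctagon,
    SEGMENT_WIDTH_DEG,
    TripletSelection,
    center_of_mass,
    direction_angle,
    directional_stats,
    map_points,
    neighbor_matrix,
    ray_segment_intersection,
    reliability_swap,
    segment_index,
    select_triplet,
    weighted_distance,
)
from made.maq import MAQSet


def maq_of(values, direction="horizontal", n_lines=None, tau=112.0):
    vals = np.asarray(values, dtype=float)
    if n_lines is None:
        n_lines = len(vals)
    evaluated = np.zeros(max(n_lines, len(vals)), dtype=bool)
    evaluated[:n_lines] = True
    padded = np.full(len(evaluated), np.nan)
    padded[: len(vals)] = vals
    return MAQSet(direction, padded, np.zeros(len(padded), bool), evaluated, tau)


def stats_of(h=(), d=(), v=(), a=(), beta=1.0, **kw):
    sets = {name: maq_of(vals, name, **kw)
            for name, vals in zip(DIRECTIONS, (h, d, v, a))}
    return directional_stats(sets, beta=beta)


class TestDirectionalStats:
    def test_constant_values(self):
        st = stats_of(h=[2, 2, 2], d=[1], v=[1], a=[1])
        assert st.means[0] == 2.0 and st.stds[0] == 0.0

    def test_mean_and_boost(self):
        st = stats_of(h=[1, 3], d=[1], v=[1], a=[1], beta=2.0)
        assert st.means[0] == 2.0
        assert st.stds[0] == 1.0          # population std of {1, 3}
        assert st.boosted[0] == 2.0

    def test_mean_weighted_by_line_count(self):
        # 2 detections of 6 px over 4 evaluated scanlines -> mean 3
        st = stats_of(h=[6, 6], d=[1], v=[1], a=[1], n_lines=4)
        assert st.means[0] == 3.0

    def test_empty_direction_lowest_reliability(self):
        st = stats_of(h=[2, 4], d=[3, 5], v=[1, 2], a=[])
        assert st.means[3] == 0.0
        assert st.reliability[3] == st.reliability.min()

    def test_all_empty_raises(self):
        with pytest.raises(NoArtifactError):
            stats_of()


class TestReliabilitySwap:
    def test_reversal(self):
        assert np.array_equal(reliability_swap([4.0, 3.0, 2.0, 1.0]), [1, 2, 3, 4])

    def test_all_equal_unchanged(self):
        assert np.array_equal(reliability_swap([2.0] * 4), [2.0] * 4)

    def test_involution(self, rng):
        for _ in range(100):
            s = rng.random(4)
            assert np.allclose(reliability_swap(reliability_swap(s)), s)

    def test_permutation_of_inputs(self, rng):
        s = rng.random(4)
        assert np.array_equal(np.sort(reliability_swap(s)), np.sort(s))


class TestMapPoints:
    def test_unit_means_layout(self):
        st = stats_of(h=[1, 1], d=[1, 1], v=[1, 1], a=[1, 1])
        st.reliability[:] = 0.0
        pts = map_points(st).points
        expected = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
        assert np.allclose(pts[:, :2], expected)
        assert np.all(pts[:, 2] == 0.0)

    def test_central_reflection(self, rng):
        st = stats_of(h=rng.random(3) * 5, d=rng.random(3) * 5,
                      v=rng.random(3) * 5, a=rng.random(3) * 5)
        pts = map_points(st).points
        for i in range(4):
            assert np.allclose(pts[i + 4, :2], -pts[i, :2])
            assert pts[i + 4, 2] == pts[i, 2]


class TestSelectTriplet:
    def test_equidistant_tie_starts_at_one(self):
        pts = np.array([[math.cos(a), math.sin(a), 0.0]
                        for a in np.linspace(0, 2 * math.pi, 9)[:-1]])
        sel = select_triplet(PointOctagon(pts))
        assert sel.indices == (1, 2, 3)

    def test_dominant_point(self):
        # distances (1,1,1,1,1,10,1,1): three tied sums, smallest start wins
        pts = np.zeros((8, 3))
        pts[:, 0] = 1.0
        pts[5, 0] = 10.0
        sel = select_triplet(PointOctagon(pts))
        assert sel.indices == (4, 5, 6)
        assert sel.total_distance == pytest.approx(12.0)

    def test_matches_bruteforce_on_random_octagons(self, rng):
        for _ in range(1000):
            pts = rng.normal(size=(8, 3))
            sel = select_triplet(PointOctagon(pts))
            d = np.linalg.norm(pts, axis=1)
            sums = [d[i] + d[(i + 1) % 8] + d[(i + 2) % 8] for i in range(8)]
            assert sel.indices[0] - 1 == int(np.argmax(sums))


class TestCenterOfMassAndAngle:
    def test_identical_points(self):
        t = TripletSelection((1, 2, 3), np.tile([2.0, 3.0, 4.0], (3, 1)), 0.0)
        assert np.allclose(center_of_mass(t), [2, 3, 4])

    def test_mean_and_translation_equivariance(self, rng):
        pts = rng.normal(size=(3, 3))
        t = TripletSelection((1, 2, 3), pts, 0.0)
        shift = rng.normal(size=3)
        t2 = TripletSelection((1, 2, 3), pts + shift, 0.0)
        assert np.allclose(center_of_mass(t2), center_of_mass(t) + shift)
        assert np.allclose(center_of_mass(t), pts.mean(axis=0))

    @pytest.mark.parametrize(
        "c, theta",
        [((1, 0), 0.0), ((0, 1), 90.0), ((-1, -1), 225.0), ((-1, 0), 180.0),
         ((0, -1), 270.0), ((1, 1), 45.0)],
    )
    def test_quadrant_table(self, c, theta):
        got, comp = direction_angle(np.array([*c, 0.5]))
        assert got == pytest.approx(theta)
        assert comp == pytest.approx((theta + 180) % 360)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            direction_angle(np.array([0.0, 0.0, 1.0]))


class TestNeighborMatrixAndSegments:
    def test_edges_closed_polygon(self, rng):
        pts = rng.normal(size=(8, 3))
        edges = neighbor_matrix(PointOctagon(pts))
        assert edges.shape == (8, 6)
        assert np.allclose(edges[-1, 3:], pts[0])
        starts = [tuple(e[:3]) for e in edges]
        ends = [tuple(e[3:]) for e in edges]
        for p in map(tuple, pts):
            assert starts.count(p) == 1 and ends.count(p) == 1

    @pytest.mark.parametrize("theta, iota", [(0, 1), (44.9, 1), (45, 2), (100, 3),
                                             (359.9, 8), (360, 1)])
    def test_segment_index(self, theta, iota):
        assert segment_index(theta) == iota

    def test_segment_width(self):
        assert SEGMENT_WIDTH_DEG == 45.0


class TestRaySegmentIntersection:
    def test_straight_crossing(self):
        point, s = ray_segment_intersection(0.0, np.array([2, -1, 0.5, 2, 1, 0.5]))
        assert np.allclose(point, [2, 0, 0.5])
        assert s == pytest.approx(0.5)

    def test_parallel_fallback_midpoint(self):
        point, s = ray_segment_intersection(0.0, np.array([1, 1, 0, 3, 1, 0]))
        assert np.allclose(point, [2, 1, 0])
        assert s == 0.5

    def test_clamped_to_segment_start(self):
        point, s = ray_segment_intersection(0.0, np.array([2, 1, 0, 2, 3, 0]))
        assert s == 0.0
        assert np.allclose(point, [2, 1, 0])

    def test_dense_sampling_oracle(self, rng):
        # the returned point lies on the segment, on the ray (when the ray
        # genuinely crosses), and matches a dense scan of the segment
        hits = 0
        while hits < 200:
            theta = rng.uniform(0, 360)
            start = rng.normal(size=3) * 5
            end = rng.normal(size=3) * 5
            edge = np.concatenate([start, end])
            point, s = ray_segment_intersection(theta, edge)
            # on-edge identity holds exactly, clamped or not
            assert np.allclose(point, start + s * (end - start))
            d = np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
            det = d[0] * -(end[1] - start[1]) - d[1] * -(end[0] - start[0])
            if abs(det) < 1e-10 or not (0 < s < 1):
                continue
            t_along = point[:2] @ d
            if t_along < 0:
                continue  # intersection behind the ray origin; not a crossing
            hits += 1
            # perpendicular distance of the intersection from the ray line
            assert abs(point[0] * d[1] - point[1] * d[0]) < 1e-9
            # dense scan: nearest sampled segment point to the ray line
            ts = np.linspace(0, 1, 10_000)
            samples = start[None, :2] + ts[:, None] * (end - start)[None, :2]
            dist = np.abs(samples[:, 0] * d[1] - samples[:, 1] * d[0])
            best = samples[int(np.argmin(dist))]
            assert np.linalg.norm(point[:2] - best) < np.linalg.norm(end - start) / 5000


class TestWeightedDistance:
    def test_pythagorean(self):
        assert weighted_distance(np.array([3.0, 4.0, 0.0])) == 5.0
        assert weighted_distance(np.zeros(3)) == 0.0

    def test_xy_rotation_invariant(self, rng):
        p = rng.normal(size=3)
        ang = rng.uniform(0, 2 * math.pi)
        rot = np.array([p[0] * math.cos(ang) - p[1] * math.sin(ang),
                        p[0] * math.sin(ang) + p[1] * math.cos(ang), p[2]])
        assert weighted_distance(rot) == pytest.approx(weighted_distance(p))

    def test_q_bounded_by_octagon_radii(self):
        # equal reliabilities, all means positive: q within vertex radii for any theta
        st = stats_of(h=[4, 4], d=[2, 2], v=[3, 3], a=[1, 1])
        st.reliability[:] = 1.0
        octagon = map_points(st)
        edges = neighbor_matrix(octagon)
        radii = np.linalg.norm(octagon.points, axis=1)
        for theta in np.arange(0.0, 360.0, 3.6):
            point, _ = ray_segment_intersection(theta, edges[segment_index(theta) - 1])
            q = weighted_distance(point)
            assert radii.min() - 1e-9 <= q <= radii.max() + 1e-9


class TestEstimateEndToEnd:
    def test_static_frame_no_artifact(self, static_frame):
        with pytest.raises(NoArtifactError):
            estimate(static_frame.intensities)

    def test_vertical_motion_recovered(self):
        f = render_object_trail(MotionParameters(v=0.24, phi=90.0), PSFSpec())
        est = estimate(f.intensities)
        assert orientation_error(est.theta, 90.0) <= 15.0
        assert est.theta_complement == pytest.approx((est.theta + 180) % 360)
        assert est.q > 0

    def test_rotation_equivariance_single_frame(self, moving_frame):
        e1 = estimate(moving_frame.intensities)
        e2 = estimate(np.rot90(moving_frame.intensities))
        assert orientation_error(e2.theta, (e1.theta + 90) % 360) <= 10.0

    def test_deterministic(self, moving_frame):
        a = estimate(moving_frame.intensities)
        b = estimate(moving_frame.intensities)
        assert a.theta == b.theta and a.q == b.q
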