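"""Vanishing-line filtering, vanishing-point estimation, grid construction."""

import math

import numpy as np
import pytest

from reefwarp.config import PipelineConfig
from reefwarp.errors import NoCandidateLinesError, NoVanishingPointError
from reefwarp.geometry import Line, LineSegment, perpendicular_distance
from reefwarp.grid import (
    build_perspective_grid,
    candidate_vanishing_points,
    detect_line_segments,
    extend_segment,
    filter_candidate_lines,
    overall_vanishing_point,
    select_vanishing_line,
)
from reefwarp.horizon import EdgeMap, HorizonLine, build_edge_map


def seg(x0, y0, x1, y1):
    return LineSegment((float(x0), float(y0)), (float(x1), float(y1)))


@pytest.fixture
def horizon():
    return HorizonLine(Line(0.0, 400.0))


class TestDetectLineSegments:
    def test_single_drawn_line_recovered(self):
        img = np.zeros((600, 800), dtype=np.uint8)
        # 200-px line at ~40 degrees
        for t in np.linspace(0, 1, 400):
            x = int(300 + t * 153)
            y = int(200 + t * 128)
            img[y - 1: y + 2, x - 1: x + 2] = 255
        edges = build_edge_map(img, "standard")
        segs = detect_line_segments(edges)
        target = math.degrees(math.atan2(128, 153))
        assert any(abs(s.angle_deg - target) < 2.0 for s in segs)

    def test_empty_map_empty_list(self):
        e = EdgeMap(np.zeros((100, 100), bool), "standard")
        assert detect_line_segments(e) == []

    def test_reef_texture_yields_many_segments(self, t1_scene):
        img, gt = t1_scene
        edges = build_edge_map(img, "standard")
        edges.data[: int(gt.horizon.intercept)] = False
        assert len(detect_line_segments(edges)) >= 50


class TestFilterCandidateLines:
    def test_horizontal_removed(self, horizon):
        segs = [seg(100, 500, 300, 500), seg(100, 700, 300, 500), seg(900, 700, 1100, 900)]
        left, right = filter_candidate_lines(segs, horizon, 1200, 900)
        assert all(abs(s.angle_deg) >= 10 for s in left + right)

    def test_sign_rule(self, horizon):
        # right-half segment with negative slope must be dropped
        segs = [
            seg(100, 700, 300, 500),   # left, negative slope: kept
            seg(900, 500, 1100, 700),  # right, positive slope: kept
            seg(900, 700, 1100, 500),  # right, negative slope: dropped
        ]
        left, right = filter_candidate_lines(segs, horizon, 1200, 900)
        assert len(left) == 1 and len(right) == 1
        assert right[0].slope > 0

    def test_balanced_downsampling_deterministic(self, horizon):
        rng = np.random.default_rng(0)
        lefts = [seg(x, 700, x + 100, 550) for x in rng.uniform(0, 400, 40)]
        rights = [seg(x, 550, x + 100, 700) for x in rng.uniform(700, 1000, 10)]
        l1, r1 = filter_candidate_lines(lefts + rights, horizon, 1200, 900, seed=5)
        l2, r2 = filter_candidate_lines(lefts + rights, horizon, 1200, 900, seed=5)
        assert len(l1) == len(r1) == 10
        assert [s.p1 for s in l1] == [s.p1 for s in l2]

    def test_empty_side_raises(self, horizon):
        with pytest.raises(NoCandidateLinesError):
            filter_candidate_lines([seg(100, 700, 300, 500)], horizon, 1200, 900)


class TestCandidateVanishingPoints:
    def test_constructed_crossing_on_horizon(self, horizon):
        # two lines meeting exactly at (600, 400)
        left = [seg(200, 700, 600, 400)]
        right = [seg(600, 400, 1000, 700)]
        pts = candidate_vanishing_points(left, right, horizon, 1200, 900)
        assert len(pts) == 1
        assert pts[0][0] == pytest.approx(600)
        assert pts[0][1] == pytest.approx(400)

    def test_parallel_pair_contributes_nothing(self, horizon):
        left = [seg(200, 700, 400, 500)]
        right = [seg(800, 100, 1000, -100)]  # parallel (slope -1 both)
        with pytest.raises(NoVanishingPointError):
            candidate_vanishing_points(left, right, horizon, 1200, 900)

    def test_survivors_satisfy_window_predicates(self, horizon):
        rng = np.random.default_rng(2)
        left = [seg(x, 700, x + 150, 550) for x in rng.uniform(0, 400, 15)]
        right = [seg(x, 550, x + 150, 700) for x in rng.uniform(650, 950, 15)]
        cfg = PipelineConfig()
        try:
            pts = candidate_vanishing_points(left, right, horizon, 1200, 900, cfg)
        except NoVanishingPointError:
            pytest.skip("no intersections under this draw")
        for x, y in pts:
            assert abs(y - 400.0) <= 0.01 * 900
            assert 0.375 * 1200 <= x <= 0.625 * 1200


class TestOverallVanishingPoint:
    def test_single_candidate(self):
        assert overall_vanishing_point([(3.0, 4.0)]) == (3.0, 4.0)

    def test_symmetric_pair(self):
        assert overall_vanishing_point([(10, 20), (30, 40)]) == (20.0, 30.0)

    def test_empty_raises(self):
        with pytest.raises(NoVanishingPointError):
            overall_vanishing_point([])


class TestSelectVanishingLine:
    def test_collinear_segment_wins(self):
        vp = (600.0, 400.0)
        on_line = seg(700, 500, 800, 600)       # collinear with vp (slope 1)
        off_line = seg(700, 520, 800, 640)
        winner = select_vanishing_line([off_line, on_line], vp, 450)
        assert perpendicular_distance(winner, vp) < 1e-9

    def test_distances_match_closed_form(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p1, p2, q = rng.uniform(0, 1000, (3, 2))
            if np.allclose(p1, p2):
                continue
            s = LineSegment(tuple(p1), tuple(p2))
            a = p2[1] - p1[1]
            b = p1[0] - p2[0]
            c = p2[0] * p1[1] - p1[0] * p2[1]
            expect = abs(a * q[0] + b * q[1] + c) / math.hypot(a, b)
            assert perpendicular_distance(s, tuple(q)) == pytest.approx(expect)

    def test_short_winner_extended_to_minimum_length(self):
        vp = (600.0, 400.0)
        short = seg(700, 500, 850, 650)  # length ~212
        winner = select_vanishing_line([short], vp, 450)
        assert winner.length == pytest.approx(500.0)
        assert winner.midpoint == pytest.approx(short.midpoint)
        assert winner.angle_deg == pytest.approx(short.angle_deg)

    def test_above_index_excluded(self):
        vp = (600.0, 400.0)
        high = seg(650, 420, 700, 470)  # midpoint y=445 above index 500
        from reefwarp.errors import NoVanishingLineError

        with pytest.raises(NoVanishingLineError):
            select_vanishing_line([high], vp, 500)


class TestBuildPerspectiveGrid:
    def test_horizontal_line_through_midpoint(self):
        v = seg(300, 520, 700, 320)
        grid = build_perspective_grid(v, 1200, (500.0, 200.0))
        assert grid.horizontal_line.p1 == (0.0, 420.0)
        assert grid.horizontal_line.p2 == (1200.0, 420.0)
        assert grid.vanishing_line.midpoint[1] == pytest.approx(420.0)

    def test_grid_angle_acute_before_transform(self):
        v = seg(300, 520, 700, 320)
        grid = build_perspective_grid(v, 1200, (500.0, 200.0))
        ang = abs(grid.vanishing_line.angle_deg - grid.horizontal_line.angle_deg)
        assert 0 < ang < 90

    def test_extend_noop_when_long_enough(self):
        s = seg(0, 0, 600, 600)
        assert extend_segment(s, 500) is s
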