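"""Counting frame, point grid, and test-line probes against brute-force
geometric oracles and known expectations."""

import numpy as np
import pytest

from stereocap import (
    CountingFrame,
    count_frame,
    count_grid_hits_profiles,
    count_grid_hits_region,
    count_line_intersections,
    generate_region,
    make_point_grid,
    make_test_lines,
)
from stereocap.probes import CountRecord, PointGrid, counts_from_csv, counts_to_csv
from stereocap.sectioning import ProfileSet
from stereocap import _geometry as geo

from conftest import (
    ellipse_polygon,
    oracle_frame_count,
    oracle_point_inside,
    oracle_segment_crossings,
    random_profiles,
)


def one_profile(cx, cy, a, b, theta=0.0, capillary=True):
    return ProfileSet(
        center=np.array([[cx, cy]]),
        semi_minor_mm=np.array([b]),
        semi_major_mm=np.array([a]),
        angle_rad=np.array([theta]),
        parent_index=np.array([0]),
        parent_diameter_um=np.array([2000.0 * b]),
        is_capillary=np.array([capillary]),
    )


# ---------------------------------------------------------------------------
# Point grid over the region (Cavalieri stage)
# ---------------------------------------------------------------------------


class TestRegionGrid:
    def test_expected_hits_equal_area_over_ap(self, rng):
        """1 mm^2 cross-section, spacing 0.1 mm: E[hits] = 100."""
        reg = generate_region((1.0, 1.0, 1.0))
        hits = [
            count_grid_hits_region(make_point_grid(0.1, rng), reg, cut_z=0.5)
            for _ in range(400)
        ]
        assert np.mean(hits) == pytest.approx(100.0, rel=0.02)

    def test_plane_outside_region_scores_zero(self, rng):
        reg = generate_region((1.0, 1.0, 1.0))
        assert count_grid_hits_region(make_point_grid(0.1, rng), reg, cut_z=2.0) == 0

    def test_offset_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            PointGrid(spacing_mm=0.1, offset=(0.2, 0.0))


# ---------------------------------------------------------------------------
# Counting frame
# ---------------------------------------------------------------------------


FRAME = CountingFrame(rect=(0.0, 0.0, 0.05, 0.05))
FRAME_SIMPLE = CountingFrame(rect=(0.0, 0.0, 0.05, 0.05), rule="paper_simple")


class TestCountingFrame:
    def test_profile_wholly_inside_is_counted(self):
        assert count_frame(one_profile(0.025, 0.025, 2e-3, 2e-3), FRAME) == 1

    def test_profile_touching_left_forbidden_edge_rejected(self):
        # overlaps the left (prohibiting) edge
        assert count_frame(one_profile(0.0, 0.025, 2e-3, 2e-3), FRAME) == 0
        assert count_frame(one_profile(0.0, 0.025, 2e-3, 2e-3), FRAME_SIMPLE) == 0

    def test_profile_touching_bottom_forbidden_edge_rejected(self):
        assert count_frame(one_profile(0.025, -1e-3, 2e-3, 2e-3), FRAME) == 0

    def test_profile_touching_top_inclusion_edge_counted(self):
        assert count_frame(one_profile(0.025, 0.05, 2e-3, 2e-3), FRAME) == 1

    def test_profile_touching_right_inclusion_edge_counted(self):
        assert count_frame(one_profile(0.051, 0.025, 2e-3, 2e-3), FRAME) == 1

    def test_profile_outside_frame_not_counted(self):
        assert count_frame(one_profile(0.2, 0.2, 2e-3, 2e-3), FRAME) == 0

    def test_non_capillary_profile_excluded(self):
        big = one_profile(0.025, 0.025, 6e-3, 6e-3, capillary=False)
        assert count_frame(big, FRAME) == 0

    def test_rules_disagree_only_on_extension_contact(self):
        """A profile overlapping the top-left corner from above-left touches
        the upward extension of the left edge: counted by the simple
        top/right rule, rejected by the full forbidden-line rule."""
        field = (-0.05, -0.05, 0.1, 0.1)
        # thin tilted ellipse dipping into the frame near the top-left
        # corner while its tail crosses x = 0 only above y = 0.05
        p = one_profile(0.004343, 0.050027, 9.144e-3, 1.034e-3, theta=-0.5433)
        assert count_frame(p, FRAME_SIMPLE, field=field) == 1
        assert count_frame(p, FRAME, field=field) == 0

    def test_rules_agree_for_small_interior_profiles(self, rng):
        ps = random_profiles(rng, 400, span=0.1)
        field = (-0.12, -0.12, 0.12, 0.12)
        # kill profiles near the corner-extension zones to force agreement
        for _ in range(50):
            fr_rect = tuple(rng.uniform(-0.06, 0.0, size=2)) + (0.0, 0.0)
            fr_rect = (fr_rect[0], fr_rect[1], fr_rect[0] + 0.05, fr_rect[1] + 0.05)
            full = CountingFrame(rect=fr_rect)
            simple = CountingFrame(rect=fr_rect, rule="paper_simple")
            nf = count_frame(ps, full, field=field)
            nsim = count_frame(ps, simple, field=field)
            assert nf <= nsim  # full rule is strictly more restrictive

    def test_poisson_intensity_recovered_by_both_rules(self, rng):
        """E[count per frame] = profile intensity x frame area for Poisson
        profiles, under either counting rule (tiny profiles)."""
        ps = random_profiles(rng, 4000, span=1.0)  # intensity 1000 per mm^2
        intensity = 4000 / 4.0
        for rule in ("gundersen_full", "paper_simple"):
            q, a = 0, 0.0
            for _ in range(4000):
                fc = rng.uniform(-0.8, 0.8, size=2)
                fr = CountingFrame(
                    rect=(fc[0], fc[1], fc[0] + 0.05, fc[1] + 0.05), rule=rule
                )
                field = (fc[0] - 0.05, fc[1] - 0.05, fc[0] + 0.1, fc[1] + 0.1)
                q += count_frame(ps, fr, field=field)
                a += fr.area_mm2
            assert q / a == pytest.approx(intensity, rel=0.03)


# ---------------------------------------------------------------------------
# Grid points over profiles
# ---------------------------------------------------------------------------


class TestProfileGrid:
    def test_node_at_profile_center_scores(self):
        grid = PointGrid(spacing_mm=0.01, offset=(0.0, 0.0))
        ps = one_profile(0.0, 0.0, 2e-3, 1e-3, theta=0.7)
        p_cap, p_ref = count_grid_hits_profiles(grid, ps, (-0.05, -0.05, 0.05, 0.05))
        assert p_cap >= 1

    def test_no_profiles_scores_zero_over_reference(self):
        grid = PointGrid(spacing_mm=0.01, offset=(0.0, 0.0))
        empty = one_profile(0, 0, 1e-3, 1e-3).subset(np.array([False]))
        p_cap, p_ref = count_grid_hits_profiles(grid, empty, (0.0, 0.0, 0.1, 0.1))
        assert p_cap == 0
        assert p_ref == 11 * 11

    def test_area_fraction_recovered(self, rng):
        """E[P_cap / P_ref] equals the profile area fraction of the field
        (shapely union as the area oracle)."""
        ps = random_profiles(rng, 60, span=0.05)
        field = (-0.05, -0.05, 0.05, 0.05)
        import shapely.geometry as sgeom
        from shapely.ops import unary_union

        polys = [
            ellipse_polygon(ps.center[i, 0], ps.center[i, 1],
                            ps.semi_major_mm[i], ps.semi_minor_mm[i], ps.angle_rad[i])
            for i in range(len(ps))
        ]
        frac_true = unary_union(polys).intersection(
            sgeom.box(*field)
        ).area / sgeom.box(*field).area
        pc, pr = 0, 0
        for _ in range(3000):
            grid = make_point_grid(0.002, rng)
            a, b = count_grid_hits_profiles(grid, ps, field)
            pc += a
            pr += b
        assert pc / pr == pytest.approx(frac_true, rel=0.03)

    def test_invariant_under_lattice_translation(self):
        """Shifting the grid offset by a full spacing leaves every
        profile-hit count unchanged (systematic uniform randomness)."""
        ps = one_profile(0.0123, -0.0077, 2.3e-3, 1.1e-3, theta=0.4)
        field = (-0.05, -0.05, 0.05, 0.05)
        g0 = PointGrid(spacing_mm=0.002, offset=(0.0005, 0.0015))
        nodes0 = g0.nodes_in_rect((-0.03, -0.03, 0.05, 0.05))
        shifted = nodes0 + np.array([0.002, 0.002])
        inside0 = geo.points_in_ellipses(
            nodes0, ps.center[:, 0], ps.center[:, 1],
            ps.semi_major_mm, ps.semi_minor_mm, ps.angle_rad,
        ).sum()
        inside1 = geo.points_in_ellipses(
            shifted, ps.center[:, 0], ps.center[:, 1],
            ps.semi_major_mm, ps.semi_minor_mm, ps.angle_rad,
        ).sum()
        assert inside0 == inside1


# ---------------------------------------------------------------------------
# Test lines
# ---------------------------------------------------------------------------


class TestLines:
    def test_segment_through_circle_counts_two(self):
        ps = one_profile(0.0, 0.0, 5e-3, 5e-3)
        n = geo.segment_boundary_crossings(
            np.array([-0.02, 0.0]), np.array([0.02, 0.0]),
            ps.center[:, 0], ps.center[:, 1],
            ps.semi_major_mm, ps.semi_minor_mm, ps.angle_rad,
        )
        assert n[0] == 2

    def test_segment_inside_ellipse_counts_zero(self):
        ps = one_profile(0.0, 0.0, 5e-3, 5e-3)
        n = geo.segment_boundary_crossings(
            np.array([-1e-3, 0.0]), np.array([1e-3, 0.0]),
            ps.center[:, 0], ps.center[:, 1],
            ps.semi_major_mm, ps.semi_minor_mm, ps.angle_rad,
        )
        assert n[0] == 0

    def test_tangent_counts_once(self):
        ps = one_profile(0.0, 0.0, 5e-3, 5e-3)
        n = geo.segment_boundary_crossings(
            np.array([-0.02, 5e-3]), np.array([0.02, 5e-3]),
            ps.center[:, 0], ps.center[:, 1],
            ps.semi_major_mm, ps.semi_minor_mm, ps.angle_rad,
        )
        assert n[0] == 1

    def test_chord_endpoint_inside_counts_once(self):
        ps = one_profile(0.0, 0.0, 5e-3, 5e-3)
        n = geo.segment_boundary_crossings(
            np.array([0.0, 0.0]), np.array([0.02, 0.0]),
            ps.center[:, 0], ps.center[:, 1],
            ps.semi_major_mm, ps.semi_minor_mm, ps.angle_rad,
        )
        assert n[0] == 1

    def test_total_length_matches_field_tiling(self, rng):
        """Parallel lines at spacing d in a field of area F have expected
        total length F/d."""
        field = (0.0, 0.0, 1.0, 1.0)
        tot = np.mean(
            [make_test_lines(field, 0.1, rng).total_length_mm for _ in range(600)]
        )
        assert tot == pytest.approx(10.0, rel=0.02)

    def test_expected_intersections_with_circle(self, rng):
        """A circle of radius r meets 2r/d of the parallel lines at spacing
        d, each crossing twice: E[I] = 4 r / d, whatever the orientation."""
        ps = one_profile(0.5, 0.5, 0.05, 0.05)
        tot = 0
        n_rep = 3000
        for _ in range(n_rep):
            lines = make_test_lines((0.0, 0.0, 1.0, 1.0), 0.1, rng)
            i, _ = count_line_intersections(lines, ps)
            tot += i
        assert tot / n_rep == pytest.approx(4 * 0.05 / 0.1, rel=0.05)


# ---------------------------------------------------------------------------
# Exact geometry vs polygonal brute force
# ---------------------------------------------------------------------------


class TestAgainstPolygonalOracle:
    def test_frame_decisions_match_oracle(self, rng):
        for _ in range(150):
            ps = random_profiles(rng, 8, span=0.08, r_um=(3.0, 30.0))
            fc = rng.uniform(-0.04, 0.0, size=2)
            frame = CountingFrame(rect=(fc[0], fc[1], fc[0] + 0.05, fc[1] + 0.05))
            field = (-0.12, -0.12, 0.12, 0.12)
            assert count_frame(ps, frame, field=field) == oracle_frame_count(
                ps, frame, field=field
            )

    def test_point_membership_matches_oracle(self, rng):
        for _ in range(200):
            cx, cy = rng.uniform(-1, 1, size=2)
            a = rng.uniform(0.05, 0.5)
            b = rng.uniform(0.01, 1.0) * a
            th = rng.uniform(0, np.pi)
            px, py = rng.uniform(-1.5, 1.5, size=2)
            mine = geo.points_in_ellipses(
                np.array([[px, py]]), np.array([cx]), np.array([cy]),
                np.array([a]), np.array([b]), np.array([th]),
            )[0, 0]
            assert bool(mine) == oracle_point_inside(px, py, cx, cy, a, b, th)

    def test_segment_crossings_match_oracle(self, rng):
        for _ in range(200):
            cx, cy = rng.uniform(-0.5, 0.5, size=2)
            a = rng.uniform(0.05, 0.5)
            b = rng.uniform(0.05, 1.0) * a
            th = rng.uniform(0, np.pi)
            p0 = rng.uniform(-1, 1, size=2)
            p1 = rng.uniform(-1, 1, size=2)
            mine = geo.segment_boundary_crossings(
                p0, p1, np.array([cx]), np.array([cy]),
                np.array([a]), np.array([b]), np.array([th]),
            )[0]
            assert mine == oracle_segment_crossings(p0, p1, cx, cy, a, b, th)


# ---------------------------------------------------------------------------
# Count records CSV boundary
# ---------------------------------------------------------------------------


class TestCountsCSV:
    def test_round_trip(self, tmp_path):
        recs = [
            CountRecord("a1", "wild_type", "s0", 0, "frame_q", 3, probe_area_mm2=2.5e-3),
            CountRecord("a1", "wild_type", "s0", 0, "line_i", 5, probe_length_mm=0.32),
        ]
        path = tmp_path / "counts.csv"
        counts_to_csv(recs, path)
        df = counts_from_csv(path)
        assert len(df) == 2
        assert df["count"].tolist() == [3, 5]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal,count\na1,3\n")
        with pytest.raises(ValueError, match="missing columns"):
            counts_from_csv(path)
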