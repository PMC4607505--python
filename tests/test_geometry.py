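"""Geometry types, file I/O, interpolation and spatial queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import karyosim.geometry as geo
from karyosim.exceptions import (
    DegenerateGeometryError,
    GeometryFormatError,
    GeometryTooNarrowError,
    GeometryValidationError,
    TimeRangeError,
)
from oracle_utils import GridOracle, to_meridional


def make_series(times, bridge_widths=None):
    frames = []
    for i, t in enumerate(times):
        bw = 0.4 if bridge_widths is None else bridge_widths[i]
        frames.append(
            geo.GeometryFrame.from_extents(t, 2.0, 1.6, 1.0, 0.8, 1.0, bw)
        )
    return geo.GeometrySeries(cell_id="c1", frames=tuple(frames))


class TestFrameConstruction:
    def test_halving_and_tip_contact(self, asymmetric_frame):
        f = asymmetric_frame
        assert f.mother.semi_long == 1.0
        assert f.mother.semi_equatorial == 0.8
        assert f.bridge.half_length == 0.5
        assert f.bridge.radius == 0.2
        assert f.mother.center_x == -1.5
        assert f.daughter.center_x == 1.0

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(GeometryValidationError):
            geo.SpheroidSpec(center_x=-1.0, semi_long=0.0, semi_equatorial=0.5)
        with pytest.raises(GeometryValidationError):
            geo.BridgeSpec(half_length=-0.1, radius=0.2)

    def test_broken_tip_contact_rejected(self):
        with pytest.raises(GeometryValidationError):
            geo.GeometryFrame(
                time=0.0,
                mother=geo.SpheroidSpec(-2.0, 1.0, 0.8),
                daughter=geo.SpheroidSpec(1.0, 0.5, 0.4),
                bridge=geo.BridgeSpec(0.5, 0.2),
            )

    def test_duplicate_times_rejected(self):
        with pytest.raises(GeometryValidationError):
            make_series([0.0, 30.0, 30.0])

    def test_series_needs_two_frames(self, asymmetric_frame):
        with pytest.raises(GeometryValidationError):
            geo.GeometrySeries(cell_id="x", frames=(asymmetric_frame,))


class TestFileIO:
    def test_round_trip_identity(self, tmp_path):
        series = make_series([0.0, 30.0, 60.0], bridge_widths=[0.4, 0.3, 0.2])
        path = tmp_path / "geom.csv"
        geo.write_geometry_series(series, path)
        back = geo.load_geometry_series(path)
        assert back.cell_id == series.cell_id
        for a, b in zip(series.frames, back.frames):
            assert a == b

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "cell_id,time_s,mother_length_um,mother_width_um,"
            "daughter_length_um,daughter_width_um,bridge_length_um\n"
            "c,0,2.0,1.6,1.0,0.8,1.0\n"
        )
        with pytest.raises(GeometryFormatError, match="bridge_width_um"):
            geo.load_geometry_series(path)

    def test_nonpositive_dimension_rejected(self, tmp_path):
        series = make_series([0.0, 30.0])
        path = tmp_path / "geom.csv"
        geo.write_geometry_series(series, path)
        txt = path.read_text().replace("0.4", "-0.4")
        path.write_text(txt)
        with pytest.raises(GeometryValidationError):
            geo.load_geometry_series(path)

    def test_multi_cell_table(self, tmp_path):
        s1 = make_series([0.0, 30.0])
        s2 = geo.GeometrySeries(cell_id="c2", frames=s1.frames)
        path = tmp_path / "geom.csv"
        geo.write_geometry_series([s1, s2], path)
        table = geo.load_geometry_table(path)
        assert sorted(table) == ["c1", "c2"]
        with pytest.raises(GeometryFormatError):
            geo.load_geometry_series(path)  # ambiguous without cell_id
        assert geo.load_geometry_series(path, cell_id="c2").cell_id == "c2"


class TestFrameAt:
    def test_stored_time_is_exact(self):
        series = make_series([0.0, 30.0], bridge_widths=[0.8, 0.4])
        assert geo.frame_at(series, 0.0) == series.frames[0]
        assert geo.frame_at(series, 30.0) == series.frames[1]

    @pytest.mark.parametrize(
        "t,expected_radius", [(15.0, 0.3), (7.5, 0.35)]
    )
    def test_linear_interpolation(self, t, expected_radius):
        series = make_series([0.0, 30.0], bridge_widths=[0.8, 0.4])
        f = geo.frame_at(series, t)
        assert f.bridge.radius == pytest.approx(expected_radius, abs=1e-12)

    def test_convex_combination_of_all_parameters(self):
        f0 = geo.GeometryFrame.from_extents(0.0, 2.0, 1.6, 0.6, 0.5, 0.8, 0.5)
        f1 = geo.GeometryFrame.from_extents(30.0, 1.8, 1.5, 1.4, 1.1, 2.0, 0.3)
        series = geo.GeometrySeries(cell_id="c", frames=(f0, f1))
        t, w = 12.0, 12.0 / 30.0
        f = geo.frame_at(series, t)
        for attr in ("semi_long", "semi_equatorial"):
            for lobe in ("mother", "daughter"):
                a = getattr(getattr(f0, lobe), attr)
                b = getattr(getattr(f1, lobe), attr)
                assert getattr(getattr(f, lobe), attr) == pytest.approx(
                    (1 - w) * a + w * b
                )
        assert f.bridge.half_length == pytest.approx(
            (1 - w) * 0.4 + w * 1.0
        )
        # centres re-derived from tip contact after interpolation
        assert f.mother.center_x == pytest.approx(
            -(f.bridge.half_length + f.mother.semi_long)
        )

    def test_out_of_span_raises(self):
        series = make_series([0.0, 30.0])
        with pytest.raises(TimeRangeError):
            geo.frame_at(series, -1.0)
        with pytest.raises(TimeRangeError):
            geo.frame_at(series, 31.0)


class TestClearanceContains:
    def test_mother_center_clearance(self, asymmetric_frame):
        # nearest surface of the mother spheroid is its equator (0.8 um);
        # the other primitives are farther from the mother centre
        assert geo.clearance(asymmetric_frame, (-1.5, 0, 0)) == pytest.approx(
            0.8, abs=1e-9
        )

    def test_bridge_axis_clearance(self, asymmetric_frame):
        # at the bridge midpoint the cylinder (radius 0.2) is the nearest
        assert geo.clearance(asymmetric_frame, (0, 0, 0)) == pytest.approx(
            0.2, abs=1e-9
        )

    def test_r_zero_is_strict_membership(self, asymmetric_frame):
        assert geo.contains(asymmetric_frame, (-1.5, 0, 0), 0.0)
        assert not geo.contains(asymmetric_frame, (0, 0.5, 0), 0.0)

    def test_sphere_larger_than_bridge(self, narrow_frame):
        # bridge radius 0.04 < r = 0.05, point far from both spheroids
        assert not geo.contains(narrow_frame, (0.0, 0.0, 0.0), 0.05)

    @pytest.mark.parametrize("r", [0.0, 0.05, 0.1])
    def test_grid_oracle_agreement(self, asymmetric_frame, r, rng):
        """contains agrees with a brute-force lattice oracle away from the
        lattice's indeterminacy band."""
        oracle = GridOracle(asymmetric_frame)
        lo, hi = asymmetric_frame.bounding_box()
        pts = rng.uniform(lo - 0.1, hi + 0.1, size=(1000, 3))
        checked = 0
        for p in pts:
            u, v = to_meridional(p)
            if oracle.indeterminate(u, v, r, tol=2 * oracle.spacing):
                continue
            assert geo.contains(asymmetric_frame, p, r) == oracle.contains(u, v, r)
            checked += 1
        assert checked > 800

    def test_clearance_sign_matches_analytic_membership(
        self, asymmetric_frame, rng
    ):
        oracle = GridOracle(asymmetric_frame)
        lo, hi = asymmetric_frame.bounding_box()
        pts = rng.uniform(lo - 0.1, hi + 0.1, size=(2000, 3))
        for p in pts:
            c = geo.clearance(asymmetric_frame, p)
            if abs(c) < 1e-9:
                continue
            u, v = to_meridional(p)
            assert (c > 0) == oracle.inside_union(u, v)


class TestProjectInside:
    def test_interior_point_unchanged(self, asymmetric_frame):
        p = np.array([-1.2, 0.1, -0.2])
        assert np.array_equal(geo.project_inside(asymmetric_frame, p, 0.05), p)

    def test_sphere_symmetry_radial_projection(self):
        # both lobes equal spheres: projection from far outside along an
        # axis through the mother centre is radial onto the (radius - r) shell
        f = geo.GeometryFrame.from_extents(0.0, 1.0, 1.0, 1.0, 1.0, 0.4, 0.2)
        center = np.array([f.mother.center_x, 0.0, 0.0])
        p = center + np.array([0.0, 0.0, 3.0])
        r = 0.1
        proj = geo.project_inside(f, p, r)
        expected = center + np.array([0.0, 0.0, 0.5 - r])
        assert np.allclose(proj, expected, atol=1e-6)

    def test_idempotent(self, asymmetric_frame, rng):
        lo, hi = asymmetric_frame.bounding_box()
        for p in rng.uniform(lo - 0.5, hi + 0.5, size=(200, 3)):
            q = geo.project_inside(asymmetric_frame, p, 0.05)
            q2 = geo.project_inside(asymmetric_frame, q, 0.05)
            assert np.linalg.norm(q - q2) <= 1e-9

    @pytest.mark.parametrize("r", [0.0, 0.05, 0.1])
    def test_matches_grid_argmin(self, asymmetric_frame, r, rng):
        oracle = GridOracle(asymmetric_frame)
        lo, hi = asymmetric_frame.bounding_box()
        pts = rng.uniform(lo - 0.3, hi + 0.3, size=(120, 3))
        for p in pts:
            if geo.contains(asymmetric_frame, p, r):
                continue
            proj = geo.project_inside(asymmetric_frame, p, r)
            assert geo.contains(asymmetric_frame, proj, r)
            d_ours = float(np.linalg.norm(proj - p))
            u, v = to_meridional(p)
            d_grid = oracle.nearest_admissible_distance(
                u, v, r, buffer=oracle.spacing
            )
            # the lattice argmin is suboptimal by at most ~2 lattice units
            assert d_ours <= d_grid + 1e-3
            assert d_ours >= d_grid - 3 * oracle.spacing

    def test_too_narrow_raises(self):
        f = geo.GeometryFrame.from_extents(0.0, 0.3, 0.2, 0.3, 0.2, 0.5, 0.05)
        with pytest.raises(GeometryTooNarrowError):
            geo.project_inside(f, (0.0, 2.0, 0.0), 0.15)


class TestCompartment:
    @pytest.mark.parametrize(
        "x,expected",
        [(-0.3, "mother"), (1e-4, "daughter"), (0.0, "mother")],
    )
    def test_midpoint_rule(self, x, expected):
        assert geo.compartment_of((x, 0.5, -0.1)) == expected


class TestSampling:
    def test_samples_satisfy_contains(self, asymmetric_frame, rng):
        pts = geo.sample_uniform(asymmetric_frame, 500, r=0.05, rng=rng)
        assert len(pts) == 500
        for p in pts:
            assert geo.contains(asymmetric_frame, p, 0.05)

    def test_symmetric_frame_splits_evenly(self, symmetric_frame, rng):
        n = 100_000
        pts = geo.sample_uniform(symmetric_frame, n, r=0.0, rng=rng)
        fd = np.mean(pts[:, 0] > 0)
        assert abs(fd - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_compartment_restriction(self, asymmetric_frame, rng):
        pts = geo.sample_uniform(
            asymmetric_frame, 200, rng=rng, compartment="mother"
        )
        assert np.all(pts[:, 0] < 0)

    def test_matches_volume_fractions(self, asymmetric_frame, rng):
        frac = geo.lobe_volume_fractions(asymmetric_frame, 200_000, rng)
        pts = geo.sample_uniform(asymmetric_frame, 100_000, rng=rng)
        fd = np.mean(pts[:, 0] > 0)
        se = np.sqrt(fd * (1 - fd) / len(pts)) + frac.se
        assert abs(fd - frac.daughter) < 3 * se

    def test_degenerate_geometry_raises(self):
        # near-zero daughter and hair-thin bridge starve the sampler when it
        # must place a compartment-restricted particle there
        f = geo.GeometryFrame.from_extents(0.0, 2.0, 1.6, 1e-3, 1e-3, 1.0, 1e-4)
        with pytest.raises(DegenerateGeometryError):
            geo.sample_uniform(
                f, 10, rng=np.random.default_rng(0), compartment="daughter"
            )


class TestVolumes:
    def test_fractions_sum_to_one(self, asymmetric_frame, rng):
        frac = geo.lobe_volume_fractions(asymmetric_frame, 20_000, rng)
        assert frac.mother + frac.daughter == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_frame_is_half(self, symmetric_frame, rng):
        frac = geo.lobe_volume_fractions(symmetric_frame, 100_000, rng)
        assert abs(frac.daughter - 0.5) < 3 * frac.se

    def test_disjoint_spheroids_match_closed_form(self, rng):
        # negligible bridge: fraction ratio approaches the closed-form
        # spheroid volume ratio (4/3) pi a b^2
        f = geo.GeometryFrame.from_extents(0.0, 2.0, 1.6, 1.2, 0.9, 0.8, 0.02)
        frac = geo.lobe_volume_fractions(f, 400_000, rng)
        vm = f.mother.volume
        vd = f.daughter.volume
        assert frac.daughter / frac.mother == pytest.approx(vd / vm, rel=0.02)

    def test_halving_dimensions_divides_volume_by_eight(self, rng):
        f1 = geo.GeometryFrame.from_extents(0.0, 2.0, 1.6, 1.0, 0.8, 1.0, 0.4)
        f2 = geo.GeometryFrame.from_extents(0.0, 1.0, 0.8, 0.5, 0.4, 0.5, 0.2)
        v1 = sum(geo.mc_lobe_volumes(f1, 400_000, rng))
        v2 = sum(geo.mc_lobe_volumes(f2, 400_000, rng))
        assert v1 / v2 == pytest.approx(8.0, rel=0.03)


class TestSeriesMetrics:
    def test_constant_series(self, rng):
        series = make_series([0.0, 30.0, 60.0])
        m = geo.series_metrics(series, 50_000, rng)
        assert m.mother_max_length == 2.0
        assert m.mother_max_width == 1.6
        assert m.daughter_max_length == 1.0
        assert m.mean_bridge_width == pytest.approx(0.4)
        assert m.anaphase_duration == 60.0

    def test_duration_over_long_series(self, rng):
        series = make_series(list(np.arange(0.0, 601.0, 30.0)))
        m = geo.series_metrics(series, 50_000, rng)
        assert m.anaphase_duration == 600.0

    def test_symmetric_final_volume_ratio(self, symmetric_frame, rng):
        import dataclasses

        f0 = dataclasses.replace(symmetric_frame, time=0.0)
        f1 = dataclasses.replace(symmetric_frame, time=30.0)
        series = geo.GeometrySeries(cell_id="s", frames=(f0, f1))
        m = geo.series_metrics(series, 200_000, rng)
        assert m.final_volume_ratio == pytest.approx(1.0, abs=0.03)


@settings(max_examples=40, deadline=None)
@given(
    bw0=st.floats(0.1, 0.8),
    bw1=st.floats(0.1, 0.8),
    w=st.floats(0.0, 1.0),
)
def test_frame_at_is_convex_combination(bw0, bw1, w):
    """Interpolated bridge radius is the convex combination of endpoints."""
    f0 = geo.GeometryFrame.from_extents(0.0, 2.0, 1.6, 1.0, 0.8, 1.0, bw0)
    f1 = geo.GeometryFrame.from_extents(30.0, 2.0, 1.6, 1.0, 0.8, 1.0, bw1)
    series = geo.GeometrySeries(cell_id="h", frames=(f0, f1))
    f = geo.frame_at(series, 30.0 * w)
    expected = ((1 - w) * bw0 + w * bw1) / 2.0
    assert f.bridge.radius == pytest.approx(expected, abs=1e-9)
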