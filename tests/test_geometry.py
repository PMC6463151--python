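"""Geometry construction: trabecula profile, chamber discretization, labels."""

import numpy as np
import pytest

from trabeflow.geometry import (
    GeometryError,
    GeometryParams,
    SyntheticVentricleSpec,
    build_idealized_chamber,
    build_synthetic_ventricle,
    count_protrusions,
    fluid_polygon,
    trabecula_profile,
)


class TestTrabeculaProfile:
    @pytest.mark.parametrize(
        "x,hT,rT,expected",
        [
            (0.0, 0.064, 0.10, 0.064),  # both factors equal 1 at the crest
            (0.10, 0.064, 0.10, 0.0),  # vanishes at the radius
            (-0.10, 1.0, 0.10, 0.0),
            # direct evaluation of the perturbed-Gaussian bump at x = rT/2
            (0.05, 0.064, 0.10, 0.064 * 0.75 * np.exp(-((0.5 / 0.7) ** 8))),
        ],
    )
    def test_pointwise_values(self, x, hT, rT, expected):
        assert trabecula_profile(x, hT, rT) == pytest.approx(expected, abs=1e-12)

    def test_even_clamped_and_peaked_at_center(self):
        x = np.linspace(-0.25, 0.25, 501)
        prof = trabecula_profile(x, 0.064, 0.10)
        assert np.allclose(prof, prof[::-1])
        assert (prof >= 0).all()
        assert np.all(prof[np.abs(x) >= 0.10] == 0.0)
        assert prof.max() == pytest.approx(0.064)
        assert x[np.argmax(prof)] == pytest.approx(0.0)

    def test_zero_height_is_flat(self):
        assert np.all(trabecula_profile(np.linspace(-1, 1, 99), 0.0, 0.1) == 0.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(GeometryError):
            trabecula_profile(0.0, 0.1, 0.0)


class TestIdealizedChamber:
    def test_smooth_chamber_matches_analytic_ellipse(self, smooth_chamber, coarse_grid):
        """With hT = 0 the cavity arc is the half ellipse, to within ds."""
        meta = smooth_chamber.meta
        arc = smooth_chamber.points[smooth_chamber.select("chamber-wall")]
        assert len(arc) > 50
        val = ((arc[:, 0] - meta["xc"]) / meta["aV"]) ** 2 + (
            (arc[:, 1] - meta["y_top"]) / meta["bV"]
        ) ** 2
        # implicit-equation residual ~ 2 * distance / semi-axis
        assert np.abs(val - 1.0).max() < 2.5 * meta["ds"]
        assert not smooth_chamber.select("trabecula").any()

    def test_trabeculated_regions(self, trabeculated_chamber):
        """Six trabecula arcs, five interior valleys, smooth flanks."""
        labels = set(trabeculated_chamber.region_names())
        assert {f"trabecula[{k}]" for k in range(6)} <= labels
        assert trabeculated_chamber.interior_valleys() == [
            f"intertrabecular[{k}]" for k in range(1, 6)
        ]
        # the flanking arc outside the trabecular field is plain chamber wall
        assert "chamber-wall" in labels
        assert "intertrabecular[0]" not in labels
        assert "intertrabecular[6]" not in labels

    def test_labels_partition_and_spacing(self, trabeculated_chamber):
        c = trabeculated_chamber
        assert len(c.labels) == len(c.points) == len(c.normals)
        assert all(str(lab) for lab in c.labels)
        ds = c.meta["ds"]
        assert c.spacing.min() >= 0.5 * ds
        assert c.spacing.max() <= 1.5 * ds

    def test_refinement_doubles_point_count(self, default_params):
        c1 = build_idealized_chamber(default_params, 4.0 / 128)
        c2 = build_idealized_chamber(default_params, 4.0 / 256)
        # arc-length / ds oracle: halving the spacing doubles the points
        assert abs(len(c2) - 2 * len(c1)) <= 4

    def test_trabecula_arc_length_matches_profile(self, trabeculated_chamber):
        """Each trabecula segment's arc length ~ the analytic bump's."""
        p = trabeculated_chamber.meta["params"]
        x = np.linspace(-p.rT, p.rT, 2001)
        prof = trabecula_profile(x, p.hT, p.rT)
        core = prof > 0.05 * p.hT  # the labelled extent of each trabecula
        analytic = np.sum(
            np.hypot(np.diff(x[core]), np.diff(prof[core]))
        )
        for k in range(6):
            sel = trabeculated_chamber.select(f"trabecula[{k}]")
            measured = trabeculated_chamber.spacing[sel].sum()
            assert measured == pytest.approx(analytic, rel=0.05)

    def test_normals_point_into_fluid(self, smooth_chamber):
        poly = fluid_polygon(smooth_chamber)
        from shapely.geometry import Point

        probes = smooth_chamber.points + 0.03 * smooth_chamber.normals
        inside = sum(poly.contains(Point(*q)) for q in probes[::7])
        assert inside / len(probes[::7]) > 0.97

    def test_overlapping_trabeculae_rejected(self, default_params):
        import dataclasses

        bad = dataclasses.replace(default_params, trab_pitch=0.15, hT=0.064)
        with pytest.raises(GeometryError, match="overlap"):
            build_idealized_chamber(bad, 4.0 / 128)

    def test_invalid_params_rejected(self):
        with pytest.raises(GeometryError):
            GeometryParams(aV=-1.0)
        with pytest.raises(GeometryError):
            GeometryParams(hT=0.9, bV=0.8)
        with pytest.raises(GeometryError):
            GeometryParams(wAV=0.8, wSV=0.7)

    def test_vertex_file_roundtrip(self, trabeculated_chamber, tmp_path):
        f = tmp_path / "boundary.vertex"
        trabeculated_chamber.save_vertex_file(f)
        lines = [ln for ln in f.read_text().splitlines() if not ln.startswith("#")]
        assert len(lines) == len(trabeculated_chamber)
        x, y, lab = lines[0].split()
        assert float(x) == pytest.approx(trabeculated_chamber.points[0, 0])
        assert lab == str(trabeculated_chamber.labels[0])


class TestSyntheticVentricle:
    def test_deterministic_per_seed(self):
        spec = SyntheticVentricleSpec(seed=7)
        a = build_synthetic_ventricle(spec)
        b = build_synthetic_ventricle(spec)
        assert np.array_equal(a.points, b.points)
        c = build_synthetic_ventricle(SyntheticVentricleSpec(seed=8))
        assert not np.array_equal(a.points, c.points)

    def test_zero_depth_outline_is_smooth(self):
        spec = SyntheticVentricleSpec(depth_mean=0.0, depth_sd=0.0, seed=3)
        curve = build_synthetic_ventricle(spec)
        assert not curve.select("trabecula").any()
        # all curvature one sign: no inward protrusions
        assert count_protrusions(curve) == 0

    def test_protrusion_count_via_curvature(self):
        spec = SyntheticVentricleSpec(
            n_trab=6, depth_mean=0.08, depth_sd=0.0, irregularity=0.02, seed=11
        )
        curve = build_synthetic_ventricle(spec)
        assert curve.select("trabecula").any()
        assert count_protrusions(curve) == 6
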