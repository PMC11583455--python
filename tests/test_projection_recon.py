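"""Biplane reconstruction: masks, depths, surfaces, capping, scaling."""

import json

import numpy as np
import pytest
from scipy.optimize import minimize

from blisterflow.errors import (
    DegenerateViewsError,
    GeometryError,
    MaskError,
    ReconstructionError,
)
from blisterflow.geometry_synth import (
    CenterlineSpec,
    RadiusProfile,
    make_bifurcation_phantom,
    make_tube_mesh,
    measure_bifurcation_angle,
    project_silhouette,
)
from blisterflow.masks import ProjectionMask, dice_coefficient
from blisterflow.projection_recon import (
    PlaneCurve,
    cap_openings,
    centerline_from_mask,
    estimate_oblique_angle,
    extend_outlet,
    load_mask,
    reconstruct_oblique,
    reconstruct_orthogonal,
    recover_depths,
    scale_to_reference,
    stack_contours_to_mesh,
    width_profile,
)


# ---------------------------------------------------------------------------
# mask ingestion
# ---------------------------------------------------------------------------


class TestLoadMask:
    def test_png_roundtrip_preserves_foreground(self, tmp_path, straight_tube):
        mask = project_silhouette(straight_tube, 0.0, 0.1)
        mask.save(tmp_path / "m.png")
        back = load_mask(tmp_path / "m.png")
        assert back.foreground_count == mask.foreground_count
        assert np.array_equal(back.data, mask.data)
        assert back.view_angle_deg == mask.view_angle_deg

    def test_square_polygon_rasterizes_to_area(self, tmp_path):
        poly = [[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]
        path = tmp_path / "poly.json"
        path.write_text(
            json.dumps({"pixel_spacing_mm": 0.5, "polygons": [poly]})
        )
        mask = load_mask(path)
        assert mask.foreground_count == pytest.approx(400, abs=45)

    def test_missing_spacing_rejected(self, tmp_path):
        path = tmp_path / "poly.json"
        path.write_text(json.dumps({"polygons": [[[0, 0], [1, 0], [1, 1]]]}))
        with pytest.raises(MaskError):
            load_mask(path)

    def test_all_background_rejected(self):
        with pytest.raises(MaskError):
            ProjectionMask(np.zeros((10, 10), bool), 0.1)


# ---------------------------------------------------------------------------
# oblique angle
# ---------------------------------------------------------------------------


class TestEstimateObliqueAngle:
    @pytest.mark.parametrize(
        "ap, obl, expected", [(60.0, 60.0, 0.0), (60.0, 30.0, 60.0)]
    )
    def test_arccos_of_ratio(self, ap, obl, expected):
        assert estimate_oblique_angle(ap, obl) == pytest.approx(expected, abs=1e-9)

    def test_ratio_above_one_rejected(self):
        with pytest.raises(ReconstructionError):
            estimate_oblique_angle(30.0, 60.0)

    def test_phantom_recovers_view_angle_within_ten_percent(self):
        true_angle, theta = 60.0, 40.0
        ap = measure_bifurcation_angle(make_bifurcation_phantom(true_angle, 0.0))
        obl = measure_bifurcation_angle(make_bifurcation_phantom(true_angle, theta))
        assert estimate_oblique_angle(ap, obl) == pytest.approx(theta, rel=0.10)


# ---------------------------------------------------------------------------
# centerline and widths
# ---------------------------------------------------------------------------


def _strip_mask(offset_mm=0.0, width_mm=4.0, spacing=0.1, rows=100):
    cols = 200
    data = np.zeros((rows, cols), bool)
    j0 = int((10.0 + offset_mm) / spacing)
    data[:, j0 : j0 + int(width_mm / spacing)] = True
    return ProjectionMask(data, spacing, 0.0, origin_mm=np.array([0.0, 0.0]))


class TestCenterlineFromMask:
    def test_centered_strip_constant_centroid(self):
        c = centerline_from_mask(_strip_mask())
        assert np.ptp(c.x) < 1e-9

    def test_offset_strip_shifts_centroid(self):
        c0 = centerline_from_mask(_strip_mask(0.0))
        c3 = centerline_from_mask(_strip_mask(3.0))
        assert np.allclose(c3.x - c0.x, 3.0, atol=1e-9)

    def test_curved_tube_centroid_tracks_analytic_centerline(self, siphon_tube):
        s = 0.05
        mask = project_silhouette(siphon_tube, 0.0, s)
        c = centerline_from_mask(mask)
        cl = siphon_tube.centerline
        x_true = np.interp(c.z, cl[:, 2], cl[:, 0])
        interior = slice(20, -20)
        # half a pixel of rasterization plus the small chord-midpoint bias
        # a curved tube induces (the silhouette is asymmetric about the
        # projected centerline where curvature varies)
        assert np.abs(c.x - x_true)[interior].max() < 0.5 * s + 0.05


class TestWidthProfile:
    def test_vertical_strip_half_width(self):
        mask = _strip_mask()
        r = width_profile(mask, centerline_from_mask(mask))
        assert np.allclose(r.radius_mm, 2.0, atol=0.1)

    def test_inclined_tube_width_measured_perpendicular(self):
        """A 45-degree tube of perpendicular radius 2 must measure 2, not
        2*sqrt(2); cross-check against the distance transform."""
        from scipy import ndimage

        pts = np.column_stack(
            [np.linspace(0, 14, 60), np.zeros(60), np.linspace(0, 14, 60)]
        )
        tube = make_tube_mesh(pts, RadiusProfile.constant(2.0), 64)
        mask = project_silhouette(tube, 0.0, 0.05)
        c = centerline_from_mask(mask)
        r = width_profile(mask, c)
        mid = r.radius_mm[len(r.radius_mm) // 3 : -len(r.radius_mm) // 3]
        assert np.median(mid) == pytest.approx(2.0, abs=0.05)
        # oracle: EDT at interior medial-axis points gives the same answer
        edt = ndimage.distance_transform_edt(mask.data) * mask.pixel_spacing_mm
        rows = ((c.z - mask.origin_mm[1]) / 0.05 - 0.5).astype(int)
        cols = ((c.x - mask.origin_mm[0]) / 0.05 - 0.5).astype(int)
        sl = slice(len(rows) // 3, -len(rows) // 3)
        edt_mid = edt[rows[sl], cols[sl]]
        assert np.median(edt_mid) == pytest.approx(2.0, abs=0.08)

    def test_conical_silhouette_recovers_linear_profile(self):
        spec = CenterlineSpec(kind="straight", length_mm=20.0, n_samples=50)
        tube = make_tube_mesh(spec, RadiusProfile.linear(1.5, 2.5), 64)
        mask = project_silhouette(tube, 0.0, 0.05)
        r = width_profile(mask, centerline_from_mask(mask))
        expected = 1.5 + r.t * 1.0
        assert np.abs(r.radius_mm - expected)[5:-5].max() < 0.06  # ~1 px


# ---------------------------------------------------------------------------
# depth recovery
# ---------------------------------------------------------------------------


def _project_curve(points, theta_deg):
    th = np.radians(theta_deg)
    u = points[:, 0] * np.cos(th) + points[:, 1] * np.sin(th)
    return PlaneCurve(points[:, 2], u)


class TestRecoverDepths:
    def test_ninety_degrees_depth_equals_other_view_abscissa(self):
        z = np.linspace(0.0, 10.0, 50)
        pts = np.column_stack([np.sin(z), np.cos(z), z])
        c1, c2 = _project_curve(pts, 0.0), _project_curve(pts, 90.0)
        sc1, _ = recover_depths(c1, c2, 90.0)
        assert np.allclose(sc1.xyz[:, 1], c2.resampled(sc1.xyz[:, 2]).x, atol=1e-12)

    def test_helix_depths_recovered_exactly(self):
        """Continuous curves (no rasterization) recover the ground-truth
        depth to 1e-9 mm."""
        z = np.linspace(0.0, 20.0, 200)
        pts = np.column_stack([2 * np.cos(z / 3), 2 * np.sin(z / 3), z])
        c1, c2 = _project_curve(pts, 0.0), _project_curve(pts, 37.0)
        sc1, _ = recover_depths(c1, c2, 37.0)
        y_true = np.interp(sc1.xyz[:, 2], z, pts[:, 1])
        assert np.abs(sc1.xyz[:, 1] - y_true).max() < 1e-9

    def test_parallel_views_rejected(self):
        z = np.linspace(0.0, 10.0, 20)
        c = PlaneCurve(z, np.sin(z))
        with pytest.raises(DegenerateViewsError):
            recover_depths(c, c, 0.0)

    def test_closed_form_equals_brute_force_minimizer(self):
        """Point-wise numeric minimization of ||X2 - Ry(theta) X1|| over
        (z1, z2) agrees with the closed form to 1e-6 mm."""
        rng = np.random.default_rng(11)
        th = np.radians(52.0)
        R = np.array(
            [
                [np.cos(th), -np.sin(th), 0.0],
                [np.sin(th), np.cos(th), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        for _ in range(5):
            z = np.linspace(0, 5, 8)
            pts = np.column_stack(
                [rng.normal(0, 2, 8), rng.normal(0, 2, 8), z]
            )
            c1 = _project_curve(pts, 0.0)
            c2 = _project_curve(pts, 52.0)
            sc1, sc2 = recover_depths(c1, c2, 52.0)
            for k in range(8):
                x1, x2 = c1.x[k], c2.x[k]
                zz = z[k]

                def objective(d, x1=x1, x2=x2, zz=zz):
                    X1 = np.array([x1, d[0], zz])
                    X2 = np.array([x2, d[1], zz])
                    # view-2 coordinates of the rotated view-1 point
                    rot = np.array(
                        [
                            X1[0] * np.cos(th) + X1[1] * np.sin(th),
                            -X1[0] * np.sin(th) + X1[1] * np.cos(th),
                            X1[2],
                        ]
                    )
                    return np.sum((X2 - rot) ** 2)

                res = minimize(objective, x0=[0.0, 0.0], method="BFGS", tol=1e-16)
                assert abs(res.x[0] - sc1.xyz[k, 1]) < 1e-6
                assert abs(res.x[1] - sc2.xyz[k, 1]) < 1e-6


# ---------------------------------------------------------------------------
# surface reconstruction
# ---------------------------------------------------------------------------


class TestReconstructOrthogonal:
    def test_strip_pair_gives_cylinder(self):
        """Two width-2R strips back-project to squares whose inscribed
        ellipse is the incircle: a circular cylinder of radius R."""
        ap = _strip_mask(width_mm=4.0)
        lat = ProjectionMask(
            _strip_mask(width_mm=4.0).data, 0.1, 90.0, origin_mm=np.zeros(2)
        )
        mesh = reconstruct_orthogonal(ap, lat)
        from blisterflow.mesh_validation import cross_section_areas

        series = cross_section_areas(cap_openings(mesh), n_slices=20)
        # hand-built masks carry a one-pixel width-convention uncertainty
        assert np.allclose(series.area_mean[2:-2], np.pi * 4.0, rtol=0.06)

    def test_unequal_widths_give_elliptical_sections(self):
        ap = _strip_mask(width_mm=4.0)
        lat = ProjectionMask(
            _strip_mask(width_mm=2.0).data, 0.1, 90.0, origin_mm=np.zeros(2)
        )
        mesh = reconstruct_orthogonal(ap, lat)
        from blisterflow.mesh_validation import cross_section_areas

        series = cross_section_areas(cap_openings(mesh), n_slices=20)
        assert np.allclose(series.area_mean[2:-2], np.pi * 2.0 * 1.0, rtol=0.08)

    def test_non_orthogonal_metadata_rejected(self):
        ap = _strip_mask()
        obl = ProjectionMask(ap.data, 0.1, 40.0, origin_mm=np.zeros(2))
        with pytest.raises(ReconstructionError):
            reconstruct_orthogonal(ap, obl)

    def test_translation_equivariance(self, siphon_tube):
        """Rigidly shifting both masks shifts the surface, nothing else."""
        s = 0.1
        ap = project_silhouette(siphon_tube, 0.0, s)
        lat = project_silhouette(siphon_tube, 90.0, s)
        m0 = reconstruct_orthogonal(ap, lat)
        ap2 = ProjectionMask(ap.data, s, 0.0, origin_mm=ap.origin_mm + [5.0, 2.0])
        lat2 = ProjectionMask(lat.data, s, 90.0, origin_mm=lat.origin_mm + [-3.0, 2.0])
        m1 = reconstruct_orthogonal(ap2, lat2)
        assert np.allclose(
            m1.vertices - m0.vertices, [5.0, -3.0, 2.0], atol=1e-9
        )


class TestReconstructOblique:
    def test_straight_cylinder_recovered(self, straight_tube):
        s = 0.1
        ap = project_silhouette(straight_tube, 0.0, s)
        obl = project_silhouette(straight_tube, 45.0, s)
        mesh = reconstruct_oblique(ap, obl, 45.0)
        assert np.median(mesh.radii) == pytest.approx(2.0, abs=s)

    def test_reprojection_overlays_input(self, siphon_tube):
        s = 0.05
        ap = project_silhouette(siphon_tube, 0.0, s)
        obl = project_silhouette(siphon_tube, 40.0, s)
        mesh = reconstruct_oblique(ap, obl, 40.0)
        for ang, ref in ((0.0, ap), (40.0, obl)):
            bounds = (
                ref.origin_mm[0],
                ref.origin_mm[1],
                ref.origin_mm[0] + s * ref.shape[1] - 1e-9,
                ref.origin_mm[1] + s * ref.shape[0] - 1e-9,
            )
            rp = project_silhouette(mesh, ang, s, bounds_mm=bounds)
            assert dice_coefficient(rp, ref) >= 0.95

    def test_ninety_degree_pair_matches_orthogonal_areas(self, siphon_tube):
        from blisterflow.mesh_validation import cross_section_areas

        s = 0.05
        ap = project_silhouette(siphon_tube, 0.0, s)
        lat = project_silhouette(siphon_tube, 90.0, s)
        obl_mesh = reconstruct_oblique(ap, lat, 90.0)
        orth_mesh = reconstruct_orthogonal(ap, lat)
        z = np.linspace(2.0, 28.0, 30)
        a = cross_section_areas(cap_openings(obl_mesh), z_positions=z)
        b = cross_section_areas(cap_openings(orth_mesh.copy()), z_positions=z)
        assert np.abs(a.area_mean / b.area_mean - 1.0).max() < 0.05


class TestStackContours:
    def test_identical_circles_make_cylinder(self):
        phi = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        circle = np.column_stack([2 * np.cos(phi), 2 * np.sin(phi)])
        mesh = stack_contours_to_mesh([circle] * 10, 1.0)
        assert mesh.bounds[1][2] == pytest.approx(9.0)
        assert cap_openings(mesh).volume() == pytest.approx(9 * np.pi * 4, rel=0.02)

    def test_growing_circles_make_cone(self):
        phi = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        contours = [
            np.column_stack([r * np.cos(phi), r * np.sin(phi)])
            for r in np.linspace(1.0, 2.0, 8)
        ]
        mesh = stack_contours_to_mesh(contours, 1.0)
        r_bot = np.linalg.norm(mesh.vertices[:32, :2], axis=1)
        r_top = np.linalg.norm(mesh.vertices[-32:, :2], axis=1)
        assert np.allclose(r_bot, 1.0, atol=1e-6)
        assert np.allclose(r_top, 2.0, atol=1e-6)

    def test_ellipse_stack_volume_matches_prism_sum(self):
        phi = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        ellipse = np.column_stack([3 * np.cos(phi), 1.5 * np.sin(phi)])
        spacing = 0.5
        mesh = stack_contours_to_mesh([ellipse] * 12, spacing)
        expected = np.pi * 3 * 1.5 * spacing * 11
        assert cap_openings(mesh).volume() == pytest.approx(expected, rel=0.02)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(ReconstructionError):
            stack_contours_to_mesh([bowtie] * 3, 1.0)


class TestCapAndExtend:
    def test_capped_cylinder_topology_and_volume(self, straight_tube):
        capped = cap_openings(straight_tube.copy())
        assert capped.is_watertight()
        assert capped.euler_characteristic() == 2
        assert capped.volume() == pytest.approx(np.pi * 4 * 20, rel=0.01)
        # inlet plate is the lower one
        from blisterflow.meshes import INLET_CAP, OUTLET_CAP

        z_in = capped.vertices[capped.faces[capped.face_labels == INLET_CAP]].mean(
            axis=(0, 1)
        )[2]
        z_out = capped.vertices[capped.faces[capped.face_labels == OUTLET_CAP]].mean(
            axis=(0, 1)
        )[2]
        assert z_in < z_out

    def test_already_closed_mesh_rejected(self, capped_cylinder):
        with pytest.raises(GeometryError):
            cap_openings(capped_cylinder)

    def test_extend_outlet_lengthens_cylinder(self, straight_tube):
        out = extend_outlet(straight_tube.copy(), 10.0)
        assert out.bounds[1][2] == pytest.approx(30.0, abs=1e-6)
        capped = cap_openings(out)
        assert capped.volume() == pytest.approx(np.pi * 4 * 30, rel=0.01)

    def test_extend_capped_mesh_stays_watertight(self, capped_cylinder):
        out = extend_outlet(capped_cylinder.copy(), 5.0)
        assert out.is_watertight()
        assert out.bounds[1][2] == pytest.approx(25.0, abs=1e-6)

    def test_curved_tube_extension_is_straight(self):
        spec = CenterlineSpec(
            kind="planar-arc", length_mm=30.0, n_samples=100, arc_angle_deg=60.0
        )
        tube = make_tube_mesh(spec, RadiusProfile.constant(2.0), 32)
        loops_before = tube.boundary_loops()
        end_ring = tube.vertices[loops_before[-1]]
        out = extend_outlet(tube, 8.0)
        new_ring = out.vertices[-len(end_ring) :]
        d = new_ring.mean(axis=0) - end_ring.mean(axis=0)
        assert np.linalg.norm(d) == pytest.approx(8.0, abs=1e-6)

    def test_nonpositive_extension_rejected(self, straight_tube):
        with pytest.raises(GeometryError):
            extend_outlet(straight_tube, 0.0)


class TestScaleToReference:
    def test_doubling_diameter_doubles_lengths(self, straight_tube):
        out = scale_to_reference(straight_tube.copy(), 8.0)
        # the 32-gon outlet ring has an effective diameter slightly under 4
        d_eff = 2.0 * np.sqrt(cap_area(straight_tube) / np.pi)
        assert out.extents[2] == pytest.approx(
            (8.0 / d_eff) * straight_tube.extents[2], rel=1e-6
        )

    def test_idempotent(self, straight_tube):
        a = scale_to_reference(straight_tube.copy(), 5.0)
        b = scale_to_reference(a, 5.0)
        assert np.allclose(a.vertices, b.vertices, atol=1e-9)

    def test_volume_scales_cubically(self, straight_tube):
        v0 = cap_openings(straight_tube.copy()).volume()
        scaled = scale_to_reference(straight_tube.copy(), 8.0)
        v1 = cap_openings(scaled).volume()
        factor = 8.0 / (2.0 * np.sqrt(cap_area(straight_tube) / np.pi))
        assert v1 / v0 == pytest.approx(factor**3, rel=1e-6)


def cap_area(tube):
    loop = tube.boundary_loops()[-1]
    pts = tube.vertices[loop][:, :2]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
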