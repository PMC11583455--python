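"""WSS, WSSG, pressure decomposition, streamlines, recirculation."""

import numpy as np
import pytest

from blisterflow.flow_solver import (
    FT_WALL,
    BoundaryConditions,
    FluidProperties,
    FlowField,
    VoxelGrid,
)
from blisterflow.hemodynamics_post import (
    WallField,
    classify_wss,
    detect_recirculation,
    max_wss,
    normalize_pressure,
    pressure_components,
    trace_streamlines,
    wall_shear_stress,
    wss_gradient,
)

from conftest import analytic_poiseuille


def _box_field(n=16, velocity=None, pressure=None, h=1e-3):
    """All-fluid cubic grid with a hand-painted velocity field."""
    fluid = np.ones((n, n, n), dtype=bool)
    grid = VoxelGrid(
        spacing=h,
        origin=np.zeros(3),
        fluid=fluid,
        ftype_x=np.zeros((n + 1, n, n), np.int8),
        ftype_y=np.zeros((n, n + 1, n), np.int8),
        ftype_z=np.zeros((n, n, n + 1), np.int8),
        reference_diameter=n * h,
    )
    u = np.zeros((n + 1, n, n))
    v = np.zeros((n, n + 1, n))
    w = np.zeros((n, n, n + 1))
    p = np.zeros((n, n, n)) if pressure is None else pressure
    if velocity is not None:
        x, y, z = grid.cell_centers()
        for i in range(n + 1):
            for j in range(n):
                for k in range(n):
                    u[i, j, k] = velocity(i * h, y[j], z[k])[0]
        for i in range(n):
            for j in range(n + 1):
                for k in range(n):
                    v[i, j, k] = velocity(x[i], j * h, z[k])[1]
        for i in range(n):
            for j in range(n):
                for k in range(n + 1):
                    w[i, j, k] = velocity(x[i], y[j], k * h)[2]
    return FlowField(
        grid=grid,
        u=u,
        v=v,
        w=w,
        p=p,
        residual_history={"continuity": np.array([1e-6])},
        converged=True,
        n_iter=1,
        props=FluidProperties(),
        bc=BoundaryConditions(),
    )


class TestWallShearStress:
    def test_poiseuille_wss_matches_closed_form(self, poiseuille_solution):
        grid, field = poiseuille_solution
        wall = wall_shear_stress(field)
        ref = analytic_poiseuille()["wss"]
        # interior wall faces, away from the tube ends
        z = wall.centers[:, 2]
        sel = (z > z.min() + 2.5e-3) & (z < z.max() - 2.5e-3)
        assert np.mean(wall.wss[sel]) == pytest.approx(ref, rel=0.12)

    def test_zero_flow_gives_zero_wss(self, poiseuille_solution):
        grid, field = poiseuille_solution
        still = FlowField(
            grid=grid,
            u=np.zeros_like(field.u),
            v=np.zeros_like(field.v),
            w=np.zeros_like(field.w),
            p=field.p,
            residual_history=field.residual_history,
            converged=True,
            n_iter=1,
            props=field.props,
            bc=field.bc,
        )
        wall = wall_shear_stress(still)
        assert np.all(wall.wss == 0.0)

    def test_kinematic_channel_is_wss_over_density(self, poiseuille_solution):
        _, field = poiseuille_solution
        wall = wall_shear_stress(field)
        assert np.array_equal(wall.wss_kinematic, wall.wss / field.props.density)


class TestWssGradient:
    def test_uniform_wss_has_zero_gradient(self, poiseuille_solution):
        _, field = poiseuille_solution
        wall = wall_shear_stress(field)
        wall.wss = np.full(len(wall), 2.0)
        out = wss_gradient(wall)
        assert np.allclose(out.wssg, 0.0, atol=1e-9)

    def test_axial_ramp_gradient_recovered(self, poiseuille_solution):
        """WSS painted as k * z on the cylinder wall has surface gradient k."""
        _, field = poiseuille_solution
        wall = wall_shear_stress(field)
        k = 500.0  # Pa/m
        wall.wss = k * wall.centers[:, 2]
        out = wss_gradient(wall)
        z = wall.centers[:, 2]
        interior = (z > z.min() + 1e-3) & (z < z.max() - 1e-3)
        med = np.median(out.wssg[interior])
        assert med == pytest.approx(k, rel=0.05)


class TestClassifyWss:
    def _wall(self, wss_values):
        wss = np.asarray(wss_values, dtype=float)
        n = len(wss)
        return WallField(
            centers=np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]) * 1e-3,
            normals=np.tile([1.0, 0.0, 0.0], (n, 1)),
            face_area=1e-8,
            wss_vector=np.zeros((n, 3)),
            wss=wss,
            wss_kinematic=wss / 1056.0,
        )

    def test_threshold_labels(self):
        wall, summary = classify_wss(self._wall([12.0, 0.3, 2.0, 5.0]))
        assert list(wall.labels) == ["high", "low", "normal", "normal"]

    def test_fractions_sum_to_one(self):
        _, summary = classify_wss(self._wall(np.linspace(0.1, 15.0, 37)))
        total = (
            summary["area_fraction_high"]
            + summary["area_fraction_normal"]
            + summary["area_fraction_low"]
        )
        assert total == pytest.approx(1.0)

    def test_all_normal_at_reference(self):
        _, summary = classify_wss(self._wall([2.0] * 5))
        assert summary["area_fraction_normal"] == 1.0

    def test_max_wss_inlet_exclusion(self):
        wall = self._wall([50.0, 1.0, 2.0, 3.0])
        assert max_wss(wall) == 50.0
        assert max_wss(
            wall, inlet_center=wall.centers[0], exclusion_margin=1.5e-3
        ) == 3.0


class TestPressure:
    def test_dynamic_pressure_formula(self):
        field = _box_field(8, velocity=lambda x, y, z: (0.0, 0.0, 0.5))
        dec = pressure_components(field)
        assert np.allclose(dec.dynamic_pa, 0.5 * 1056.0 * 0.25)

    def test_hydrostatic_height_difference(self):
        n = 8
        field = _box_field(n)
        dec = pressure_components(field)
        span = dec.hydrostatic_pa.max() - dec.hydrostatic_pa.min()
        expected = 1056.0 * 9.81 * (n - 1) * 1e-3
        assert span == pytest.approx(expected, rel=1e-9)

    def test_zero_velocity_zero_dynamic(self):
        field = _box_field(6)
        dec = pressure_components(field)
        assert np.all(dec.dynamic_pa == 0.0)

    def test_kinematic_conversion(self):
        field = _box_field(6, velocity=lambda x, y, z: (0.0, 0.0, 1.0))
        dec = pressure_components(field)
        assert np.allclose(dec.kinematic("dynamic") * 1056.0, dec.dynamic_pa)

    def test_dynamic_and_hydrostatic_negligible_vs_static(self, poiseuille_solution):
        """On the default tube run the dynamic and hydrostatic ranges stay
        well under the static pressure range (< 20% at desk scale)."""
        _, field = poiseuille_solution
        s = pressure_components(field).summary()
        assert s["dynamic_over_static"] < 0.2
        assert s["hydrostatic_over_static"] < 0.2


class TestNormalizePressure:
    def test_unit_span_between_inlet_and_outlet(self, poiseuille_solution):
        _, field = poiseuille_solution
        pn = normalize_pressure(field)
        from blisterflow.flow_solver import FT_INLET, FT_OUTLET
        from blisterflow.hemodynamics_post import _patch_cell_pressure

        # by construction the patch means map to 1 and 0
        p_in = _patch_cell_pressure(field, FT_INLET)
        p_out = _patch_cell_pressure(field, FT_OUTLET)
        mapped = (np.array([p_in, p_out]) - p_out) / (p_in - p_out)
        assert mapped == pytest.approx([1.0, 0.0], abs=1e-12)
        assert np.nanmax(pn) <= 1.3 and np.nanmin(pn) >= -0.3

    def test_monotone_map_preserves_ordering(self, poiseuille_solution):
        _, field = poiseuille_solution
        pn = normalize_pressure(field)
        fl = field.grid.fluid
        order_raw = np.argsort(field.p[fl])
        order_norm = np.argsort(pn[fl])
        assert np.array_equal(order_raw, order_norm)

    def test_poiseuille_normalized_pressure_linear_in_z(self, poiseuille_solution):
        grid, field = poiseuille_solution
        pn = normalize_pressure(field)
        i, j = (np.argwhere(grid.fluid[:, :, grid.shape[2] // 2])
                .mean(axis=0).astype(int))
        col = grid.fluid[i, j, :]
        z = grid.cell_centers()[2][col]
        vals = pn[i, j, col]
        sel = (z > z.min() + 1.5e-3) & (z < z.max() - 1.5e-3)
        fit = np.polyfit(z[sel], vals[sel], 1)
        resid = vals[sel] - np.polyval(fit, z[sel])
        assert np.abs(resid).max() < 0.02


class TestStreamlines:
    def test_uniform_axial_field_gives_straight_lines(self):
        field = _box_field(12, velocity=lambda x, y, z: (0.0, 0.0, 0.1))
        seeds = np.array([[6e-3, 6e-3, 2e-3], [3e-3, 9e-3, 2e-3]])
        lines = trace_streamlines(field, seeds, step=5e-4)
        assert len(lines) == 2
        for pl in lines.polylines:
            assert np.ptp(pl[:, 0]) < 1e-9 and np.ptp(pl[:, 1]) < 1e-9
            assert pl[-1, 2] > pl[0, 2]

    def test_solid_body_rotation_circles(self):
        omega = 10.0
        c = 8e-3

        def vel(x, y, z):
            return (-omega * (y - c), omega * (x - c), 0.0)

        field = _box_field(16, velocity=vel)
        seed = np.array([[c + 4e-3, c, 8e-3]])
        lines = trace_streamlines(field, seed, step=2e-4, max_length=2 * np.pi * 4e-3)
        pl = lines.polylines[0]
        radii = np.linalg.norm(pl[:, :2] - [c, c], axis=1)
        assert np.abs(radii / 4e-3 - 1.0).max() < 0.01

    def test_seed_outside_fluid_skipped(self, poiseuille_solution):
        _, field = poiseuille_solution
        with pytest.warns(UserWarning, match="outside"):
            lines = trace_streamlines(field, np.array([[1.0, 1.0, 1.0]]))
        assert lines.skipped_seeds == 1

    def test_speeds_match_local_field(self):
        field = _box_field(12, velocity=lambda x, y, z: (0.0, 0.0, 0.25))
        lines = trace_streamlines(
            field, np.array([[6e-3, 6e-3, 3e-3]]), step=5e-4
        )
        assert np.allclose(lines.speeds[0], 0.25, atol=1e-9)


class TestDetectRecirculation:
    def test_unidirectional_flow_is_anterograde(self):
        field = _box_field(10, velocity=lambda x, y, z: (0.0, 0.0, 0.2))
        sac = np.zeros((10, 10, 10), bool)
        sac[3:7, 3:7, 3:7] = True
        out = detect_recirculation(field, sac, np.array([0.0, 0.0, 1.0]))
        assert out["reversed_fraction"] == 0.0
        assert out["pattern"] == "anterograde"

    def test_imposed_vortex_is_retrograde(self):
        c = 5e-3

        def vel(x, y, z):
            return (0.0, 10.0 * (z - c), -10.0 * (y - c))  # vortex in y-z

        field = _box_field(10, velocity=vel)
        sac = np.ones((10, 10, 10), bool)
        out = detect_recirculation(field, sac, np.array([0.0, 0.0, 1.0]))
        assert out["reversed_fraction"] > 0.25
        assert out["pattern"] == "retrograde-recirculating"

    def test_empty_sac_rejected(self):
        field = _box_field(6)
        with pytest.raises(ValueError):
            detect_recirculation(
                field, np.zeros((6, 6, 6), bool), np.array([0.0, 0.0, 1.0])
            )
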