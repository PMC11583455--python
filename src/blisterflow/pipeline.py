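"""End-to-end pipeline: synthesize -> project -> reconstruct -> validate ->
voxelize -> solve -> post-process -> report.

Each run writes a deterministic directory layout::

    run_dir/
      config.json            resolved configuration + hash + versions
      meshes/*.stl           ground truth, blister variant, reconstructions
      masks/*.png|.json      rendered projections
      validation/*.csv       per-slice area series, band-overlap summary
      flow/solution.vtk      velocity/pressure field
      flow/wall.csv          per-face WSS / WSSG / classification
      report.json, report.html

Identical configurations give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import PipelineError
from .flow_solver import (
    BoundaryConditions,
    FluidProperties,
    solve_steady,
    voxelize,
    check_mass_conservation,
    reynolds_number,
)
from .geometry_synth import (
    BlisterSpec,
    CenterlineSpec,
    RadiusProfile,
    add_blister,
    make_tube_mesh,
    project_silhouette,
)
from .hemodynamics_post import (
    classify_wss,
    detect_recirculation,
    max_wss,
    normalize_pressure,
    pressure_components,
    sac_cell_mask,
    wall_shear_stress,
    wss_gradient,
)
from .mesh_validation import (
    band_overlap,
    cross_section_series_with_uncertainty,
    normalize_like,
    normalize_unit_cube,
)
from .projection_recon import cap_openings, reconstruct_oblique, reconstruct_orthogonal
from .vtkio import write_vtk_structured_points


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage on the bundled synthetic siphon geometry."""
    out = Path(out_dir)
    for sub in ("meshes", "masks", "validation", "flow"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    (out / "config.json").write_text(config.to_json())

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3),
                **(result or {}),
            }
            return result

        return wrap

    # -- synth -------------------------------------------------------------
    radius = config.vessel_diameter_mm / 2.0
    spec = CenterlineSpec(n_samples=config.n_centerline_samples)
    tube = make_tube_mesh(
        spec, RadiusProfile.constant(radius), config.n_circumferential
    )
    blister = BlisterSpec(
        t0=config.blister_t0,
        height_mm=config.blister_height_mm,
        longitudinal_extent_mm=config.blister_longitudinal_mm,
        circumferential_extent_deg=config.blister_circumferential_deg,
    )
    bulged = add_blister(tube, blister)

    @stage("synthesize")
    def _synth():
        tube.save(out / "meshes" / "ground_truth.stl")
        bulged.save(out / "meshes" / "blister.stl")
        return {"n_vertices": len(tube.vertices)}

    # -- project -----------------------------------------------------------
    s = config.pixel_spacing_mm
    theta = config.oblique_angle_deg
    mask_ap = project_silhouette(tube, 0.0, s)
    mask_lat = project_silhouette(tube, 90.0, s)
    mask_obl = project_silhouette(tube, theta, s)

    @stage("project")
    def _project():
        mask_ap.save(out / "masks" / "ap.png")
        mask_lat.save(out / "masks" / "lateral.png")
        mask_obl.save(out / "masks" / "oblique.png")
        return {"pixel_spacing_mm": s, "views_deg": [0.0, 90.0, theta]}

    # -- reconstruct -------------------------------------------------------
    recon_orth = reconstruct_orthogonal(mask_ap, mask_lat)
    recon_obl = reconstruct_oblique(mask_ap, mask_obl, theta)

    @stage("reconstruct")
    def _recon():
        recon_orth.save(out / "meshes" / "recon_orthogonal.stl")
        recon_obl.save(out / "meshes" / "recon_oblique.stl")
        return {}

    # -- validate ----------------------------------------------------------
    @stage("validate")
    def _validate():
        truth_capped = cap_openings(tube.copy())
        truth_n = normalize_unit_cube(truth_capped)
        truth = cross_section_series_with_uncertainty(
            truth_n,
            n_slices=config.n_slices,
            n_boot=config.n_bootstrap,
            seed=config.seed_for("bootstrap"),
        )
        overlaps = {}
        for name, recon in (("orthogonal", recon_orth), ("oblique", recon_obl)):
            # shared frame + same statistic on both sides, so that only
            # genuine geometric disagreement breaks the band
            rn = normalize_like(cap_openings(recon.copy()), truth_capped)
            series = cross_section_series_with_uncertainty(
                rn,
                n_slices=config.n_slices,
                n_boot=config.n_bootstrap,
                seed=config.seed_for(f"bootstrap-{name}"),
                z_positions=truth.z,
            )
            ov = band_overlap(series, truth, k_sd=config.band_k_sd)
            overlaps[name] = ov.a_in_b
            series.to_frame().to_csv(
                out / "validation" / f"areas_{name}.csv", index=False
            )
        truth.to_frame().to_csv(out / "validation" / "areas_truth.csv", index=False)
        return {"band_overlap": overlaps}

    # -- flow --------------------------------------------------------------
    props = FluidProperties(
        dynamic_viscosity=config.dynamic_viscosity,
        density=config.density,
        gravity=config.gravity,
    )
    bc = BoundaryConditions(
        flow_rate=config.flow_rate,
        outlet_pressure_mmhg=config.outlet_pressure_mmhg,
    )
    capped = cap_openings(bulged.copy())
    grid = voxelize(capped, cells_per_diameter=config.cells_per_diameter)
    flow_result: dict = {}

    @stage("solve")
    def _solve():
        field = solve_steady(
            grid,
            props,
            bc,
            relax=(config.relax_pressure, config.relax_velocity),
            tol=config.residual_tol,
            max_iter=config.max_iter,
            stokes=config.stokes,
        )
        flow_result["field"] = field
        write_vtk_structured_points(out / "flow" / "solution.vtk", field)
        field.save_npz(out / "flow" / "field.npz")
        mass = check_mass_conservation(field)
        return {
            "converged": field.converged,
            "iterations": field.n_iter,
            "final_residuals": {
                k: float(vals[-1]) for k, vals in field.residual_history.items()
            },
            "reynolds": reynolds_number(
                props, config.flow_rate, grid.reference_diameter
            ),
            "mass_conservation": mass,
        }

    # -- post --------------------------------------------------------------
    @stage("post")
    def _post():
        field = flow_result["field"]
        wall = wss_gradient(wall_shear_stress(field, props))
        wall, wss_summary = classify_wss(
            wall,
            thresholds={
                "high": config.wss_high_pa,
                "low": config.wss_low_pa,
                "normal_ref": config.wss_normal_ref_pa,
            },
        )
        wall.to_frame().to_csv(out / "flow" / "wall.csv", index=False)
        from .flow_solver import FT_INLET

        margin = config.inlet_exclusion_diameters * grid.reference_diameter
        inlet_center = grid.patch_center(FT_INLET)
        pdec = pressure_components(field, props).summary()
        pnorm = normalize_pressure(field)
        sac = sac_cell_mask(grid, tube)
        recirc = (
            detect_recirculation(
                field,
                sac,
                parent_axis=np.array([0.0, 0.0, 1.0]),
                threshold=config.recirculation_threshold,
            )
            if sac.any()
            else {"pattern": "no-sac", "reversed_fraction": 0.0}
        )
        return {
            "max_wss_pa": max_wss(wall),
            "max_wss_pa_inlet_excluded": max_wss(
                wall, inlet_center=inlet_center, exclusion_margin=margin
            ),
            "wss_classification": wss_summary,
            "pressure_decomposition": pdec,
            "normalized_pressure_span": [
                float(np.nanmin(pnorm)),
                float(np.nanmax(pnorm)),
            ],
            "recirculation": recirc,
        }

    # -- report ------------------------------------------------------------
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "report.html").write_text(_render_html(report))
    return out


def _render_html(report: dict) -> str:
    rows = "".join(
        f"<tr><th>{k}</th><td><pre>{json.dumps(v, indent=1, sort_keys=True)}"
        f"</pre></td></tr>"
        for k, v in report["stages"].items()
    )
    return (
        "<html><head><title>blisterflow run report</title></head><body>"
        f"<h1>blisterflow run {report['config_hash']}</h1>"
        f"<p>seed {report['seed']}, version {report['version']}</p>"
        f"<table border='1'>{rows}</table></body></html>"
    )
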