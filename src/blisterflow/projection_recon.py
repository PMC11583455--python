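"""3D reconstruction of the vessel lumen from segmented projections.

Two biplane algorithms are provided, mirroring the two acquisition
scenarios of X-ray angiography, plus a contour-stacking path for axial
CTA-style input:

``reconstruct_orthogonal``
    When a pure lateral view exists, every axial image row back-projects to
    a rectangle (the AP row interval x the lateral row interval); the
    emitted cross-section is the largest inscribed axis-aligned ellipse of
    that rectangle, and the sections are lofted into a surface.

``reconstruct_oblique``
    When only an oblique second view exists, the view separation theta is
    estimated from the apparent bifurcation angles (arccos of their ratio).
    Per-view centerlines are extracted by row-wise momentum (intensity
    centroid) averaging, the missing depths are recovered in closed form
    from ``argmin || X2 - Ry(theta) X1 ||``, and a circle of radius R(t)
    (the mean of the two views' half-width profiles) is swept along the
    fused 3D spline.

Shared conventions: masks use lower-left origin with rows mapping to world
Z; both views are put in correspondence through their shared vertical (row)
coordinate, which assumes the vessel is single-valued per row (true for the
gently curved supraclinoid segment emulated by the synthetic generator).
Angles are degrees at the interface, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateViewsError,
    GeometryError,
    MaskError,
    ReconstructionError,
)
from .geometry_synth import RadiusProfile, make_tube_mesh
from .masks import ProjectionMask, rasterize_polygons
from .meshes import INLET_CAP, OUTLET_CAP, WALL, SurfaceMesh, TubeMesh

__all__ = [
    "PlaneCurve",
    "SpaceCurve",
    "load_mask",
    "estimate_oblique_angle",
    "centerline_from_mask",
    "width_profile",
    "recover_depths",
    "reconstruct_orthogonal",
    "reconstruct_oblique",
    "stack_contours_to_mesh",
    "cap_openings",
    "extend_outlet",
    "scale_to_reference",
]


@dataclass
class PlaneCurve:
    """In-plane vessel centerline of one view.

    ``z`` is the shared vertical coordinate (mm, strictly increasing) and
    ``x`` the in-plane horizontal coordinate (mm).
    """

    z: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.z) != len(self.x) or len(self.z) < 2:
            raise ReconstructionError("curve needs matching z/x arrays (>= 2)")
        if not np.all(np.isfinite(self.z)) or not np.all(np.isfinite(self.x)):
            raise ReconstructionError("curve coordinates must be finite")
        if np.any(np.diff(self.z) <= 0):
            raise ReconstructionError("curve parameter must strictly increase")

    def resampled(self, z_new: np.ndarray) -> "PlaneCurve":
        return PlaneCurve(z_new, np.interp(z_new, self.z, self.x))


@dataclass
class SpaceCurve:
    """3D centerline with per-sample residual of the view-consistency fit."""

    t: np.ndarray
    xyz: np.ndarray
    residual_mm: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.residual_mm = np.asarray(self.residual_mm, dtype=float)
        if np.any(self.residual_mm < 0):
            raise ReconstructionError("residuals must be non-negative")


# ---------------------------------------------------------------------------
# mask ingestion
# ---------------------------------------------------------------------------


def load_mask(path, sidecar=None) -> ProjectionMask:
    """Load a PNG + JSON mask or a polygon-outline JSON file.

    Polygon files hold ``{"pixel_spacing_mm": ..., "view_angle_deg": ...,
    "polygons": [[[x, z], ...], ...]}`` in mm; rings are rasterized with
    the even-odd rule.
    """
    from pathlib import Path
    import json

    path = Path(path)
    if path.suffix.lower() == ".png":
        return ProjectionMask.from_png(path, sidecar)
    meta = json.loads(path.read_text())
    if "polygons" not in meta:
        raise MaskError("polygon file must contain a 'polygons' list")
    if "pixel_spacing_mm" not in meta:
        raise MaskError("polygon file is missing pixel_spacing_mm")
    return rasterize_polygons(
        meta["polygons"],
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        view_angle_deg=float(meta.get("view_angle_deg", 0.0)),
    )


# ---------------------------------------------------------------------------
# oblique-angle estimation
# ---------------------------------------------------------------------------


def estimate_oblique_angle(
    bif_angle_ap_deg: float, bif_angle_oblique_deg: float
) -> float:
    """Estimate the AP/oblique view separation from bifurcation angles.

    For a bifurcation lying in a vertical plane, rotating the view by theta
    shrinks the apparent opening angle; theta is approximated as
    ``arccos(angle_oblique / angle_ap)``, in degrees within [0, 90].
    """
    if bif_angle_ap_deg <= 0 or bif_angle_oblique_deg <= 0:
        raise ReconstructionError("bifurcation angles must be positive")
    ratio = bif_angle_oblique_deg / bif_angle_ap_deg
    if ratio > 1.0 + 1e-12:
        raise ReconstructionError(
            "oblique bifurcation angle cannot exceed the AP angle"
        )
    return float(np.degrees(np.arccos(min(ratio, 1.0))))


# ---------------------------------------------------------------------------
# per-view measurements
# ---------------------------------------------------------------------------


def _row_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) column runs of foreground in one row."""
    padded = np.concatenate([[0], row.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def _select_runs(mask: ProjectionMask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row foreground interval tracked by continuity.

    Returns (row indices, start cols, stop cols) for the trimmed row range.
    Rows with several runs (vessel self-overlap in projection) keep the run
    whose centroid is nearest the previous selection; the first row keeps
    the widest run.  Interior rows with no foreground are interpolated.
    """
    data = mask.data
    have = data.any(axis=1)
    rows = np.nonzero(have)[0]
    if len(rows) == 0:
        raise MaskError("mask has no foreground rows")
    r0, r1 = rows[0], rows[-1]
    idx, lo, hi = [], [], []
    prev_c = None
    for r in range(r0, r1 + 1):
        runs = _row_runs(data[r])
        if not runs:
            continue
        if prev_c is None:
            a, b = max(runs, key=lambda ab: ab[1] - ab[0])
        else:
            a, b = min(runs, key=lambda ab: abs(0.5 * (ab[0] + ab[1]) - prev_c))
        prev_c = 0.5 * (a + b)
        idx.append(r)
        lo.append(a)
        hi.append(b)
    idx = np.asarray(idx)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    full = np.arange(r0, r1 + 1)
    lo = np.interp(full, idx, lo)
    hi = np.interp(full, idx, hi)
    return full, lo, hi


def centerline_from_mask(mask: ProjectionMask) -> PlaneCurve:
    """Row-wise momentum (centroid) averaging of the tracked interval."""
    rows, lo, hi = _select_runs(mask)
    s = mask.pixel_spacing_mm
    # centroid of the uniform-intensity run: midpoint of [lo, hi)
    x = mask.origin_mm[0] + s * (0.5 * (lo + hi))
    z = mask.origin_mm[1] + s * (rows + 0.5)
    if len(rows) < 2:
        raise MaskError("mask too fragmented to track a centerline")
    return PlaneCurve(z, x)


def width_profile(mask: ProjectionMask, curve: PlaneCurve) -> RadiusProfile:
    """Half-width perpendicular to the local centerline tangent.

    The tracked row chord gives the in-row width (one pixel narrower than
    the pixel count, since rasterized runs include both boundary pixels);
    multiplying by the cosine of the local tangent's tilt from vertical
    converts it to the width perpendicular to the vessel course, so an
    inclined vessel is not overestimated.
    """
    rows, lo, hi = _select_runs(mask)
    s = mask.pixel_spacing_mm
    z = mask.origin_mm[1] + s * (rows + 0.5)
    chord = np.maximum(hi - lo - 1.0, 0.5) * s
    # the tangent tilt varies slowly; differentiating the raw (half-pixel
    # jittered) centroid row by row would swamp it in noise
    win = max(int(round(2.0 / s)), 3)
    x_smooth = _smooth(curve.x, win)
    dxdz = np.gradient(x_smooth, curve.z)
    tilt = np.interp(z, curve.z, dxdz)
    cos_a = 1.0 / np.sqrt(1.0 + tilt**2)
    radii = np.maximum(0.5 * chord * cos_a, 0.25 * s)
    t = (z - z[0]) / (z[-1] - z[0])
    return RadiusProfile(t, radii)


# ---------------------------------------------------------------------------
# depth recovery
# ---------------------------------------------------------------------------


def recover_depths(
    curve1: PlaneCurve, curve2: PlaneCurve, theta_deg: float
) -> tuple[SpaceCurve, SpaceCurve]:
    """Closed-form depths of the centerline from an AP/oblique curve pair.

    With view 1 frontal and view 2 rotated by theta about the vertical
    axis, the in-plane abscissae satisfy ``x2 = x1 cos(theta) + z1
    sin(theta)`` where ``z1`` is the view-1 depth.  Minimizing
    ``|| X2 - Ry(theta) X1 ||`` over the two depths therefore has the
    closed-form solution::

        z1 = (x2 - x1 cos(theta)) / sin(theta)
        z2 = -x1 sin(theta) + z1 cos(theta)

    and the leftover residual is the vertical mismatch ``|y2 - y1|`` (zero
    here because both curves are resampled to a common vertical grid).
    Returns the two space curves in their own view frames.
    """
    th = np.radians(theta_deg)
    if not 0.0 < theta_deg <= 90.0:
        raise DegenerateViewsError("theta must lie in (0, 90] degrees")
    if np.sin(th) < 1e-9:
        raise DegenerateViewsError("parallel views cannot resolve depth")
    z_lo = max(curve1.z[0], curve2.z[0])
    z_hi = min(curve1.z[-1], curve2.z[-1])
    if z_hi <= z_lo:
        raise ReconstructionError("views share no vertical overlap")
    n = max(len(curve1.z), len(curve2.z))
    z = np.linspace(z_lo, z_hi, n)
    c1, c2 = curve1.resampled(z), curve2.resampled(z)

    d1 = (c2.x - c1.x * np.cos(th)) / np.sin(th)
    d2 = -c1.x * np.sin(th) + d1 * np.cos(th)
    resid = np.zeros_like(z)  # vertical coordinates agree by construction
    t = (z - z[0]) / (z[-1] - z[0])
    sc1 = SpaceCurve(t, np.column_stack([c1.x, d1, z]), resid)
    sc2 = SpaceCurve(t, np.column_stack([c2.x, d2, z]), resid)
    return sc1, sc2


# ---------------------------------------------------------------------------
# surface reconstruction
# ---------------------------------------------------------------------------


def _loft_sections(
    centers: np.ndarray,
    semi_a: np.ndarray,
    semi_b: np.ndarray,
    z: np.ndarray,
    n_points: int = 32,
) -> SurfaceMesh:
    """Loft axis-aligned elliptical sections stacked along Z."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    cosp, sinp = np.cos(phi), np.sin(phi)
    n = len(z)
    verts = np.empty((n * n_points, 3))
    for i in range(n):
        verts[i * n_points : (i + 1) * n_points, 0] = centers[i, 0] + semi_a[i] * cosp
        verts[i * n_points : (i + 1) * n_points, 1] = centers[i, 1] + semi_b[i] * sinp
        verts[i * n_points : (i + 1) * n_points, 2] = z[i]
    faces = []
    for i in range(n - 1):
        for j in range(n_points):
            a = i * n_points + j
            b = i * n_points + (j + 1) % n_points
            c = (i + 1) * n_points + j
            d = (i + 1) * n_points + (j + 1) % n_points
            faces.append((a, b, d))
            faces.append((a, d, c))
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return a
    return ndimage.uniform_filter1d(a, size=window, mode="nearest")


def _noise_sigma(vals: np.ndarray) -> float:
    """Robust per-sample noise level from second differences.

    For a smooth signal plus white noise of standard deviation sigma, the
    second difference has standard deviation ``sqrt(6) * sigma``; the MAD
    makes the estimate insensitive to genuine curvature outliers.
    """
    d2 = np.diff(vals, n=2)
    if len(d2) == 0:
        return 0.0
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(mad / 0.6745 / np.sqrt(6.0))


def reconstruct_orthogonal(
    mask_ap: ProjectionMask,
    mask_lateral: ProjectionMask,
    n_points: int = 32,
    smooth_mm: float = 0.5,
) -> SurfaceMesh:
    """Inscribed-ellipse reconstruction from an orthogonal view pair.

    Per axial row, the intersection of the two back-projected silhouettes
    is the rectangle [x-interval] x [y-interval]; the emitted cross-section
    is its largest inscribed ellipse (axis-aligned, centred, semi-axes =
    half-widths).  A light moving-average over ~``smooth_mm`` suppresses
    single-pixel rasterization jitter before lofting.
    """
    dang = abs((mask_lateral.view_angle_deg - mask_ap.view_angle_deg) % 180.0)
    if abs(dang - 90.0) > 1e-6:
        raise ReconstructionError("views must be 90 degrees apart")
    s = mask_ap.pixel_spacing_mm
    if abs(mask_lateral.pixel_spacing_mm - s) > 1e-12:
        raise ReconstructionError("views must share one pixel spacing")

    rows_a, lo_a, hi_a = _select_runs(mask_ap)
    rows_l, lo_l, hi_l = _select_runs(mask_lateral)
    za = mask_ap.origin_mm[1] + s * (rows_a + 0.5)
    zl = mask_lateral.origin_mm[1] + s * (rows_l + 0.5)
    z_lo, z_hi = max(za[0], zl[0]), min(za[-1], zl[-1])
    if z_hi <= z_lo:
        raise ReconstructionError("views share no vertical overlap")
    keep = (za >= z_lo) & (za <= z_hi)
    z = za[keep]

    def interval(zq, zsrc, lo, hi, origin_u):
        # a run of pixels [lo, hi) covers pixel centres; the physical
        # interval is half a pixel narrower on each side
        a = origin_u + s * (np.interp(zq, zsrc, lo) + 0.5)
        b = origin_u + s * (np.interp(zq, zsrc, hi) - 0.5)
        return a, b

    ax0, ax1 = interval(z, za, lo_a, hi_a, mask_ap.origin_mm[0])
    ly0, ly1 = interval(z, zl, lo_l, hi_l, mask_lateral.origin_mm[0])

    w = max(int(round(smooth_mm / s)), 1)
    cx = _smooth(0.5 * (ax0 + ax1), w)
    cy = _smooth(0.5 * (ly0 + ly1), w)
    sa = _smooth(0.5 * (ax1 - ax0), w)
    sb = _smooth(0.5 * (ly1 - ly0), w)
    good = (sa > 0) & (sb > 0)
    if good.sum() < 2:
        raise ReconstructionError("row overlap too small to loft")
    centers = np.column_stack([cx[good], cy[good]])
    return _loft_sections(centers, sa[good], sb[good], z[good], n_points)


def reconstruct_oblique(
    mask_ap: ProjectionMask,
    mask_oblique: ProjectionMask,
    theta_deg: float,
    n_sections: int = 100,
    n_points: int = 32,
    smooth_mm: float = 0.8,
) -> TubeMesh:
    """Swept-circle reconstruction from an AP/oblique view pair.

    Centerlines come from row-wise momentum averaging, depths from the
    closed-form two-view minimizer, and the tube radius R(t) is the
    arithmetic mean of the two views' perpendicular half-width profiles.
    The fused 3D spline is swept with parallel-transported frames.
    """
    c1 = centerline_from_mask(mask_ap)
    c2 = centerline_from_mask(mask_oblique)
    sc1, sc2 = recover_depths(c1, c2, theta_deg)

    th = np.radians(theta_deg)
    # back-rotate view-2 into the world (view-1) frame and fuse
    x2, d2, z = sc2.xyz[:, 0], sc2.xyz[:, 1], sc2.xyz[:, 2]
    w2 = np.column_stack(
        [x2 * np.cos(th) - d2 * np.sin(th), x2 * np.sin(th) + d2 * np.cos(th), z]
    )
    fused = 0.5 * (sc1.xyz + w2)

    r1 = width_profile(mask_ap, c1)
    r2 = width_profile(mask_oblique, c2)
    t = sc1.t
    radii = 0.5 * (r1(t) + r2(t))

    # Rasterized centroids jitter by ~half a pixel, which a discrete sweep
    # would amplify into spurious curvature; smoothing splines scaled to
    # the noise of each coordinate recover the smooth vessel course.  The
    # in-plane abscissa carries plain centroid noise, while the recovered
    # depth amplifies it by 1/sin(theta), so the two are smoothed
    # separately (the vertical coordinate is exact).
    from scipy.interpolate import UnivariateSpline

    px = mask_ap.pixel_spacing_mm
    n = len(z)
    ts = np.linspace(0.0, 1.0, n_sections)
    zs = z[0] + ts * (z[-1] - z[0])
    # floor at half a pixel: quantized centroids under-report their own
    # noise in second differences
    sig_x = max(_noise_sigma(fused[:, 0]), 0.5 * px)
    sig_y = max(_noise_sigma(fused[:, 1]), 0.5 * px / np.sin(th))
    rr = np.interp(ts, t, radii)
    span = z[-1] - z[0]
    w = max(int(round(smooth_mm / (span / n_sections))), 1)
    rr = _smooth(rr, w)
    profile = RadiusProfile(ts, rr)
    # escalate smoothing if leftover jitter curvature would make the swept
    # surface self-intersect at the tube radius
    import warnings as _warnings

    for attempt in range(6):
        scale = 4.0**attempt
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            spl_x = UnivariateSpline(z, fused[:, 0], s=n * (scale * sig_x) ** 2, k=3)
            spl_y = UnivariateSpline(z, fused[:, 1], s=n * (scale * sig_y) ** 2, k=3)
        pts = np.column_stack([spl_x(zs), spl_y(zs), zs])
        try:
            return make_tube_mesh(pts, profile, n_circumferential=n_points)
        except GeometryError:
            if attempt == 5:
                raise
    raise AssertionError("unreachable")


def stack_contours_to_mesh(
    contours: list, slice_spacing_mm: float, n_points: int = 32
) -> SurfaceMesh:
    """Loft an ordered stack of planar polygons spaced along Z.

    Vertex correspondence between slices is established by angular
    resampling about each slice's centroid (adequate for the near-convex
    lumen sections of CTA data).
    """
    from shapely.geometry import Polygon

    if len(contours) < 2:
        raise ReconstructionError("need at least two contours")
    if slice_spacing_mm <= 0:
        raise ReconstructionError("slice spacing must be positive")
    rings = []
    for c in contours:
        c = np.asarray(c, dtype=float)
        if c.ndim != 2 or c.shape[0] < 3 or c.shape[1] != 2:
            raise ReconstructionError("each contour must be (k >= 3, 2)")
        if not Polygon(c).is_simple or Polygon(c).area <= 0:
            raise ReconstructionError("contour is self-intersecting or degenerate")
        ctr = c.mean(axis=0)
        ang = np.arctan2(c[:, 1] - ctr[1], c[:, 0] - ctr[0])
        order = np.argsort(ang)
        ang, cc = ang[order], c[order]
        rad = np.linalg.norm(cc - ctr, axis=1)
        phi = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
        rphi = np.interp(
            phi, np.concatenate([ang - 2 * np.pi, ang, ang + 2 * np.pi]),
            np.tile(rad, 3),
        )
        rings.append(ctr + np.column_stack([rphi * np.cos(phi), rphi * np.sin(phi)]))
    n = len(rings)
    verts = np.empty((n * n_points, 3))
    for i, ring in enumerate(rings):
        verts[i * n_points : (i + 1) * n_points, :2] = ring
        verts[i * n_points : (i + 1) * n_points, 2] = i * slice_spacing_mm
    faces = []
    for i in range(n - 1):
        for j in range(n_points):
            a = i * n_points + j
            b = i * n_points + (j + 1) % n_points
            c_ = (i + 1) * n_points + j
            d = (i + 1) * n_points + (j + 1) % n_points
            faces.append((a, b, d))
            faces.append((a, d, c_))
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# capping, extension, scaling
# ---------------------------------------------------------------------------


def _loop_plane(mesh: SurfaceMesh, loop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, outward unit normal) of a boundary loop."""
    pts = mesh.vertices[loop]
    ctr = pts.mean(axis=0)
    q = pts - ctr
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    n = vt[2]
    outward = ctr - mesh.vertices.mean(axis=0)
    if np.dot(n, outward) < 0:
        n = -n
    return ctr, n


def _fan_cap(mesh: SurfaceMesh, loop: np.ndarray, label: int) -> SurfaceMesh:
    """Close one boundary loop with a centroid fan carrying ``label``."""
    ctr, normal = _loop_plane(mesh, loop)
    verts = np.vstack([mesh.vertices, ctr])
    ci = len(mesh.vertices)
    ring = mesh.vertices[loop]
    e1 = ring[1] - ring[0]
    e2 = ring[2 % len(ring)] - ring[1]
    flip = np.dot(np.cross(e1, e2), normal) < 0
    faces = list(map(tuple, mesh.faces))
    face_labels = list(mesh.face_labels)
    m = len(loop)
    for k in range(m):
        a, b = int(loop[k]), int(loop[(k + 1) % m])
        tri = (a, ci, b) if flip else (a, b, ci)
        faces.append(tri)
        face_labels.append(label)
    return SurfaceMesh(verts, np.asarray(faces), np.asarray(face_labels))


def cap_openings(mesh: SurfaceMesh) -> SurfaceMesh:
    """Add planar triangulated plates over the two open ends.

    The lower-Z loop is labelled as the inlet plate, the other as the
    outlet, matching the proximal-inlet / distal-outlet convention.  The
    result is watertight.
    """
    loops = mesh.boundary_loops()
    if len(loops) != 2:
        raise GeometryError(
            f"expected exactly 2 boundary loops, found {len(loops)}"
        )
    z_means = [mesh.vertices[lp][:, 2].mean() for lp in loops]
    order = np.argsort(z_means)
    labels = {int(order[0]): INLET_CAP, int(order[1]): OUTLET_CAP}
    out = mesh
    for li, loop in enumerate(loops):
        out = _fan_cap(out, loop, labels[li])
    tm = out.as_trimesh()
    if not tm.is_watertight:
        raise GeometryError("capping failed to produce a watertight surface")
    if tm.volume < 0:  # global winding was inward; flip everything
        out.faces = out.faces[:, ::-1].copy()
    return out


def _outlet_loop(mesh: SurfaceMesh) -> np.ndarray:
    loops = mesh.boundary_loops()
    if not loops:
        raise GeometryError("mesh has no open boundary; cannot find outlet")
    z_means = [mesh.vertices[lp][:, 2].mean() for lp in loops]
    return loops[int(np.argmax(z_means))]


def extend_outlet(mesh: SurfaceMesh, length_mm: float) -> SurfaceMesh:
    """Extrude the outlet along its end tangent, preserving the section.

    Moves the outlet boundary away from the region of interest so that the
    outflow condition of a subsequent flow simulation cannot contaminate
    it.  Works on open tubes and on capped meshes (the outlet plate is
    removed, the wall extruded, and the plate restored).
    """
    if length_mm <= 0:
        raise GeometryError("extension length must be positive")
    capped = len(mesh.boundary_loops()) == 0
    work = mesh.copy()
    if capped:
        keep = work.face_labels != OUTLET_CAP
        if keep.all():
            raise GeometryError("capped mesh has no labelled outlet plate")
        work = SurfaceMesh(work.vertices, work.faces[keep], work.face_labels[keep])
        # drop the now-unreferenced cap centroid vertex lazily (harmless)
    loop = _outlet_loop(work)
    ctr, normal = _loop_plane(work, loop)
    new_idx = np.arange(len(work.vertices), len(work.vertices) + len(loop))
    new_verts = work.vertices[loop] + length_mm * normal
    verts = np.vstack([work.vertices, new_verts])
    faces = list(map(tuple, work.faces))
    labels = list(work.face_labels)
    m = len(loop)
    ring_map = {int(loop[k]): int(new_idx[k]) for k in range(m)}
    for k in range(m):
        a, b = int(loop[k]), int(loop[(k + 1) % m])
        a2, b2 = ring_map[a], ring_map[b]
        # loop order opposes face winding (see boundary_loops): the free
        # edge runs b->a in its wall face, so the new quad must use a->b
        faces.append((a, b, b2))
        faces.append((a, b2, a2))
        labels.append(WALL)
        labels.append(WALL)
    out = SurfaceMesh(verts, np.asarray(faces), np.asarray(labels))
    if capped:
        new_loop = _outlet_loop(out)
        out = _fan_cap(out, new_loop, OUTLET_CAP)
        tm = out.as_trimesh()
        if not tm.is_watertight:
            raise GeometryError("outlet extension failed to close the surface")
        if tm.volume < 0:
            out.faces = out.faces[:, ::-1].copy()
    return out


def _outlet_diameter(mesh: SurfaceMesh) -> float:
    if len(mesh.boundary_loops()) == 0:
        # capped: use the outlet plate's boundary ring
        cap = mesh.face_labels == OUTLET_CAP
        if not cap.any():
            raise GeometryError("no outlet found on capped mesh")
        ring = np.unique(mesh.faces[cap])
        pts = mesh.vertices[ring]
    else:
        pts = mesh.vertices[_outlet_loop(mesh)]
    ctr = pts.mean(axis=0)
    q = pts - ctr
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    uv = q @ vt[:2].T
    ang = np.arctan2(uv[:, 1], uv[:, 0])
    order = np.argsort(ang)
    uv = uv[order]
    x, y = uv[:, 0], uv[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise GeometryError("degenerate outlet section")
    return float(2.0 * np.sqrt(area / np.pi))


def scale_to_reference(mesh: SurfaceMesh, reference_diameter_mm: float) -> SurfaceMesh:
    """Isotropically scale so the mean outlet diameter hits the reference.

    Used to normalize reconstructions against a standard carotid terminus
    calibre when absolute image calibration is unreliable.
    """
    if reference_diameter_mm <= 0:
        raise GeometryError("reference diameter must be positive")
    d = _outlet_diameter(mesh)
    out = mesh.scaled(reference_diameter_mm / d)
    out.face_labels = mesh.face_labels.copy()
    return out
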