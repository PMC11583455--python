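"""Synthetic ground-truth vessels and their projections.

Every downstream stage (reconstruction, validation, CFD, post-processing)
is exercised on vessels generated here, so no patient imagery is needed.
The generator produces:

* curved, siphon-like tubes of 3-5 mm luminal diameter swept along a
  parametrized centerline with parallel-transported frames (no twist);
* optional blister-like bulges: smooth, cosine-tapered outward bumps on the
  tube wall, standing in for the small outpouching / berry-like sac of a
  blister aneurysm, with an "enlarge" operation for the digitally grown sac;
* orthographic binary silhouettes at arbitrary view angles about the
  vertical axis, emulating AP / lateral / oblique angiographic projections;
* a two-limb bifurcation phantom used to exercise the oblique-angle
  estimation rule.

World frame: the vertical axis is ``Z`` (shared image row axis across all
views); the AP viewing direction is ``+Y``; an oblique view rotates the
viewing direction about ``Z`` by its view angle.  Projection is parallel
beam: X-ray cone-beam divergence is deliberately not modelled, consistent
with the reconstruction math that consumes these images.

All functions are deterministic; ``seed`` arguments are accepted for API
uniformity and future noise models and do not change current outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy.interpolate import CubicSpline

from .errors import GeometryError, MaskError
from .masks import ProjectionMask
from .meshes import SurfaceMesh, TubeMesh

# Default luminal diameter (mm): centred in the 3-5 mm range typical of the
# supraclinoid internal carotid artery.
DEFAULT_DIAMETER_MM = 4.0

# Default siphon-like control points (mm): a gentle S-curve, monotone in Z so
# that every horizontal image row meets the vessel exactly once.
DEFAULT_SIPHON_CONTROL_POINTS = (
    (0.0, 0.0, 0.0),
    (1.0, 0.4, 10.0),
    (-1.0, -0.4, 20.0),
    (0.0, 0.0, 30.0),
)


@dataclass(frozen=True)
class CenterlineSpec:
    """Parametrized vessel course.

    kind : "straight" | "planar-arc" | "siphon-spline"
    length_mm : total length for straight/arc kinds
    control_points_mm : spline control points for "siphon-spline"
    n_samples : number of centerline samples (>= 2)
    arc_angle_deg : total turning angle for "planar-arc"
    """

    kind: str = "siphon-spline"
    length_mm: float = 30.0
    control_points_mm: Sequence = DEFAULT_SIPHON_CONTROL_POINTS
    n_samples: int = 200
    arc_angle_deg: float = 90.0

    def sample(self) -> np.ndarray:
        """Return (n_samples, 3) centerline points, uniform in arc length."""
        if self.n_samples < 2:
            raise GeometryError("need at least 2 centerline samples")
        n = self.n_samples
        if self.kind == "straight":
            z = np.linspace(0.0, self.length_mm, n)
            pts = np.column_stack([np.zeros(n), np.zeros(n), z])
        elif self.kind == "planar-arc":
            ang = np.radians(self.arc_angle_deg)
            if ang <= 0:
                raise GeometryError("arc angle must be positive")
            rho = self.length_mm / ang  # arc radius
            phi = np.linspace(0.0, ang, n)
            # starts at origin heading +Z, curving towards +X
            pts = np.column_stack(
                [rho * (1.0 - np.cos(phi)), np.zeros(n), rho * np.sin(phi)]
            )
        elif self.kind == "siphon-spline":
            cp = np.asarray(self.control_points_mm, dtype=float)
            if cp.ndim != 2 or cp.shape[0] < 2 or cp.shape[1] != 3:
                raise GeometryError("control points must be (k >= 2, 3)")
            chord = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
            )
            if chord[-1] <= 0:
                raise GeometryError("degenerate control polygon")
            # clamp the end tangents to the vertical: the segment enters and
            # leaves the field of view along its axis, so the inlet/outlet
            # plates cut it perpendicularly (and the caps stay axis-aligned)
            end_d = (0.0, 0.0, chord[-1])
            spl = CubicSpline(
                chord / chord[-1], cp, axis=0, bc_type=((1, end_d), (1, end_d))
            )
            dense = spl(np.linspace(0.0, 1.0, 40 * n))
            s = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
            )
            pts = np.empty((n, 3))
            for k in range(3):
                pts[:, k] = np.interp(np.linspace(0.0, s[-1], n), s, dense[:, k])
        else:
            raise GeometryError(f"unknown centerline kind {self.kind!r}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if not np.all(seg > 0):
            raise GeometryError("centerline samples must strictly advance")
        return pts


@dataclass(frozen=True)
class RadiusProfile:
    """Tube radius R(t) versus normalized parameter t in [0, 1], in mm."""

    t: np.ndarray
    radius_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "radius_mm", np.asarray(self.radius_mm, dtype=float))
        if len(self.t) != len(self.radius_mm) or len(self.t) < 2:
            raise GeometryError("radius profile needs matching t/R arrays (>=2)")
        if np.any(np.diff(self.t) <= 0):
            raise GeometryError("profile parameter must be strictly increasing")
        if np.any(self.radius_mm <= 0):
            raise GeometryError("radius must be positive everywhere")

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.t, self.radius_mm)

    @classmethod
    def constant(cls, radius_mm: float = DEFAULT_DIAMETER_MM / 2) -> "RadiusProfile":
        return cls(np.array([0.0, 1.0]), np.array([radius_mm, radius_mm]))

    @classmethod
    def linear(cls, r0_mm: float, r1_mm: float) -> "RadiusProfile":
        return cls(np.array([0.0, 1.0]), np.array([r0_mm, r1_mm]))


@dataclass(frozen=True)
class BlisterSpec:
    """Cosine-tapered outward bump standing in for a blister sac.

    t0 : bump centre along the tube parameter, in (0, 1)
    angular_position_deg : circumferential position (0 = dorsal = +X side
        of the local frame)
    height_mm : peak outward displacement
    longitudinal_extent_mm : full support length along the centerline
    circumferential_extent_deg : full angular support (< 360)
    """

    t0: float = 0.5
    angular_position_deg: float = 0.0
    height_mm: float = 0.6
    longitudinal_extent_mm: float = 3.5
    circumferential_extent_deg: float = 110.0

    def __post_init__(self) -> None:
        if not 0.0 < self.t0 < 1.0:
            raise GeometryError("bump centre t0 must lie in (0, 1)")
        if self.height_mm < 0:
            raise GeometryError("bump height must be non-negative")
        if self.longitudinal_extent_mm <= 0 or self.circumferential_extent_deg <= 0:
            raise GeometryError("bump extents must be positive")
        if self.circumferential_extent_deg >= 360.0:
            raise GeometryError("circumferential extent must be < 360 degrees")

    def scaled(self, factor: float) -> "BlisterSpec":
        if factor < 1:
            raise GeometryError("enlargement factor must be >= 1")
        return replace(
            self,
            height_mm=self.height_mm * factor,
            longitudinal_extent_mm=self.longitudinal_extent_mm * factor,
            circumferential_extent_deg=min(
                self.circumferential_extent_deg * factor, 359.0
            ),
        )


# ---------------------------------------------------------------------------
# tube construction
# ---------------------------------------------------------------------------


def _parallel_transport_frames(points: np.ndarray) -> np.ndarray:
    """(n, 3, 3) frames [tangent, n1, n2]; normals parallel-transported."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    frames = np.empty((len(points), 3, 3))
    # initial normal: any unit vector orthogonal to the first tangent
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tang[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = ref - np.dot(ref, tang[0]) * tang[0]
    n1 /= np.linalg.norm(n1)
    for i in range(len(points)):
        if i > 0:
            a, b = tang[i - 1], tang[i]
            axis = np.cross(a, b)
            s = np.linalg.norm(axis)
            c = float(np.clip(np.dot(a, b), -1.0, 1.0))
            if s > 1e-12:
                axis = axis / s
                ang = np.arctan2(s, c)
                n1 = (
                    n1 * np.cos(ang)
                    + np.cross(axis, n1) * np.sin(ang)
                    + axis * np.dot(axis, n1) * (1.0 - np.cos(ang))
                )
            n1 = n1 - np.dot(n1, tang[i]) * tang[i]
            n1 /= np.linalg.norm(n1)
        frames[i, 0] = tang[i]
        frames[i, 1] = n1
        frames[i, 2] = np.cross(tang[i], n1)
    return frames


def make_tube_mesh(
    centerline: CenterlineSpec | np.ndarray,
    radii: RadiusProfile | float = DEFAULT_DIAMETER_MM / 2,
    n_circumferential: int = 32,
    seed: int | None = None,
) -> TubeMesh:
    """Sweep a circle of radius R(t) along the centerline.

    The cross-section perpendicular to the local tangent is an exact circle;
    frames are parallel-transported so the tube carries no twist.  Raises
    :class:`GeometryError` when the radius exceeds the local radius of
    curvature (the swept surface would self-intersect).
    """
    if n_circumferential < 8:
        raise GeometryError("need at least 8 circumferential segments")
    pts = (
        centerline.sample()
        if isinstance(centerline, CenterlineSpec)
        else np.asarray(centerline, dtype=float)
    )
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise GeometryError("centerline must be (n >= 2, 3)")
    if isinstance(radii, (int, float)):
        radii = RadiusProfile.constant(float(radii))
    n = len(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = s / s[-1]
    r = radii(t)

    # curvature check: R(t) * kappa < 1 or the sweep self-intersects
    if n >= 3:
        d1 = np.gradient(pts, s, axis=0)
        d2 = np.gradient(d1, s, axis=0)
        kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(
            np.linalg.norm(d1, axis=1) ** 3, 1e-12
        )
        if np.any(r * kappa >= 0.999):
            raise GeometryError(
                "tube radius exceeds the centerline's radius of curvature"
            )

    frames = _parallel_transport_frames(pts)
    phi = np.linspace(0.0, 2.0 * np.pi, n_circumferential, endpoint=False)
    ring = np.stack([np.cos(phi), np.sin(phi)], axis=1)  # (n_circ, 2)
    verts = (
        pts[:, None, :]
        + r[:, None, None]
        * (
            ring[None, :, 0, None] * frames[:, None, 1, :]
            + ring[None, :, 1, None] * frames[:, None, 2, :]
        )
    ).reshape(-1, 3)

    faces = []
    nc = n_circumferential
    for i in range(n - 1):
        for j in range(nc):
            a = i * nc + j
            b = i * nc + (j + 1) % nc
            c = (i + 1) * nc + j
            d = (i + 1) * nc + (j + 1) % nc
            faces.append((a, b, d))
            faces.append((a, d, c))
    faces = np.asarray(faces, dtype=np.int64)

    return TubeMesh(
        vertices=verts,
        faces=faces,
        centerline=pts,
        frames=frames,
        radii=np.asarray(r, dtype=float),
        t=t,
        angles=phi,
        n_circ=nc,
    )


# ---------------------------------------------------------------------------
# blister bumps
# ---------------------------------------------------------------------------


def _bump_weights(mesh: TubeMesh, spec: BlisterSpec) -> np.ndarray:
    """Per-vertex cosine-taper weight in [0, 1]; exactly 0 outside support."""
    s = mesh.arc_length
    s0 = np.interp(spec.t0, mesh.t, s)
    half_long = spec.longitudinal_extent_mm / 2.0
    if s0 - half_long <= s[0] or s0 + half_long >= s[-1]:
        raise GeometryError("bump support must be strictly interior to the tube")
    u_t = (s - s0) / half_long  # per-ring longitudinal coordinate
    ang0 = np.radians(spec.angular_position_deg)
    half_circ = np.radians(spec.circumferential_extent_deg) / 2.0
    dphi = np.angle(np.exp(1j * (mesh.angles - ang0)))  # wrapped to (-pi, pi]
    u_p = dphi / half_circ

    w_t = np.where(np.abs(u_t) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u_t)), 0.0)
    w_p = np.where(np.abs(u_p) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u_p)), 0.0)
    return (w_t[:, None] * w_p[None, :]).reshape(-1)


def add_blister(mesh: TubeMesh, spec: BlisterSpec, seed: int | None = None) -> TubeMesh:
    """Displace the tube wall radially outward by a smooth tapered bump.

    Vertices outside the bump support are bit-identical to the input.  The
    cosine taper is C1, which keeps the perturbed surface manifold and
    avoids meshing artifacts at the bump rim.
    """
    if not isinstance(mesh, TubeMesh):
        raise GeometryError("add_blister requires a parametrized tube mesh")
    w = _bump_weights(mesh, spec)
    out = mesh.copy()
    if spec.height_mm == 0:
        return out
    centers = np.repeat(mesh.centerline, mesh.n_circ, axis=0)
    radial = mesh.vertices - centers
    rnorm = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = radial / np.maximum(rnorm, 1e-12)
    hot = w > 0
    out.vertices[hot] = mesh.vertices[hot] + (spec.height_mm * w[hot])[
        :, None
    ] * radial[hot]
    return out


def enlarge_blister(
    mesh: TubeMesh, spec: BlisterSpec, factor: float, seed: int | None = None
) -> TubeMesh:
    """Apply a blister whose height and extents are scaled by ``factor``.

    ``mesh`` is the *parent* (sac-free) tube; the parent wall outside the
    enlarged support is untouched, emulating the digital enlargement of an
    aneurysmal sac on a fixed parent artery.
    """
    return add_blister(mesh, spec.scaled(factor), seed=seed)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def _project_uv(vertices: np.ndarray, view_angle_deg: float) -> np.ndarray:
    """(n, 2) image-plane coordinates (u = horizontal, v = world Z)."""
    th = np.radians(view_angle_deg)
    u = vertices[:, 0] * np.cos(th) + vertices[:, 1] * np.sin(th)
    return np.column_stack([u, vertices[:, 2]])


def project_silhouette(
    mesh: SurfaceMesh,
    view_angle_deg: float = 0.0,
    pixel_spacing_mm: float = 0.1,
    bounds_mm: tuple | None = None,
    margin_px: int = 2,
    seed: int | None = None,
) -> ProjectionMask:
    """Orthographic binary silhouette of the mesh at a view angle.

    The silhouette is the union of all projected triangles.  ``bounds_mm``
    = (u_min, z_min, u_max, z_max) pins the image frame, which is required
    when comparing a reprojection pixel-by-pixel against an earlier mask.
    """
    if pixel_spacing_mm <= 0:
        raise MaskError("pixel spacing must be positive")
    uv = _project_uv(mesh.vertices, view_angle_deg)
    s = pixel_spacing_mm
    if bounds_mm is None:
        lo = uv.min(axis=0) - margin_px * s
        hi = uv.max(axis=0) + margin_px * s
    else:
        lo = np.asarray(bounds_mm[:2], dtype=float)
        hi = np.asarray(bounds_mm[2:], dtype=float)
    cols = max(int(np.ceil((hi[0] - lo[0]) / s)), 1)
    rows = max(int(np.ceil((hi[1] - lo[1]) / s)), 1)

    img = Image.new("1", (cols, rows), 0)
    draw = ImageDraw.Draw(img)
    # pixel (i, j) centre at lo + s*(j+1/2, i+1/2); PIL coordinates are
    # pixel-centre based, so world -> pixel is (x - lo)/s - 1/2
    # fill without outlines: outlined triangles would dilate the silhouette
    # by a pixel per side and bias every width measurement upstream
    px = (uv - lo) / s - 0.5
    tri = px[mesh.faces]
    for t in tri:
        coords = [tuple(pt) for pt in t]
        draw.polygon(coords, fill=1)
    data = np.asarray(img, dtype=bool)
    # sliver triangles can leave interior pinholes; a silhouette is the
    # filled union of the projections
    from scipy.ndimage import binary_fill_holes

    data = binary_fill_holes(data)
    if not data.any():
        raise MaskError("projection is empty")
    return ProjectionMask(
        data=data,
        pixel_spacing_mm=s,
        view_angle_deg=float(view_angle_deg) % 180.0,
        origin_mm=lo,
    )


# ---------------------------------------------------------------------------
# bifurcation phantom
# ---------------------------------------------------------------------------


def make_bifurcation_phantom(
    angle_deg: float,
    view_angle_deg: float = 0.0,
    limb_length_mm: float = 20.0,
    limb_width_mm: float = 1.5,
    pixel_spacing_mm: float = 0.1,
    seed: int | None = None,
) -> ProjectionMask:
    """Render two straight limbs opening symmetrically about the vertical.

    Both limbs lie in the vertical (X-Z) plane, so the apparent angle
    between them shrinks with the view angle; this is the geometry behind
    the arccos rule used to estimate the obliquity of a projection.
    """
    if not 0.0 < angle_deg < 180.0:
        raise GeometryError("bifurcation angle must lie in (0, 180) degrees")
    half = np.radians(angle_deg) / 2.0
    apex = np.zeros(3)
    dirs = [
        np.array([np.sin(half), 0.0, np.cos(half)]),
        np.array([-np.sin(half), 0.0, np.cos(half)]),
    ]
    ends = [apex + limb_length_mm * d for d in dirs]
    pts = _project_uv(np.vstack([apex, *ends]), view_angle_deg)
    s = pixel_spacing_mm
    lo = pts.min(axis=0) - 4 * s
    hi = pts.max(axis=0) + 4 * s
    cols = int(np.ceil((hi[0] - lo[0]) / s))
    rows = int(np.ceil((hi[1] - lo[1]) / s))
    img = Image.new("1", (cols, rows), 0)
    draw = ImageDraw.Draw(img)
    apex_px = tuple((pts[0] - lo) / s - 0.5)
    w = max(int(round(limb_width_mm / s)), 1)
    for end in pts[1:]:
        end_px = tuple((end - lo) / s - 0.5)
        draw.line([apex_px, end_px], fill=1, width=w)
    data = np.asarray(img, dtype=bool)
    return ProjectionMask(
        data=data,
        pixel_spacing_mm=s,
        view_angle_deg=float(view_angle_deg) % 180.0,
        origin_mm=lo,
    )


def measure_bifurcation_angle(mask: ProjectionMask) -> float:
    """Recover the 2D angle between the two limbs of a phantom mask.

    The apex is taken as the centroid of the lowest foreground rows; each
    limb direction is the principal axis of the pixels on its side of the
    apex.  Returns degrees.
    """
    rows, cols = np.nonzero(mask.data)
    z = mask.row_z_mm()[rows]
    u = mask.col_u_mm()[cols]
    z0 = z.min()
    apex_u = u[z <= z0 + 2 * mask.pixel_spacing_mm].mean()
    du, dz = u - apex_u, z - z0
    angles = []
    for side in (du >= 0, du < 0):
        if side.sum() < 3:
            angles.append(0.0)
            continue
        pts = np.column_stack([du[side], dz[side]])
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        d = vt[0]
        if d[1] < 0:
            d = -d
        angles.append(np.degrees(np.arctan2(abs(d[0]), d[1])))
    return float(angles[0] + angles[1])
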