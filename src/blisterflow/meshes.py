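"""Triangulated luminal surfaces.

All surface geometry in this package lives in millimetres.  ``SurfaceMesh``
is a thin container over vertex/face arrays; ``trimesh`` does the heavy
lifting (IO, watertightness, containment, plane sections) behind it.  Tube
surfaces produced by the synthetic generator additionally carry their sweep
parametrization (``TubeMesh``) so that blister bumps can be applied exactly.

Face labels distinguish the vessel wall from the inlet/outlet capping plates
added before CFD; the flow solver relies on them to locate its boundary
patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .errors import GeometryError

#: face label values
WALL, INLET_CAP, OUTLET_CAP = 0, 1, 2


@dataclass
class SurfaceMesh:
    """Triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array
    face_labels : (m,) uint8 array
        ``0`` wall, ``1`` inlet cap, ``2`` outlet cap.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")
        if self.face_labels is None:
            self.face_labels = np.zeros(len(self.faces), dtype=np.uint8)
        else:
            self.face_labels = np.asarray(self.face_labels, dtype=np.uint8)
            if len(self.face_labels) != len(self.faces):
                raise GeometryError("face_labels length must match faces")

    # -- conversions ---------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.face_labels.copy()
        )

    # -- basic measures ------------------------------------------------
    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def extents(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    def volume(self) -> float:
        """Enclosed volume in mm^3 (meaningful for watertight meshes)."""
        return float(abs(self.as_trimesh().volume))

    def euler_characteristic(self) -> int:
        tm = self.as_trimesh()
        return int(tm.euler_number)

    # -- boundary loops -------------------------------------------------
    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loops of the open boundary.

        Loops follow the winding induced by the faces, so extruding along a
        loop keeps triangle orientation consistent with the rest of the
        surface.
        """
        edges = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                edges.setdefault(key, []).append((a, b))
        # boundary edge: appears in exactly one face; keep its face direction
        nxt: dict[int, int] = {}
        for key, occ in edges.items():
            if len(occ) == 1:
                a, b = occ[0]
                nxt[int(b)] = int(a)  # traverse opposite to face direction
        loops: list[np.ndarray] = []
        seen: set[int] = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                if cur not in nxt:  # non-manifold boundary; bail out
                    break
                cur = nxt[cur]
            if len(loop) >= 3:
                loops.append(np.array(loop, dtype=np.int64))
        return loops

    # -- IO --------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write STL or PLY (binary little-endian), by file suffix."""
        path = Path(path)
        self.as_trimesh().export(str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    # -- transforms -----------------------------------------------------
    def translated(self, offset) -> "SurfaceMesh":
        out = self.copy()
        out.vertices = out.vertices + np.asarray(offset, dtype=float)
        return out

    def scaled(self, factor: float, origin=None) -> "SurfaceMesh":
        """Isotropic scaling about ``origin`` (default: vertex centroid)."""
        out = self.copy()
        o = (
            out.vertices.mean(axis=0)
            if origin is None
            else np.asarray(origin, dtype=float)
        )
        out.vertices = o + factor * (out.vertices - o)
        return out


@dataclass
class TubeMesh(SurfaceMesh):
    """A swept circular tube that remembers its own parametrization.

    ``vertices[i * n_circ + j]`` is the point at centerline sample ``i`` and
    circumferential angle ``angles[j]``.  The radial bump operations need
    this exact layout.
    """

    centerline: np.ndarray = field(default=None)  # type: ignore[assignment]
    frames: np.ndarray = field(default=None)  # type: ignore[assignment]
    radii: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: np.ndarray = field(default=None)  # type: ignore[assignment]
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_circ: int = 0

    def copy(self) -> "TubeMesh":
        return replace(
            self,
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            face_labels=self.face_labels.copy(),
            centerline=self.centerline.copy(),
            frames=self.frames.copy(),
            radii=self.radii.copy(),
            t=self.t.copy(),
            angles=self.angles.copy(),
        )

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])
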