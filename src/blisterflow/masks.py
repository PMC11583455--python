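"""Segmented angiographic projection masks.

A ``ProjectionMask`` is one binary silhouette of the vessel lumen as seen in
a single (parallel-beam) projection, together with the metadata needed to
map pixels back to world coordinates: pixel spacing, the view angle about
the vertical axis relative to the frontal (AP) view, and the world position
of the image's lower-left pixel.

Conventions
-----------
* image row index increases with world ``Z`` (origin lower-left);
* pixel ``(i, j)`` covers the world square centred at
  ``origin + (spacing * (j + 1/2), spacing * (i + 1/2))`` in (u, z);
* on disk a mask is an 8-bit PNG (0 background / 255 vessel) plus a JSON
  sidecar with the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import MaskError


@dataclass
class ProjectionMask:
    """One segmented 2D angiographic silhouette.

    Attributes
    ----------
    data : (rows, cols) bool array
        Foreground = vessel.  Row 0 is the *bottom* of the image.
    pixel_spacing_mm : float
    view_angle_deg : float
        Rotation of the viewing direction about the vertical axis relative
        to the AP view, in ``[0, 180)``.
    origin_mm : (2,) float
        World (u, z) of the lower-left corner of pixel (0, 0).
    """

    data: np.ndarray
    pixel_spacing_mm: float
    view_angle_deg: float = 0.0
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.pixel_spacing_mm <= 0:
            raise MaskError("pixel spacing must be positive")
        if self.data.ndim != 2:
            raise MaskError("mask data must be 2D")
        if not self.data.any():
            raise MaskError("mask has no foreground pixels")
        if not 0.0 <= self.view_angle_deg < 180.0:
            raise MaskError("view angle must lie in [0, 180) degrees")

    # -- coordinates -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def row_z_mm(self) -> np.ndarray:
        """World Z of each row's pixel centres."""
        s = self.pixel_spacing_mm
        return self.origin_mm[1] + s * (np.arange(self.data.shape[0]) + 0.5)

    def col_u_mm(self) -> np.ndarray:
        """In-plane horizontal coordinate of each column's pixel centres."""
        s = self.pixel_spacing_mm
        return self.origin_mm[0] + s * (np.arange(self.data.shape[1]) + 0.5)

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    def area_mm2(self) -> float:
        return self.foreground_count * self.pixel_spacing_mm**2

    # -- IO --------------------------------------------------------------
    def save(self, png_path: str | Path, sidecar_path: str | Path | None = None):
        png_path = Path(png_path)
        if sidecar_path is None:
            sidecar_path = png_path.with_suffix(".json")
        # PNG stores rows top-down; our row 0 is the bottom of the image.
        img = Image.fromarray(np.flipud(self.data).astype(np.uint8) * 255, mode="L")
        img.save(str(png_path))
        meta = {
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "view_angle_deg": self.view_angle_deg,
            "image_origin": "lower-left",
            "origin_mm": [float(self.origin_mm[0]), float(self.origin_mm[1])],
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))
        return png_path

    @classmethod
    def from_png(
        cls, png_path: str | Path, sidecar_path: str | Path | None = None
    ) -> "ProjectionMask":
        png_path = Path(png_path)
        if sidecar_path is None:
            sidecar_path = png_path.with_suffix(".json")
        meta = json.loads(Path(sidecar_path).read_text())
        if "pixel_spacing_mm" not in meta:
            raise MaskError("sidecar is missing pixel_spacing_mm")
        arr = np.asarray(Image.open(str(png_path)).convert("L"))
        data = np.flipud(arr > 127)
        return cls(
            data=data,
            pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
            view_angle_deg=float(meta.get("view_angle_deg", 0.0)),
            origin_mm=np.asarray(meta.get("origin_mm", (0.0, 0.0)), dtype=float),
        )


def rasterize_polygons(
    polygons: list,
    pixel_spacing_mm: float,
    view_angle_deg: float = 0.0,
    margin_px: int = 2,
) -> ProjectionMask:
    """Rasterize polygon outlines (mm coordinates) with the even-odd rule.

    Overlapping rings toggle foreground (XOR), so holes can be expressed as
    inner rings.
    """
    polys = [np.asarray(p, dtype=float) for p in polygons]
    if not polys or any(len(p) < 3 for p in polys):
        raise MaskError("need at least one polygon with >= 3 vertices")
    allpts = np.vstack(polys)
    s = pixel_spacing_mm
    lo = allpts.min(axis=0) - margin_px * s
    hi = allpts.max(axis=0) + margin_px * s
    cols = max(int(np.ceil((hi[0] - lo[0]) / s)), 1)
    rows = max(int(np.ceil((hi[1] - lo[1]) / s)), 1)
    acc = np.zeros((rows, cols), dtype=bool)
    from PIL import ImageDraw

    for p in polys:
        img = Image.new("1", (cols, rows), 0)
        draw = ImageDraw.Draw(img)
        px = [((x - lo[0]) / s - 0.5, (y - lo[1]) / s - 0.5) for x, y in p]
        draw.polygon(px, fill=1)
        acc ^= np.asarray(img, dtype=bool)
    if not acc.any():
        raise MaskError("rasterization produced an empty mask")
    return ProjectionMask(
        data=acc,
        pixel_spacing_mm=s,
        view_angle_deg=view_angle_deg,
        origin_mm=lo,
    )


def dice_coefficient(a: ProjectionMask, b: ProjectionMask) -> float:
    """Dice overlap of two masks defined on the same image frame."""
    if a.shape != b.shape:
        raise MaskError("masks must share the same image frame")
    inter = np.logical_and(a.data, b.data).sum()
    return 2.0 * inter / (a.foreground_count + b.foreground_count)
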