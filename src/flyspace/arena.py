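"""Arena geometry and point configurations.

The spatial domain for all social-space operations is a triangular chamber
described in physical units (mm).  Flies avoid the chamber walls, so every
point operation works on the *eroded* triangle: the inner parallel body of
the chamber at distance ``margin`` from each edge.  For a triangle that
inner body is again a triangle, obtained exactly by a homothety about the
incenter with ratio ``(r - margin) / r`` where ``r`` is the inradius.

Coordinates are planar (x, y) in mm.  Pixel-space conversions live in
:class:`ImageTransform`: 0-based pixel coordinates, origin at the top-left
corner, x rightward, y downward.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "ArenaGeometry",
    "PointConfig",
    "ImageTransform",
    "equilateral_arena",
    "DensityRangeWarning",
]

#: Adult Drosophila body length in mm; four body lengths = 1 cm, the
#: counting radius of the social-space metric.
DEFAULT_BODY_LENGTH_MM = 2.5

#: Chamber fly counts for which the social-space metric is density-robust.
ASSAY_N_RANGE = (12, 17)


class DensityRangeWarning(UserWarning):
    """Fly count outside the density-robust 12-17 assay range."""


def _triangle_area(vertices: np.ndarray) -> float:
    (x0, y0), (x1, y1), (x2, y2) = vertices
    return 0.5 * ((x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0))


@dataclass(frozen=True)
class ArenaGeometry:
    """Triangular chamber in physical units.

    Parameters
    ----------
    vertices
        Three planar points in mm, counter-clockwise.
    margin
        Wall-exclusion margin in mm; the usable domain is the triangle
        eroded inward by this distance.
    """

    vertices: np.ndarray
    margin: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (3, 2):
            raise ValueError(f"expected 3 planar vertices, got shape {v.shape}")
        signed = _triangle_area(v)
        if signed < 0:  # normalise to counter-clockwise
            v = v[::-1].copy()
            signed = -signed
        if signed <= 0:
            raise ValueError("arena vertices are collinear (zero area)")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        object.__setattr__(self, "vertices", v)
        v.setflags(write=False)
        if self.margin >= self.inradius:
            raise ValueError(
                f"margin {self.margin} mm leaves an empty arena "
                f"(inradius {self.inradius:.3f} mm)"
            )

    @property
    def area(self) -> float:
        """Chamber area in mm^2."""
        return _triangle_area(self.vertices)

    @property
    def side_lengths(self) -> np.ndarray:
        """Lengths of the sides opposite each vertex, in mm."""
        v = self.vertices
        return np.array(
            [
                np.linalg.norm(v[1] - v[2]),
                np.linalg.norm(v[2] - v[0]),
                np.linalg.norm(v[0] - v[1]),
            ]
        )

    @property
    def incenter(self) -> np.ndarray:
        s = self.side_lengths
        return (s[:, None] * self.vertices).sum(axis=0) / s.sum()

    @property
    def inradius(self) -> float:
        return 2.0 * self.area / self.side_lengths.sum()

    @property
    def eroded_vertices(self) -> np.ndarray:
        """Vertices of the margin-eroded triangle (homothety at incenter)."""
        ratio = (self.inradius - self.margin) / self.inradius
        c = self.incenter
        return c + ratio * (self.vertices - c)

    @property
    def eroded_area(self) -> float:
        return _triangle_area(self.eroded_vertices)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def eroded_polygon(self) -> Polygon:
        return Polygon(self.eroded_vertices)

    def contains(self, coords: np.ndarray, eroded: bool = True, atol: float = 1e-9) -> np.ndarray:
        """Vectorised point-in-arena test (boundary inclusive within ``atol``).

        Half-plane test against the CCW triangle edges; a point is inside
        iff it lies on the left of every edge (within ``atol``, scaled by
        the edge length so the tolerance is a distance).
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        v = self.eroded_vertices if eroded else self.vertices
        inside = np.ones(len(coords), dtype=bool)
        for i in range(3):
            a, b = v[i], v[(i + 1) % 3]
            edge = b - a
            cross = edge[0] * (coords[:, 1] - a[1]) - edge[1] * (coords[:, 0] - a[0])
            inside &= cross >= -atol * np.linalg.norm(edge)
        return inside

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full triangle in mm."""
        v = self.vertices
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())


def equilateral_arena(side: float = 80.0, margin: float = 2.0) -> ArenaGeometry:
    """Equilateral triangular chamber with one edge on the x-axis."""
    h = side * np.sqrt(3.0) / 2.0
    verts = np.array([[0.0, 0.0], [side, 0.0], [side / 2.0, h]])
    return ArenaGeometry(vertices=verts, margin=margin)


@dataclass
class PointConfig:
    """One settled group of fly positions with physical scale.

    A ``PointConfig`` is the unit of social-space analysis: it comes either
    from the point-process simulators or from calibrated image detections.
    """

    coords: np.ndarray
    arena: ArenaGeometry | None = None
    body_length: float = DEFAULT_BODY_LENGTH_MM
    seed: int | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.body_length <= 0:
            raise ValueError("body_length must be > 0")
        self.coords = c

    @property
    def n_flies(self) -> int:
        return len(self.coords)

    def warn_if_outside_assay_range(self) -> None:
        lo, hi = ASSAY_N_RANGE
        if not (lo <= self.n_flies <= hi):
            warnings.warn(
                f"{self.n_flies} flies is outside the density-robust "
                f"{lo}-{hi} assay range; the social-space metric may be "
                "density-sensitive",
                DensityRangeWarning,
                stacklevel=3,
            )

    def replace(self, **kwargs) -> "PointConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ImageTransform:
    """Affine mm <-> pixel mapping.

    Pixel convention: 0-based, origin top-left, x rightward, y downward.
    mm convention: mathematical, y upward.  The mapping flips y about the
    top of the padded arena bounding box and scales by ``px_per_mm``.
    """

    px_per_mm: float
    origin_mm: tuple[float, float]  # mm point mapped to pixel (pad, pad)
    y_top_mm: float                 # mm y mapped to pixel row `pad`
    pad_px: float = 0.0

    def mm_to_px(self, coords_mm: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords_mm, dtype=float))
        x = (c[:, 0] - self.origin_mm[0]) * self.px_per_mm + self.pad_px
        y = (self.y_top_mm - c[:, 1]) * self.px_per_mm + self.pad_px
        return np.column_stack([x, y])

    def px_to_mm(self, coords_px: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords_px, dtype=float))
        x = (c[:, 0] - self.pad_px) / self.px_per_mm + self.origin_mm[0]
        y = self.y_top_mm - (c[:, 1] - self.pad_px) / self.px_per_mm
        return np.column_stack([x, y])


def transform_for_arena(arena: ArenaGeometry, px_per_mm: float, pad_mm: float = 2.0) -> ImageTransform:
    """Build the mm->px mapping that frames ``arena`` with a pad."""
    xmin, ymin, xmax, ymax = arena.bounds()
    return ImageTransform(
        px_per_mm=px_per_mm,
        origin_mm=(xmin, ymin),
        y_top_mm=ymax,
        pad_px=pad_mm * px_per_mm,
    )


def image_shape_for_arena(arena: ArenaGeometry, px_per_mm: float, pad_mm: float = 2.0) -> tuple[int, int]:
    xmin, ymin, xmax, ymax = arena.bounds()
    h = int(np.ceil((ymax - ymin + 2 * pad_mm) * px_per_mm)) + 1
    w = int(np.ceil((xmax - xmin + 2 * pad_mm) * px_per_mm)) + 1
    return (h, w)
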