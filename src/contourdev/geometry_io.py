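"""Contour data model, JSON interchange format, and polygon rasterization.

The coordinate convention used throughout the package: all vertex and voxel
coordinates are physical millimetres; voxel index ``(0, 0, 0)`` maps to the
grid origin, which is the *center* of that voxel (not its corner).  Slices
are indexed along the third axis, 0-based.

The canonical interchange file is plain JSON::

    {"grid": {"origin": [x, y, z], "spacing": [dx, dy, dz],
              "shape": [nx, ny, nz]},
     "structures": [{"name": "...", "role": "reference" | "analysed",
                     "slices": {"0": [[[x, y], ...], ...]}}]}

Each polygon is an ordered vertex list, implicitly closed (the last vertex
connects back to the first).  Multiple polygons on one slice combine under
the even-odd rule, which supports disjoint segments and holes (ring-shaped
structures with a void interior) without any hole flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath

logger = logging.getLogger(__name__)

__all__ = [
    "ImageGrid",
    "StructureContours",
    "BinaryMask",
    "ContourFormatError",
    "GeometryError",
    "GridMismatchError",
    "read_contours",
    "write_contours",
    "rasterize",
    "refine_grid",
    "polygon_area",
]


class ContourFormatError(ValueError):
    """Raised when a contour file does not conform to the JSON schema."""


class GeometryError(ValueError):
    """Raised for geometrically invalid inputs (bad polygons, bad slices)."""


class GridMismatchError(ValueError):
    """Raised when images or masks on different grids/modes are combined."""


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of the voxel lattice.

    Parameters
    ----------
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    spacing : tuple of float
        Per-axis voxel size in mm, ``(dx, dy, dz)``.  ``dz`` may differ
        from the in-plane spacing (anisotropic MR is the typical case).
    shape : tuple of int
        Voxel counts per axis, ``(nx, ny, nz)``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    #: axis that indexes slices (fixed)
    slice_axis: int = field(default=2, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise GeometryError("grid origin, spacing and shape must have 3 entries")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"grid spacings must be > 0, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise GeometryError(f"grid shape entries must be >= 1, got {self.shape}")

    @property
    def n_slices(self) -> int:
        return self.shape[2]

    @property
    def in_plane_diagonal(self) -> float:
        """Diagonal of one voxel within a slice, mm."""
        return float(np.hypot(self.spacing[0], self.spacing[1]))

    @property
    def physical_diagonal(self) -> float:
        """Diagonal extent of the whole grid, mm; cap for distance values."""
        ext = (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return float(max(np.linalg.norm(ext), self.in_plane_diagonal))

    def slice_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane voxel-center coordinate axes ``(xs, ys)`` in mm."""
        xs = self.origin[0] + self.spacing[0] * np.arange(self.shape[0])
        ys = self.origin[1] + self.spacing[1] * np.arange(self.shape[1])
        return xs, ys

    def slice_points(self) -> np.ndarray:
        """All in-plane voxel centers as an ``(nx * ny, 2)`` array (mm)."""
        xs, ys = self.slice_coordinates()
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (mm^2)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _clean_polygon(raw, structure: str, slice_index: int, poly_index: int) -> np.ndarray:
    v = np.asarray(raw, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ContourFormatError(
            f"structure {structure!r}, slice {slice_index}, polygon {poly_index}: "
            f"vertices must be an (n, 2) array of in-plane mm coordinates"
        )
    # tolerate an explicitly repeated closing vertex
    if len(v) > 1 and np.array_equal(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise ContourFormatError(
            f"structure {structure!r}, slice {slice_index}, polygon {poly_index}: "
            f"a closed contour needs at least 3 vertices, got {len(v)}"
        )
    if not np.isfinite(v).all():
        raise ContourFormatError(
            f"structure {structure!r}, slice {slice_index}, polygon {poly_index}: "
            f"non-finite vertex coordinate"
        )
    if polygon_area(v) == 0.0:
        raise ContourFormatError(
            f"structure {structure!r}, slice {slice_index}, polygon {poly_index}: "
            f"polygon has zero area"
        )
    return v


@dataclass
class StructureContours:
    """One delineated structure: closed polygons grouped by 0-based slice.

    ``slices`` maps slice index to a list of ``(n, 2)`` vertex arrays in
    physical mm.  Vertex winding order is irrelevant (even-odd semantics).
    ``role`` is ``"analysed"`` or ``"reference"``.
    """

    name: str
    slices: dict[int, list[np.ndarray]]
    role: str = "analysed"

    def __post_init__(self) -> None:
        if self.role not in ("analysed", "reference"):
            raise ContourFormatError(
                f"structure {self.name!r}: role must be 'analysed' or 'reference', "
                f"got {self.role!r}"
            )
        cleaned: dict[int, list[np.ndarray]] = {}
        for k, polys in self.slices.items():
            k = int(k)
            cleaned[k] = [
                _clean_polygon(p, self.name, k, i) for i, p in enumerate(polys)
            ]
        self.slices = cleaned

    @property
    def contoured_slices(self) -> frozenset[int]:
        """Slice indices that carry at least one polygon."""
        return frozenset(k for k, polys in self.slices.items() if polys)

    def slice_edges(self, slice_index: int) -> tuple[np.ndarray, np.ndarray]:
        """All polygon edges on a slice as ``(starts, ends)`` arrays."""
        starts, ends = [], []
        for poly in self.slices.get(slice_index, []):
            starts.append(poly)
            ends.append(np.roll(poly, -1, axis=0))
        if not starts:
            return np.empty((0, 2)), np.empty((0, 2))
        return np.vstack(starts), np.vstack(ends)


@dataclass
class BinaryMask:
    """Delineation image: one bit per voxel, 1 inside the structure."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )


# ---------------------------------------------------------------------------
# JSON interchange


def read_contours(path) -> tuple[list[StructureContours], ImageGrid]:
    """Read a contour file; returns all structures (mm vertices) and the grid.

    Unknown top-level keys are ignored with a logged warning.  Malformed
    content raises :class:`ContourFormatError` naming the offending
    structure/slice.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ContourFormatError(f"{path}: malformed JSON: {exc}") from exc

    if not isinstance(doc, dict) or "grid" not in doc:
        raise ContourFormatError(f"{path}: missing top-level 'grid' block")
    for key in doc:
        if key not in ("grid", "structures"):
            logger.warning("%s: ignoring unknown top-level key %r", path, key)

    g = doc["grid"]
    try:
        grid = ImageGrid(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["shape"]))
    except (KeyError, TypeError, GeometryError) as exc:
        raise ContourFormatError(f"{path}: invalid grid block: {exc}") from exc

    structures = []
    for entry in doc.get("structures", []):
        try:
            name = entry["name"]
            slices = {
                int(k): [np.asarray(p, dtype=float) for p in polys]
                for k, polys in entry.get("slices", {}).items()
            }
        except (KeyError, TypeError, ValueError) as exc:
            raise ContourFormatError(f"{path}: invalid structure entry: {exc}") from exc
        structures.append(
            StructureContours(name=name, slices=slices, role=entry.get("role", "analysed"))
        )
    return structures, grid


def write_contours(structures, grid: ImageGrid, path) -> None:
    """Write structures and grid to the canonical JSON format.

    Round-trips through :func:`read_contours` vertex-exactly (floats are
    serialized at full ``repr`` precision).
    """
    doc = {
        "grid": {
            "origin": list(grid.origin),
            "spacing": list(grid.spacing),
            "shape": list(grid.shape),
        },
        "structures": [
            {
                "name": s.name,
                "role": s.role,
                "slices": {
                    str(k): [p.tolist() for p in polys]
                    for k, polys in sorted(s.slices.items())
                },
            }
            for s in structures
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Rasterization


def _min_dist_to_segments(points, starts, ends, point_chunk=8192, edge_chunk=512):
    """Min Euclidean distance from each point to any segment, vectorized.

    Chunked over both points and edges to bound memory.
    """
    points = np.asarray(points, dtype=float)
    out = np.empty(len(points))
    for p0 in range(0, len(points), point_chunk):
        pts = points[p0 : p0 + point_chunk]
        d2 = np.full(len(pts), np.inf)
        for e0 in range(0, len(starts), edge_chunk):
            a = starts[e0 : e0 + edge_chunk]
            ab = ends[e0 : e0 + edge_chunk] - a
            denom = np.einsum("ij,ij->i", ab, ab)
            denom = np.where(denom == 0.0, 1.0, denom)
            ap = pts[:, None, :] - a[None, :, :]
            t = np.clip(np.einsum("pej,ej->pe", ap, ab) / denom, 0.0, 1.0)
            diff = ap - t[..., None] * ab[None, :, :]
            d2 = np.minimum(d2, np.einsum("pej,pej->pe", diff, diff).min(axis=1))
        out[p0 : p0 + point_chunk] = np.sqrt(d2)
    return out


def _even_odd_inside(points: np.ndarray, polygons) -> np.ndarray:
    """Even-odd membership: XOR of per-polygon point-in-polygon tests.

    XOR of simple-polygon membership is exactly the even-odd rule on the
    combined edge set, so a polygon listed twice cancels and an inner ring
    carves a hole.
    """
    inside = np.zeros(len(points), dtype=bool)
    for poly in polygons:
        verts = np.vstack([poly, poly[:1]])
        codes = np.full(len(verts), _MplPath.LINETO, dtype=np.uint8)
        codes[0] = _MplPath.MOVETO
        codes[-1] = _MplPath.CLOSEPOLY
        inside ^= _MplPath(verts, codes).contains_points(points)
    return inside


def rasterize(structure: StructureContours, grid: ImageGrid) -> BinaryMask:
    """Draw the delineation image: 1 where the voxel center is inside.

    Membership is center-in-polygon under the even-odd rule applied jointly
    to all polygons of a slice; a center lying exactly on a polygon edge
    counts as inside (deterministic tie-break).  Slices without polygons
    are all-zero.
    """
    nz = grid.shape[2]
    values = np.zeros(grid.shape, dtype=bool)
    points = grid.slice_points()
    for k, polys in structure.slices.items():
        if not 0 <= k < nz:
            raise GeometryError(
                f"structure {structure.name!r}: slice {k} outside grid with "
                f"{nz} slices"
            )
        if not polys:
            continue
        inside = _even_odd_inside(points, polys)
        starts, ends = structure.slice_edges(k)
        scale = max(1.0, float(np.abs(np.vstack([starts, ends])).max()))
        on_edge = _min_dist_to_segments(points, starts, ends) <= 1e-9 * scale
        values[:, :, k] = (inside | on_edge).reshape(grid.shape[:2])
    return BinaryMask(grid=grid, values=values)


def refine_grid(grid: ImageGrid, factor: int) -> ImageGrid:
    """In-plane supersampling: divide dx, dy by ``factor``, keep the extent.

    Voxel centers of the refined grid include all original centers, so the
    origin is unchanged.  The slice axis is untouched.
    """
    if factor < 1 or int(factor) != factor:
        raise GeometryError(f"refinement factor must be a positive integer, got {factor}")
    f = int(factor)
    if f == 1:
        return grid
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.spacing
    return ImageGrid(
        origin=grid.origin,
        spacing=(dx / f, dy / f, dz),
        shape=((nx - 1) * f + 1, (ny - 1) * f + 1, nz),
    )
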