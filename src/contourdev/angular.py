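"""Angular (polar) collapse of deviation maps for topographic analysis.

Each slice's deviation map is reduced to one value per angle: the maximal
deviation found along the ray from a chosen contour center, restricted to
the region of contour disagreement.  Stacking the per-slice profiles gives
a compact slice-by-angle picture of where on the structure's surface the
observers disagree.

Angle convention (matching radiological display): 0° points anterior
(image top, the -y direction), -90° to the patient's right (image right,
+x), +90° left, and ±180° posterior.  Bins cover (-180°, 180°].

The center choice strongly influences the result for eccentric or complex
shapes; it is therefore always recorded alongside the profile.  A ray that
exits and re-enters the disagreement region contributes the maximum over
*all* its samples inside the region, which can blur (but never exaggerate)
the spatial attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry_io import BinaryMask, GeometryError
from .deviation import DeviationImage

__all__ = [
    "AngularProfile",
    "angular_profile",
    "centroid_center",
    "assemble_matrix",
    "write_matrix_csv",
]


@dataclass
class AngularProfile:
    """Per-angle maximal deviation (mm) on one slice.

    ``values`` holds NaN for missing bins: slices without contours, or
    angles whose ray never meets the disagreement region.  Missing is never
    encoded as 0 — a 0 means *measured* perfect agreement.
    """

    slice_index: int
    center: tuple[float, float]
    step: float
    angles: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.angles.shape != self.values.shape:
            raise ValueError("angles and values must align")


def _bin_centers(step: float) -> np.ndarray:
    if step <= 0 or not float(360.0 / step).is_integer():
        raise ValueError(f"angular step must divide 360, got {step}")
    n = int(round(360.0 / step))
    return -180.0 + step * (np.arange(n) + 1)


def _ray_directions(angles_deg: np.ndarray) -> np.ndarray:
    """Unit in-plane direction for each angle: 0° -> (0,-1), -90° -> (1,0)."""
    rad = np.deg2rad(angles_deg)
    return np.stack([-np.sin(rad), -np.cos(rad)], axis=-1)


def angular_profile(
    dd: DeviationImage,
    delta_i: BinaryMask,
    slice_index: int,
    center: tuple[float, float],
    step: float = 1.0,
) -> AngularProfile:
    """Maximal deviation per angle bin on one slice.

    Rays are cast from ``center`` (mm) at radial increments of half the
    minimum in-plane spacing out to the grid edge.  The deviation is
    sampled with bilinear interpolation of the masked product DD * delta_i,
    so values outside the disagreement region can never influence the
    profile; membership itself uses nearest-neighbor lookup (interpolating
    a binary mask would manufacture fractional membership).  Bins whose
    ray never meets the region are missing (NaN).
    """
    grid = dd.grid
    if delta_i.grid != grid:
        raise GeometryError("deviation image and disagreement mask grids differ")
    if not 0 <= slice_index < grid.shape[2]:
        raise GeometryError(f"slice {slice_index} outside grid with {grid.shape[2]} slices")
    angles = _bin_centers(step)

    xs, ys = grid.slice_coordinates()
    cx, cy = float(center[0]), float(center[1])
    if not (xs[0] - grid.spacing[0] / 2 <= cx <= xs[-1] + grid.spacing[0] / 2
            and ys[0] - grid.spacing[1] / 2 <= cy <= ys[-1] + grid.spacing[1] / 2):
        raise GeometryError(f"center ({cx}, {cy}) mm lies outside the grid extent")

    if slice_index not in dd.valid_slices:
        return AngularProfile(slice_index, (cx, cy), step, angles, np.full(angles.shape, np.nan))

    dr = min(grid.spacing[0], grid.spacing[1]) / 2.0
    corners = np.array([[xs[0], ys[0]], [xs[0], ys[-1]], [xs[-1], ys[0]], [xs[-1], ys[-1]]])
    r_max = float(np.linalg.norm(corners - [cx, cy], axis=1).max())
    radii = np.arange(0.0, r_max + dr, dr)

    dirs = _ray_directions(angles)                      # (a, 2)
    pts = np.array([cx, cy]) + radii[None, :, None] * dirs[:, None, :]  # (a, r, 2)
    fx = (pts[..., 0] - grid.origin[0]) / grid.spacing[0]
    fy = (pts[..., 1] - grid.origin[1]) / grid.spacing[1]

    # nearest-neighbor membership of the disagreement region
    ix = np.round(fx).astype(int)
    iy = np.round(fy).astype(int)
    in_grid = (ix >= 0) & (ix < grid.shape[0]) & (iy >= 0) & (iy < grid.shape[1])
    member = np.zeros(fx.shape, dtype=bool)
    dmask = delta_i.values[:, :, slice_index]
    member[in_grid] = dmask[ix[in_grid], iy[in_grid]]

    field = np.where(dmask, dd.values[:, :, slice_index], 0.0)
    sampled = ndimage.map_coordinates(
        field, [fx.ravel(), fy.ravel()], order=1, mode="nearest",
    ).reshape(fx.shape)

    sampled = np.where(member, sampled, -np.inf)
    values = sampled.max(axis=1)
    values[~member.any(axis=1)] = np.nan
    return AngularProfile(slice_index, (cx, cy), step, angles, values)


def centroid_center(mask: BinaryMask, slice_index: int) -> tuple[float, float]:
    """Center of gravity of the set voxels of one mask slice, in mm."""
    if not 0 <= slice_index < mask.grid.shape[2]:
        raise GeometryError(
            f"slice {slice_index} outside grid with {mask.grid.shape[2]} slices"
        )
    sl = mask.values[:, :, slice_index]
    if not sl.any():
        raise GeometryError(f"slice {slice_index} has no set voxels; centroid undefined")
    ix, iy = np.nonzero(sl)
    return (
        float(mask.grid.origin[0] + mask.grid.spacing[0] * ix.mean()),
        float(mask.grid.origin[1] + mask.grid.spacing[1] * iy.mean()),
    )


def assemble_matrix(
    profiles: list[AngularProfile],
    n_slices: int | None = None,
) -> pd.DataFrame:
    """Stack profiles into a slice-by-angle matrix (rows = slices).

    Slices without a profile appear as all-missing rows, so the matrix
    always spans slices ``0 .. n_slices-1`` (default: up to the largest
    profiled slice).  All profiles must share the angular binning.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    seen: set[int] = set()
    for p in profiles:
        if p.step != ref.step or not np.array_equal(p.angles, ref.angles):
            raise ValueError("profiles use inconsistent angular binning")
        if p.slice_index in seen:
            raise ValueError(f"duplicate profile for slice {p.slice_index}")
        seen.add(p.slice_index)
    if n_slices is None:
        n_slices = max(seen) + 1
    matrix = np.full((n_slices, len(ref.angles)), np.nan)
    for p in profiles:
        if p.slice_index >= n_slices:
            raise ValueError(f"profile slice {p.slice_index} exceeds n_slices={n_slices}")
        matrix[p.slice_index] = p.values
    return pd.DataFrame(matrix, index=pd.RangeIndex(n_slices, name="slice"),
                        columns=ref.angles)


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """CSV export: header row of bin centers, NA for missing cells."""
    matrix.to_csv(path, na_rep="NA", float_format="%.6g")
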