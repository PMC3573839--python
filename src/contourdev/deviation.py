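"""Distance-deviation images, disagreement regions, and scalar summaries.

Given signed distance images D_i of the compared contours, the deviation at
a voxel x is

* ``|D_1(x) - D_2(x)|`` for a pair,
* ``sqrt(mean_i (D_i(x) - D_R(x))^2)`` against a reference contour R, and
* the population standard deviation of ``{D_i(x)}`` when no reference
  exists (deviations around the mean distance image).

All statistics are restricted to *valid slices* — slices contoured by every
structure entering the comparison.  The region of contour disagreement
``delta_i`` (voxels covered by some but not all of the M delineations)
carries the maximum deviation; the union region ``i_hat`` of all
delineations is the averaging domain for the mean deviation.  For M = 2 the
maximal deviation equals the symmetric Hausdorff distance between the two
contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import BinaryMask, GridMismatchError, ImageGrid
from .distance_maps import DistanceImage, _check_same_lattice, mean_distance_image

__all__ = [
    "DeviationImage",
    "ScalarSummary",
    "dd_pair",
    "dd_vs_reference",
    "dd_std",
    "disagreement_region",
    "union_region",
    "summarize",
]


@dataclass
class DeviationImage:
    """Non-negative per-voxel deviation (mm) with its validity bookkeeping.

    ``kind`` is ``"pair"``, ``"vs_reference"`` or ``"std"``; ``n_analysed``
    is N, the number of analysed contours (excluding any reference).
    Voxels outside ``valid_slices`` are NaN.
    """

    grid: ImageGrid
    values: np.ndarray
    kind: str
    n_analysed: int
    valid_slices: frozenset[int]

    def __post_init__(self) -> None:
        if self.kind not in ("pair", "vs_reference", "std"):
            raise ValueError(f"unknown deviation kind {self.kind!r}")
        if self.kind == "pair" and self.n_analysed != 1:
            raise ValueError("pair deviation has n_analysed = 1 by definition")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"deviation shape {self.values.shape} != grid {self.grid.shape}"
            )
        self.valid_slices = frozenset(int(k) for k in self.valid_slices)

    def slice_valid(self, k: int) -> bool:
        return k in self.valid_slices


@dataclass
class ScalarSummary:
    """Overall scalar estimates of contour disagreement.

    ``dd_max`` is the maximal deviation over the disagreement region (the
    Hausdorff distance when two contours are compared); ``dd_mean`` the
    average deviation over the union of all delineated regions.
    """

    dd_max: float
    dd_mean: float
    n_voxels_union: int
    n_voxels_disagreement: int

    def as_dict(self) -> dict:
        return {
            "dd_max_mm": self.dd_max,
            "dd_mean_mm": self.dd_mean,
            "n_voxels_union": self.n_voxels_union,
            "n_voxels_disagreement": self.n_voxels_disagreement,
        }


def _mask_invalid(values: np.ndarray, grid: ImageGrid, valid: frozenset[int]) -> np.ndarray:
    keep = np.zeros(grid.shape[2], dtype=bool)
    keep[list(valid)] = True
    values[:, :, ~keep] = np.nan
    return values


def dd_pair(d1: DistanceImage, d2: DistanceImage) -> DeviationImage:
    """Pairwise distance deviation ``|D1 - D2|``; symmetric in its arguments."""
    _check_same_lattice([d1, d2])
    valid = d1.contoured_slices & d2.contoured_slices
    values = np.abs(d1.values - d2.values)
    return DeviationImage(
        grid=d1.grid, values=_mask_invalid(values, d1.grid, valid),
        kind="pair", n_analysed=1, valid_slices=valid,
    )


def dd_vs_reference(
    analysed: list[DistanceImage],
    reference: DistanceImage,
    sample_variance: bool = False,
) -> DeviationImage:
    """RMS deviation of N analysed distance images from the reference one.

    Follows the population form (divide by N); ``sample_variance=True``
    switches to N-1.  With a single analysed image this reduces exactly to
    :func:`dd_pair`.
    """
    if not analysed:
        raise ValueError("need at least one analysed distance image")
    _check_same_lattice([reference, *analysed])
    valid = frozenset.intersection(
        reference.contoured_slices, *[d.contoured_slices for d in analysed]
    )
    n = len(analysed)
    if n == 1 and not sample_variance:
        values = np.abs(analysed[0].values - reference.values)
    else:
        denom = n - 1 if sample_variance else n
        if denom < 1:
            raise ValueError("sample variance needs at least two analysed images")
        sq = np.stack([(d.values - reference.values) ** 2 for d in analysed])
        # sorting makes the reduction independent of input ordering
        values = np.sqrt(np.sort(sq, axis=0).sum(axis=0) / denom)
    return DeviationImage(
        grid=reference.grid, values=_mask_invalid(values, reference.grid, valid),
        kind="vs_reference", n_analysed=n, valid_slices=valid,
    )


def dd_std(
    analysed: list[DistanceImage],
    sample_variance: bool = False,
) -> DeviationImage:
    """Per-voxel standard deviation of distances when no reference exists.

    Deviations are taken around the mean distance image; the population
    form (divide by N) is the default.  For two images this is exactly half
    their absolute difference.
    """
    n = len(analysed)
    if n < 2:
        raise ValueError("standard deviation needs at least two analysed images")
    _check_same_lattice(analysed)
    valid = frozenset.intersection(*[d.contoured_slices for d in analysed])
    if n == 2 and not sample_variance:
        values = np.abs(analysed[0].values - analysed[1].values) / 2.0
    else:
        mean = mean_distance_image(analysed)
        sq = np.stack([(d.values - mean.values) ** 2 for d in analysed])
        denom = n - 1 if sample_variance else n
        values = np.sqrt(np.sort(sq, axis=0).sum(axis=0) / denom)
        # identical distances must give exactly 0, not rounding residue of
        # the mean; clamp voxels whose values all coincide
        stack = np.stack([d.values for d in analysed])
        values[np.ptp(stack, axis=0) == 0.0] = 0.0
    return DeviationImage(
        grid=analysed[0].grid, values=_mask_invalid(values, analysed[0].grid, valid),
        kind="std", n_analysed=n, valid_slices=valid,
    )


def _check_masks(masks, minimum: int) -> None:
    if len(masks) < minimum:
        raise ValueError(f"need at least {minimum} masks, got {len(masks)}")
    for m in masks[1:]:
        if m.grid != masks[0].grid:
            raise GridMismatchError("masks live on different grids")


def disagreement_region(masks: list[BinaryMask]) -> BinaryMask:
    """Voxels covered by at least one but not all of the M delineations."""
    _check_masks(masks, 2)
    total = np.sum([m.values for m in masks], axis=0)
    return BinaryMask(grid=masks[0].grid, values=(total > 0) & (total < len(masks)))


def union_region(masks: list[BinaryMask]) -> BinaryMask:
    """Union of all delineated regions; the averaging domain for dd_mean."""
    _check_masks(masks, 1)
    return BinaryMask(
        grid=masks[0].grid,
        values=np.logical_or.reduce([m.values for m in masks]),
    )


def summarize(dd: DeviationImage, masks: list[BinaryMask]) -> ScalarSummary:
    """Scalar summary: max over the disagreement region, mean over the union.

    ``masks`` are the M delineation masks of every compared structure,
    reference included when present.  Statistics run over the deviation's
    valid slices only.  Perfect agreement (empty disagreement region)
    yields ``dd_max = 0``; an empty union region is an error.
    """
    _check_masks(masks, 1)
    if masks[0].grid != dd.grid:
        raise GridMismatchError("deviation image and masks live on different grids")
    keep = np.zeros(dd.grid.shape[2], dtype=bool)
    keep[list(dd.valid_slices)] = True

    delta = disagreement_region(masks).values if len(masks) >= 2 else np.zeros(dd.grid.shape, bool)
    delta = delta & keep[None, None, :]
    union = union_region(masks).values & keep[None, None, :]
    if not union.any():
        raise ValueError("union region is empty on the valid slices")

    dd_max = float(dd.values[delta].max()) if delta.any() else 0.0
    dd_mean = float(dd.values[union].mean())
    return ScalarSummary(
        dd_max=dd_max,
        dd_mean=dd_mean,
        n_voxels_union=int(union.sum()),
        n_voxels_disagreement=int(delta.sum()),
    )
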