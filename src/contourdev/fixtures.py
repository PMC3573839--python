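"""Synthetic contour sets covering the geometric regimes of interest.

The generator produces the shapes a contouring study actually stresses:
smooth convex outlines (circle, ellipse), shapes with pronounced extremes
(cosine stars), ring targets with a void interior (annulus, even-odd),
rigidly shifted pairs, and families of observer contours scattered around
a reference.  The observer model defaults to a per-contour constant radial
offset drawn from a normal distribution, which makes the expected
deviation statistics analytically predictable (the per-voxel standard
deviation of distances equals the standard deviation of the drawn
offsets); a smooth low-order Fourier perturbation is available when shape
variability rather than pure size variability is wanted.

All randomness flows from the single explicit ``seed`` in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import ImageGrid, StructureContours

__all__ = ["FixtureSpec", "make_fixture", "KINDS"]

KINDS = ("circle", "ellipse", "star", "annulus", "offset_pair", "perturbed_family")
_STOCHASTIC = ("perturbed_family",)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic contour set.

    ``radius2`` is the second semi-axis for ellipses and the inner radius
    for annuli (defaults: 0.6 x and 0.5 x ``radius``).  ``sigma`` (mm) and
    ``n_observers`` drive the ``perturbed_family`` kind, whose ``seed`` is
    mandatory.  The grid is derived from the generated shapes plus
    ``margin``; the anisotropic default slice thickness mirrors a typical
    MR protocol.
    """

    kind: str
    radius: float = 10.0
    radius2: float | None = None
    n_spikes: int = 6
    spike_depth: float = 2.5
    offset: tuple[float, float] = (3.0, 0.0)
    base_kind: str = "circle"
    sigma: float = 1.5
    n_observers: int = 20
    perturbation: str = "offset"
    n_vertices: int = 720
    seed: int | None = None
    center: tuple[float, float] = (0.0, 0.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.9)
    margin: float = 5.0
    n_slices: int = 1
    slices: tuple[int, ...] = (0,)

    def validate(self) -> None:
        problems = []
        if self.kind not in KINDS:
            problems.append(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.radius <= 0:
            problems.append(f"radius must be > 0, got {self.radius}")
        if self.radius2 is not None and self.radius2 <= 0:
            problems.append(f"radius2 must be > 0, got {self.radius2}")
        if self.n_vertices < 16:
            problems.append(f"n_vertices must be >= 16, got {self.n_vertices}")
        if self.kind == "star":
            if self.n_spikes < 2:
                problems.append(f"n_spikes must be >= 2, got {self.n_spikes}")
            if not 0 < self.spike_depth < self.radius:
                problems.append(
                    f"spike_depth must be in (0, radius), got {self.spike_depth}"
                )
        if self.kind == "annulus":
            inner = self.radius2 if self.radius2 is not None else 0.5 * self.radius
            if inner >= self.radius:
                problems.append(
                    f"annulus inner radius {inner} must be smaller than outer {self.radius}"
                )
        if self.kind == "perturbed_family":
            if self.n_observers < 1:
                problems.append(f"n_observers must be >= 1, got {self.n_observers}")
            if self.sigma < 0:
                problems.append(f"sigma must be >= 0, got {self.sigma}")
            if self.perturbation not in ("offset", "fourier"):
                problems.append(
                    f"perturbation must be 'offset' or 'fourier', got {self.perturbation!r}"
                )
        if self.kind in _STOCHASTIC and self.seed is None:
            problems.append(f"seed is mandatory for stochastic kind {self.kind!r}")
        if self.kind == "offset_pair" and self.base_kind not in ("circle", "ellipse", "star", "square"):
            problems.append(f"unsupported base_kind {self.base_kind!r}")
        if any(s <= 0 for s in self.spacing):
            problems.append(f"spacing entries must be > 0, got {self.spacing}")
        if problems:
            raise ValueError("invalid fixture spec: " + "; ".join(problems))


def _theta(n: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(n) / n


def _radial_polygon(center, radii, theta) -> np.ndarray:
    return np.column_stack(
        [center[0] + radii * np.cos(theta), center[1] + radii * np.sin(theta)]
    )


def _base_polygon(spec: FixtureSpec, kind: str) -> np.ndarray:
    th = _theta(spec.n_vertices)
    c = spec.center
    if kind == "circle":
        return _radial_polygon(c, np.full_like(th, spec.radius), th)
    if kind == "ellipse":
        b = spec.radius2 if spec.radius2 is not None else 0.6 * spec.radius
        return np.column_stack(
            [c[0] + spec.radius * np.cos(th), c[1] + b * np.sin(th)]
        )
    if kind == "star":
        return _radial_polygon(
            c, spec.radius + spec.spike_depth * np.cos(spec.n_spikes * th), th
        )
    if kind == "square":
        r = spec.radius
        return np.array(
            [[c[0] - r, c[1] - r], [c[0] + r, c[1] - r],
             [c[0] + r, c[1] + r], [c[0] - r, c[1] + r]]
        )
    raise ValueError(f"unknown base shape {kind!r}")


def _grid_for(polygon_sets, spec: FixtureSpec) -> ImageGrid:
    all_pts = np.vstack([p for polys in polygon_sets for p in polys])
    dx, dy, dz = spec.spacing
    xmin, ymin = all_pts.min(axis=0) - spec.margin
    xmax, ymax = all_pts.max(axis=0) + spec.margin
    nx = int(np.ceil((xmax - xmin) / dx)) + 1
    ny = int(np.ceil((ymax - ymin) / dy)) + 1
    return ImageGrid(
        origin=(float(xmin), float(ymin), 0.0),
        spacing=(dx, dy, dz),
        shape=(nx, ny, max(spec.n_slices, max(spec.slices) + 1)),
    )


def make_fixture(spec: FixtureSpec) -> tuple[list[StructureContours], ImageGrid]:
    """Generate the contour set and a grid that covers it with a margin.

    Deterministic for a given spec and seed: the same spec always yields
    vertex-identical output.
    """
    spec.validate()
    th = _theta(spec.n_vertices)

    if spec.kind in ("circle", "ellipse", "star"):
        polys = [[_base_polygon(spec, spec.kind)]]
        names, roles = [spec.kind], ["analysed"]
    elif spec.kind == "annulus":
        inner_r = spec.radius2 if spec.radius2 is not None else 0.5 * spec.radius
        outer = _radial_polygon(spec.center, np.full_like(th, spec.radius), th)
        inner = _radial_polygon(spec.center, np.full_like(th, inner_r), th)
        polys = [[outer, inner]]
        names, roles = ["annulus"], ["analysed"]
    elif spec.kind == "offset_pair":
        a = _base_polygon(spec, spec.base_kind)
        b = a + np.asarray(spec.offset, dtype=float)
        polys = [[a], [b]]
        names, roles = ["shape_a", "shape_b"], ["analysed", "analysed"]
    elif spec.kind == "perturbed_family":
        rng = np.random.default_rng(spec.seed)
        reference = _radial_polygon(spec.center, np.full_like(th, spec.radius), th)
        polys, names, roles = [[reference]], ["reference"], ["reference"]
        offsets = rng.normal(0.0, spec.sigma, size=spec.n_observers)
        for i, eps in enumerate(offsets):
            radii = np.full_like(th, spec.radius + eps)
            if spec.perturbation == "fourier":
                # smooth low-order shape wobble on top of the size offset
                for harmonic in range(2, 6):
                    amp = spec.sigma / (2.0 * harmonic)
                    radii = radii + rng.normal(0, amp) * np.cos(
                        harmonic * th + rng.uniform(0, 2 * np.pi)
                    )
            polys.append([_radial_polygon(spec.center, radii, th)])
            names.append(f"observer_{i + 1:02d}")
            roles.append("analysed")
    else:  # pragma: no cover - validate() already rejects
        raise ValueError(f"unknown kind {spec.kind!r}")

    grid = _grid_for(polys, spec)
    structures = [
        StructureContours(
            name=name,
            role=role,
            slices={int(k): [p.copy() for p in slice_polys] for k in spec.slices},
        )
        for name, role, slice_polys in zip(names, roles, polys)
    ]
    return structures, grid
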