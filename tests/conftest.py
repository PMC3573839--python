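"""Shared geometric helpers and fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from contourdev import ImageGrid, StructureContours


def circle_polygon(cx=0.0, cy=0.0, r=10.0, n=360) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def star_polygon(cx=0.0, cy=0.0, r=10.0, depth=2.5, spikes=6, n=360) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    rad = r + depth * np.cos(spikes * th)
    return np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])


def ellipse_polygon(cx=0.0, cy=0.0, a=10.0, b=6.0, phi=0.0, n=360) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    x, y = a * np.cos(th), b * np.sin(th)
    c, s = np.cos(phi), np.sin(phi)
    return np.column_stack([cx + c * x - s * y, cy + s * x + c * y])


def structure(name: str, *polys, slice_index=0, role="analysed") -> StructureContours:
    return StructureContours(name, {slice_index: list(polys)}, role=role)


def grid_around(polys, spacing=(1.0, 1.0, 1.0), margin=5.0, n_slices=1) -> ImageGrid:
    """Unit-test grid covering the given polygons with a margin."""
    pts = np.vstack(list(polys))
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    nx = int(np.ceil((hi[0] - lo[0]) / spacing[0])) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / spacing[1])) + 1
    return ImageGrid((float(lo[0]), float(lo[1]), 0.0), spacing, (nx, ny, n_slices))


def densify_polygon(poly: np.ndarray, ds: float = 0.2) -> np.ndarray:
    """Resample polygon edges at roughly ds spacing (Hausdorff oracle input)."""
    pts = []
    closed = np.vstack([poly, poly[:1]])
    for a, b in zip(closed[:-1], closed[1:]):
        length = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(length / ds)))
        t = np.arange(n) / n
        pts.append(a + t[:, None] * (b - a))
    return np.vstack(pts)


@pytest.fixture(scope="session")
def concentric_pair():
    """Circles of radii 10 and 12 mm about a shared center: the analytic
    constant-deviation case (|D1 - D2| = 2 mm everywhere)."""
    inner = structure("inner", circle_polygon(r=10.0, n=720))
    outer = structure("outer", circle_polygon(r=12.0, n=720))
    grid = grid_around([circle_polygon(r=12.0, n=64)], margin=5.0)
    return inner, outer, grid


@pytest.fixture(scope="session")
def offset_squares():
    """Congruent 20 mm squares offset by (3, 0) mm; Hausdorff distance 3."""
    sq = np.array([[0.0, 0.0], [20.0, 0.0], [20.0, 20.0], [0.0, 20.0]])
    a = structure("a", sq)
    b = structure("b", sq + [3.0, 0.0])
    grid = grid_around([sq, sq + [3.0, 0.0]], margin=5.0)
    return a, b, grid
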