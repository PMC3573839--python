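"""HSV overlay rendering and angular heatmaps.

The medical image keeps its familiar grayscale appearance as the HSV value
channel; the deviation is coded as hue, running from blue (agreement) to
red (the cap, default 5 mm); deviations beyond the cap get a distinct dark
purple.  Saturation is a fixed chroma level chosen only to separate the two
information channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .deviation import DeviationImage

__all__ = [
    "OverlaySpec",
    "render_overlay",
    "render_angular_heatmap",
    "robust_window",
    "save_png",
]


@dataclass(frozen=True)
class OverlaySpec:
    """Color coding of deviation values.

    ``cap`` (mm) saturates the ramp; ``hue_low``/``hue_high`` are the hue
    angles (degrees) for 0 mm and for the cap.  The default 240° -> 0°
    ramp runs blue through cyan/green/yellow to red.  ``over_cap_color``
    is the RGB triple used verbatim for values beyond the cap.
    """

    cap: float = 5.0
    hue_low: float = 240.0
    hue_high: float = 0.0
    saturation: float = 0.8
    over_cap_color: tuple[float, float, float] = (0.35, 0.0, 0.40)

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValueError(f"cap must be > 0 mm, got {self.cap}")
        for h in (self.hue_low, self.hue_high):
            if not 0.0 <= h < 360.0:
                raise ValueError(f"hue {h} outside [0, 360)")
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError(f"saturation {self.saturation} outside [0, 1]")

    def hue_of(self, dd_mm: np.ndarray) -> np.ndarray:
        """Hue (degrees) for clamped deviation values — a monotone ramp."""
        t = np.clip(np.asarray(dd_mm, dtype=float) / self.cap, 0.0, 1.0)
        return self.hue_low + t * (self.hue_high - self.hue_low)


def robust_window(volume: np.ndarray, p_low: float = 1.0, p_high: float = 99.0):
    """Per-volume grayscale display window (percentiles), so a single
    bright slice does not dim the rest."""
    finite = np.asarray(volume, dtype=float)
    finite = finite[np.isfinite(finite)]
    lo, hi = np.percentile(finite, [p_low, p_high])
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def _normalize(img: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return np.clip((np.asarray(img, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def render_overlay(
    image_slice: np.ndarray,
    dd: DeviationImage,
    slice_index: int,
    spec: OverlaySpec = OverlaySpec(),
    window=None,
) -> np.ndarray:
    """Render one slice: grayscale as V, deviation as H, fixed S.

    ``image_slice`` is the raw grayscale slice, indexed ``[ix, iy]`` like
    the deviation values.  On slices where the deviation is invalid the
    saturation drops to 0, leaving the pure grayscale image.  Returns an
    ``(nx, ny, 3)`` float RGB array in [0, 1].
    """
    image_slice = np.asarray(image_slice, dtype=float)
    dd_slice = dd.values[:, :, slice_index]
    if image_slice.shape != dd_slice.shape:
        raise ValueError(
            f"grayscale slice {image_slice.shape} and deviation slice "
            f"{dd_slice.shape} differ in shape"
        )
    if not np.isfinite(image_slice).all():
        raise ValueError("grayscale slice contains non-finite values")
    if window is None:
        window = robust_window(image_slice)
    v = _normalize(image_slice, window)

    if slice_index not in dd.valid_slices:
        hsv = np.stack([np.zeros_like(v), np.zeros_like(v), v], axis=-1)
        return hsv_to_rgb(hsv)

    h = spec.hue_of(dd_slice) / 360.0
    s = np.full_like(v, spec.saturation)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    over = dd_slice > spec.cap
    rgb[over] = spec.over_cap_color
    return rgb


def render_angular_heatmap(matrix, spec: OverlaySpec = OverlaySpec()) -> np.ndarray:
    """Render the slice-by-angle matrix with the same ramp as the overlays.

    Missing cells are white; cells beyond the cap take ``over_cap_color``.
    Accepts the DataFrame from ``assemble_matrix`` or a plain 2D array;
    returns an ``(n_slices, n_bins, 3)`` float RGB array.
    """
    values = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if values.size == 0:
        raise ValueError("empty angular matrix")
    h = spec.hue_of(np.nan_to_num(values)) / 360.0
    s = np.full_like(h, spec.saturation)
    v = np.ones_like(h)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    rgb[np.isnan(values)] = (1.0, 1.0, 1.0)
    rgb[values > spec.cap] = spec.over_cap_color
    return rgb


def save_png(rgb: np.ndarray, path, transpose: bool = True, upscale: int = 1) -> None:
    """Write a float RGB array to PNG.

    With ``transpose`` (default) the array is taken in ``[ix, iy]`` index
    order and flipped so +x runs right and +y runs down in the image.
    """
    from PIL import Image

    arr = np.asarray(rgb, dtype=float)
    if transpose:
        arr = np.transpose(arr, (1, 0, 2))
    if upscale > 1:
        arr = np.repeat(np.repeat(arr, upscale, axis=0), upscale, axis=1)
    Image.fromarray((np.clip(arr, 0, 1) * 255).round().astype(np.uint8)).save(path)
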