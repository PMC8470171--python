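"""Raster encodings of induction curves for 2D convolutional classifiers.

The two image-input model variants "see" the plotted transient rather than
its numeric values, one with a linear time axis and one with a logarithmic
one.  Rendering is deliberately minimal and bit-deterministic: single
channel, y min-max scaled per image, binary 1-px Bresenham stroke, no axes,
ticks, margins or anti-aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CurveDataset, InductionCurve
from .transforms import NormalizedCurve

__all__ = ["CurveImage", "curve_to_image", "dataset_to_images", "save_png"]


class RenderError(ValueError):
    """Curve cannot be rendered under the requested settings."""


@dataclass(frozen=True)
class CurveImage:
    """Single-channel raster of one transient, intensities in {0, 1}."""

    pixels: np.ndarray  # (height, width) float array
    axis_scale: str  # "linear" or "log"
    ec_label: str = "control"
    concentration: float = 0.0
    replicate_id: int = 0


def _bresenham(r0: int, c0: int, r1: int, c1: int):
    """Integer line raster from (r0, c0) to (r1, c1), inclusive."""
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r0 < r1 else -1
    sc = 1 if c0 < c1 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        yield r, c
        if r == r1 and c == c1:
            return
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr


def _curve_values_times(curve) -> tuple[np.ndarray, np.ndarray, dict]:
    if isinstance(curve, InductionCurve):
        return curve.fluorescence, curve.time.times, {
            "ec_label": curve.ec_label,
            "concentration": curve.concentration,
            "replicate_id": curve.replicate_id,
        }
    if isinstance(curve, NormalizedCurve):
        return curve.values, curve.time.times, {
            "ec_label": curve.ec_label,
            "concentration": curve.concentration,
            "replicate_id": curve.replicate_id,
        }
    raise TypeError("expected InductionCurve or NormalizedCurve")


def render(
    values: np.ndarray,
    times: np.ndarray,
    axis_scale: str = "linear",
    height: int = 128,
    width: int = 128,
) -> np.ndarray:
    """Rasterize one polyline; the array-level core of :func:`curve_to_image`."""
    if height < 16 or width < 16:
        raise RenderError("height and width must be >= 16")
    if axis_scale not in ("linear", "log"):
        raise RenderError(f"unknown axis_scale {axis_scale!r}")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise RenderError("values and times must align")
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise RenderError("flat curve cannot be rendered (y min-max undefined)")
    y = (values - lo) / (hi - lo)
    if axis_scale == "log":
        if np.any(times <= 0):
            raise RenderError("log time axis requires strictly positive times")
        x = np.log10(times)
    else:
        x = times
    x = (x - x[0]) / (x[-1] - x[0])
    cols = np.rint(x * (width - 1)).astype(int)
    rows = (height - 1) - np.rint(y * (height - 1)).astype(int)
    img = np.zeros((height, width), dtype=float)
    for i in range(len(cols) - 1):
        for r, c in _bresenham(rows[i], cols[i], rows[i + 1], cols[i + 1]):
            img[r, c] = 1.0
    img[rows[-1], cols[-1]] = 1.0
    return img


def curve_to_image(
    curve,
    axis_scale: str = "linear",
    height: int = 128,
    width: int = 128,
) -> CurveImage:
    """Render a transient (raw or normalized) to a fixed-size binary raster.

    The y axis is min-max scaled per image so image content encodes shape;
    x positions map grid times (or their log10) linearly onto [0, width-1].
    Deterministic: the same curve and settings give identical pixels.
    """
    values, times, meta = _curve_values_times(curve)
    pixels = render(values, times, axis_scale=axis_scale, height=height, width=width)
    return CurveImage(pixels=pixels, axis_scale=axis_scale, **meta)


def dataset_to_images(
    dataset: CurveDataset,
    axis_scale: str = "linear",
    height: int = 128,
    width: int = 128,
    values: np.ndarray | None = None,
) -> np.ndarray:
    """Render every sample; returns an (n, height, width) stack aligned with rows.

    ``values`` optionally substitutes a transformed matrix (e.g. min-max
    normalized) for the raw fluorescence; metadata alignment is unchanged.
    """
    mat = dataset.values if values is None else np.asarray(values, dtype=float)
    if mat.shape[0] != len(dataset):
        raise RenderError("substitute values must align with the dataset rows")
    times = dataset.time.times
    stack = np.zeros((mat.shape[0], height, width), dtype=float)
    for i in range(mat.shape[0]):
        try:
            stack[i] = render(
                mat[i], times, axis_scale=axis_scale, height=height, width=width
            )
        except RenderError as exc:
            row = dataset.meta.iloc[i]
            raise RenderError(
                f"sample {i} ({row['ec_label']}, {row['concentration']} ug/L, "
                f"replicate {row['replicate_id']}): {exc}"
            ) from exc
    return stack


def save_png(image: CurveImage, path) -> None:
    """Export one raster as an 8-bit grayscale PNG (inspection aid)."""
    from PIL import Image

    arr = (np.clip(image.pixels, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def export_pngs(
    dataset: CurveDataset,
    outdir,
    axis_scale: str = "linear",
    height: int = 128,
    width: int = 128,
) -> list[str]:
    """Write one PNG per sample, named <ec>_<concentration>_<replicate>.png.

    An inspection aid only — the classification pipeline passes pixel
    matrices directly.  Returns the written paths in dataset order.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(dataset)):
        img = curve_to_image(dataset.curve(i), axis_scale, height, width)
        name = f"{img.ec_label}_{img.concentration:g}_{img.replicate_id}.png"
        save_png(img, outdir / name)
        paths.append(str(outdir / name))
    return paths
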