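"""Deterministic PNG rendering of portraits and map-shaped arrays.

Three color modes mirror the three kinds of map:

* ``standard`` — the portrait's own min..max range mapped blue → green →
  red (major-homozygous, heterozygous, minor-homozygous ends of the score
  scale).  Invariant under positive affine rescaling of the values.
* ``waterline`` — diverging blue/white/red split exactly at 0, scaled by
  the largest magnitude; shows where scores sit above/below the dataset
  mean.
* ``correlation`` — diverging blue/white/red with the fixed range [-1, 1].

Rendering is pure numpy + Pillow so identical inputs give identical PNG
bytes.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .som import Portrait

__all__ = ["render_portrait", "render_array", "MODES"]

MODES = ("standard", "waterline", "correlation")

_BLUE = np.array([0, 0, 255.0])
_GREEN = np.array([0, 200.0, 0])
_RED = np.array([255.0, 0, 0])
_WHITE = np.array([255.0, 255.0, 255.0])


def _lerp(c0: np.ndarray, c1: np.ndarray, t: np.ndarray) -> np.ndarray:
    return c0[None, :] + (c1 - c0)[None, :] * t[:, None]


def _standard_rgb(t: np.ndarray) -> np.ndarray:
    """t in [0,1] -> blue..green..red."""
    lo = t <= 0.5
    out = np.empty((t.size, 3))
    out[lo] = _lerp(_BLUE, _GREEN, t[lo] * 2.0)
    out[~lo] = _lerp(_GREEN, _RED, (t[~lo] - 0.5) * 2.0)
    return out


def _diverging_rgb(t: np.ndarray) -> np.ndarray:
    """t in [-1,1] -> blue..white..red, white exactly at 0."""
    neg = t < 0
    out = np.empty((t.size, 3))
    out[neg] = _lerp(_WHITE, _BLUE, -t[neg])
    out[~neg] = _lerp(_WHITE, _RED, t[~neg])
    return out


def colorize(values: np.ndarray, mode: str) -> np.ndarray:
    """Map a flat value array to uint8 RGB rows according to ``mode``."""
    v = np.asarray(values, dtype=float).ravel()
    if mode == "standard":
        rng = np.ptp(v)
        t = np.full_like(v, 0.5) if rng == 0 else (v - v.min()) / rng
        rgb = _standard_rgb(t)
    elif mode == "waterline":
        scale = np.max(np.abs(v))
        t = np.zeros_like(v) if scale == 0 else v / scale
        rgb = _diverging_rgb(t)
    elif mode == "correlation":
        rgb = _diverging_rgb(np.clip(v, -1.0, 1.0))
    else:
        raise ValueError(f"unknown rendering mode {mode!r}; use one of {MODES}")
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_array(
    grid: np.ndarray, mode: str = "standard", pixel_scale: int = 8
) -> Image.Image:
    """Render any H x W array as a PNG-ready image."""
    grid = np.asarray(grid, dtype=float)
    h, w = grid.shape
    rgb = colorize(grid, mode).reshape(h, w, 3)
    img = Image.fromarray(rgb, mode="RGB")
    if pixel_scale != 1:
        img = img.resize((w * pixel_scale, h * pixel_scale), Image.NEAREST)
    return img


def render_portrait(
    portrait: Portrait, mode: str | None = None, pixel_scale: int = 8
) -> Image.Image:
    """Render a portrait in its own or an explicit color mode."""
    return render_array(portrait.grid, mode or portrait.mode, pixel_scale)
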