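"""Facial regions of interest and per-frame surface features.

Four of the twelve hypomimia markers describe texture dynamics of skin
areas (forehead lines, nose-root/glabellar lines, lateral canthal lines,
cheek surface variability).  This module derives those regions from the
landmarks, normalises frame intensity, highlights edges and reduces a
patch to a scalar Shannon entropy.

All region sizes are dimensionless multiples of the inner-eye-corner
distance (IED, landmarks 39-42), so the geometry is invariant to face
scale.  The exact multipliers, the 3x3 gradient kernels, the 64-bin
histogram and the 64x64 canonical patch are fixed, documented defaults:
what the downstream markers consume is only the *variability over time*
of the resulting scalar, which any consistent choice preserves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LandmarkSequence

__all__ = [
    "RegionSpec",
    "Patch",
    "REGION_SPECS",
    "luminance_normalize",
    "region_rect",
    "extract_patch",
    "edge_highlight",
    "patch_entropy",
]

#: BT.601 luma weights for RGB input
_LUMA = np.array([0.299, 0.587, 0.114])

#: default canonical patch edge, pixels
PATCH_SIZE = 64

#: default histogram bins for patch_entropy
ENTROPY_BINS = 64


@dataclass(frozen=True)
class RegionSpec:
    """Geometry of one surface region, in IED units.

    The region is an axis-aligned rectangle of ``width_ied`` x
    ``height_ied`` whose placement is computed by ``region_rect`` from the
    anchor landmarks.  ``patch_size`` is the canonical square resampling
    grid in pixels.
    """

    name: str
    width_ied: float
    height_ied: float
    patch_size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        if self.width_ied <= 0 or self.height_ied <= 0:
            raise ValueError("region size multipliers must be positive")
        if self.patch_size < 8:
            raise ValueError("canonical patch size must be at least 8 px")


REGION_SPECS: dict[str, RegionSpec] = {
    "forehead": RegionSpec("forehead", 1.6, 0.8),
    "nose_root": RegionSpec("nose_root", 0.5, 0.5),
    "lateral_canthal_L": RegionSpec("lateral_canthal_L", 0.5, 0.5),
    "lateral_canthal_R": RegionSpec("lateral_canthal_R", 0.5, 0.5),
    "cheek_L": RegionSpec("cheek_L", 0.7, 0.9),
    "cheek_R": RegionSpec("cheek_R", 0.7, 0.9),
}

#: placement parameters (IED units) used by region_rect
_FOREHEAD_GAP = 0.15     # gap between eyebrow apices and rectangle bottom
_CANTHAL_OFFSET = 0.35   # lateral offset of the canthal square centre
_CHEEK_DROP = 0.25       # gap between lower eyelid and cheek-rectangle top


@dataclass(frozen=True)
class Patch:
    """Canonical P x P luminance patch plus its frame-coverage fraction."""

    values: np.ndarray
    coverage: float

    @property
    def ok(self) -> bool:
        return self.coverage >= 0.5


def luminance_normalize(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to luminance with levels in [0, 1].

    Colour input goes through the standard BT.601 luma transform.  Integer
    images are divided by the maximum representable level of their dtype
    (255 for 8-bit) — deliberately not per-frame min-max, so temporal
    contrast changes stay visible to the entropy features.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(frame.dtype, np.integer):
        frame = frame.astype(float) / float(np.iinfo(frame.dtype).max)
    else:
        frame = frame.astype(float)
    if frame.ndim == 3:
        if frame.shape[2] >= 3:
            frame = frame[..., :3] @ _LUMA
        else:
            frame = frame[..., 0]
    elif frame.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got ndim={frame.ndim}")
    return np.clip(frame, 0.0, 1.0)


def _ied(coords_t: np.ndarray) -> float:
    d = float(np.linalg.norm(coords_t[39] - coords_t[42]))
    if d <= 0:
        raise ValueError("inner-eye-corner distance is zero (degenerate geometry)")
    return d


def region_rect(coords_t: np.ndarray, region: RegionSpec) -> tuple[float, float, float, float]:
    """Place a region for one frame; returns (x0, x1, y0, y1) in pixels.

    Subject-right features have smaller image x in a frontal non-mirrored
    view, so "lateral" for the right side points toward smaller x.
    """
    ied = _ied(coords_t)
    w = region.width_ied * ied
    h = region.height_ied * ied
    name = region.name

    if name == "forehead":
        apex_r, apex_l = coords_t[19], coords_t[24]
        cx = 0.5 * (apex_r[0] + apex_l[0])
        y1 = 0.5 * (apex_r[1] + apex_l[1]) - _FOREHEAD_GAP * ied
        return cx - w / 2, cx + w / 2, y1 - h, y1
    if name == "nose_root":
        c = 0.5 * (coords_t[21] + coords_t[22])
        return c[0] - w / 2, c[0] + w / 2, c[1] - h / 2, c[1] + h / 2
    if name in ("lateral_canthal_L", "lateral_canthal_R"):
        if name.endswith("_R"):
            inner, outer = coords_t[39], coords_t[36]
        else:
            inner, outer = coords_t[42], coords_t[45]
        direction = outer - inner
        nrm = np.linalg.norm(direction)
        if nrm <= 0:
            raise ValueError("degenerate eye-corner geometry")
        c = outer + _CANTHAL_OFFSET * ied * (direction / nrm)
        return c[0] - w / 2, c[0] + w / 2, c[1] - h / 2, c[1] + h / 2
    if name in ("cheek_L", "cheek_R"):
        if name.endswith("_R"):
            lid_mid = 0.5 * (coords_t[40] + coords_t[41])
            x_med = coords_t[31][0]          # right nose wing
            x0, x1 = x_med - w, x_med        # extends laterally (smaller x)
        else:
            lid_mid = 0.5 * (coords_t[46] + coords_t[47])
            x_med = coords_t[35][0]
            x0, x1 = x_med, x_med + w
        y0 = lid_mid[1] + _CHEEK_DROP * ied
        return x0, x1, y0, y0 + h
    raise ValueError(f"unknown region {name!r}")


def extract_patch(
    frame: np.ndarray,
    seq: LandmarkSequence,
    t: int,
    region: RegionSpec,
) -> Patch:
    """Resample a region of the frame to the canonical P x P grid.

    The region rectangle is placed from the frame-t landmarks, sampled at
    P x P pixel centres with bilinear interpolation, and clamped at the
    frame border.  The coverage fraction is the share of sample points
    that fell inside the frame; frames with coverage < 0.5 are unusable
    for this region (``Patch.ok``).
    """
    x0, x1, y0, y1 = region_rect(seq.coords[t], region)
    p = region.patch_size
    xs = x0 + (np.arange(p) + 0.5) / p * (x1 - x0)
    ys = y0 + (np.arange(p) + 0.5) / p * (y1 - y0)
    gx, gy = np.meshgrid(xs, ys)
    h, w = frame.shape
    inside = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
    coverage = float(inside.mean())
    values = ndimage.map_coordinates(
        frame, [gy.ravel(), gx.ravel()], order=1, mode="nearest"
    ).reshape(p, p)
    return Patch(values=values, coverage=coverage)


#: 3x3 horizontal-difference kernel (Sobel); a unit step edge yields
#: gradient magnitude 4, hence the 1/4 rescale in edge_highlight.
_KX = np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]])
_KY = _KX.T


def edge_highlight(patch: np.ndarray | Patch) -> np.ndarray:
    """Gradient-magnitude map of a patch, scaled so a unit step edge ~ 1.

    Deterministic; a constant patch maps to all zeros, and adding a
    constant offset to the patch leaves the output unchanged.
    """
    values = patch.values if isinstance(patch, Patch) else np.asarray(patch, dtype=float)
    gx = ndimage.convolve(values, _KX, mode="nearest")
    gy = ndimage.convolve(values, _KY, mode="nearest")
    return np.hypot(gx, gy) / 4.0


def patch_entropy(
    values: np.ndarray,
    bins: int = ENTROPY_BINS,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Shannon entropy (bits) of the fixed-range histogram of ``values``.

    Values outside the range are clipped into the edge bins; empty bins
    contribute nothing (0 log 0 = 0).  Bounded by log2(bins).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty value array")
    lo, hi = value_range
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())
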