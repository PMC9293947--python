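"""The twelve hypomimia markers.

Each marker is the sample standard deviation, over the usable frames of a
recording, of one scalar facial-dynamics quantity: a landmark distance
normalised by the inner-eye-corner distance (IED), an angle in degrees, a
normalised eye-opening area, or the Shannon entropy of an edge-highlighted
skin patch.  Hypomimia — the reduction of spontaneous and deliberate
facial movement in Parkinson's disease — lowers the variability of every
one of these quantities, so all twelve markers are expected to decrease
with disease severity.

Marker catalogue (8 facial regions, 7 markers with left/right variants,
hence 19 sided values):

====================== ================ ========= =========================
marker                 region           bilateral per-frame quantity
====================== ================ ========= =========================
forehead_lines         forehead         no        entropy of edge patch
nose_root_lines        nose_root        no        entropy of edge patch
eyebrow_elevation      eyebrows         yes       |apex - nose tip| / IED
eyebrow_tilt           eyebrows         yes       eyebrow-line angle (deg)
eyebrow_shape          eyebrows         yes       eyebrow apex angle (deg)
palpebral_aperture     eyes             yes       eye polygon area / IED^2
lateral_canthal_lines  lateral_canthal  yes       entropy of edge patch
cheek_surface          cheeks           yes       entropy of frame-pair diff
upper_lip              mouth            no        |lip 51 - nose tip| / IED
lower_lip              mouth            no        |lip 57 - nose tip| / IED
mouth_corner           mouth            yes       |corner - nose tip| / IED
jaw                    jaw              no        |chin 8 - nose tip| / IED
====================== ================ ========= =========================

Sided values of bilateral markers are averaged ((L+R)/2) for cohort-level
correlation and classification analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FrameSource, LandmarkSequence, usable_segments
from .roi import REGION_SPECS, RegionSpec, edge_highlight, extract_patch, patch_entropy

__all__ = [
    "MarkerDef",
    "MARKER_CATALOGUE",
    "REGIONS",
    "REGION_MARKERS",
    "MarkerVector",
    "sided_marker_names",
    "averaged_marker_names",
    "sample_std",
    "normalized_distance_marker",
    "eyebrow_tilt_marker",
    "eyebrow_shape_marker",
    "palpebral_aperture_marker",
    "entropy_line_marker",
    "cheek_surface_marker",
    "compute_marker_vector",
    "markers_to_frame",
    "read_marker_table",
    "write_marker_table",
]


@dataclass(frozen=True)
class MarkerDef:
    name: str
    region: str
    bilateral: bool
    kind: str  # euclidean | angle | area | surface


MARKER_CATALOGUE: list[MarkerDef] = [
    MarkerDef("forehead_lines", "forehead", False, "surface"),
    MarkerDef("nose_root_lines", "nose_root", False, "surface"),
    MarkerDef("eyebrow_elevation", "eyebrows", True, "euclidean"),
    MarkerDef("eyebrow_tilt", "eyebrows", True, "angle"),
    MarkerDef("eyebrow_shape", "eyebrows", True, "angle"),
    MarkerDef("palpebral_aperture", "eyes", True, "area"),
    MarkerDef("lateral_canthal_lines", "lateral_canthal", True, "surface"),
    MarkerDef("cheek_surface", "cheeks", True, "surface"),
    MarkerDef("upper_lip", "mouth", False, "euclidean"),
    MarkerDef("lower_lip", "mouth", False, "euclidean"),
    MarkerDef("mouth_corner", "mouth", True, "euclidean"),
    MarkerDef("jaw", "jaw", False, "euclidean"),
]

#: the eight facial regions, in face-top-to-bottom order
REGIONS: list[str] = [
    "forehead", "nose_root", "eyebrows", "eyes",
    "lateral_canthal", "cheeks", "mouth", "jaw",
]

#: region -> averaged marker names it pools (used for affected-area counts)
REGION_MARKERS: dict[str, list[str]] = {
    r: [m.name for m in MARKER_CATALOGUE if m.region == r] for r in REGIONS
}

# landmark index map (iBUG 300-W, 0-based); sides are the subject's
NOSE_TIP = 30
CHIN = 8
INNER_EYE = (39, 42)  # right, left medial canthi
_SIDE_IDX = {
    "R": dict(brow=slice(17, 22), apex=19, brow_ends=(17, 21),
              eye=slice(36, 42), mouth_corner=48),
    "L": dict(brow=slice(22, 27), apex=24, brow_ends=(22, 26),
              eye=slice(42, 48), mouth_corner=54),
}


def sided_marker_names() -> list[str]:
    names = []
    for m in MARKER_CATALOGUE:
        if m.bilateral:
            names += [f"{m.name}_L", f"{m.name}_R"]
        else:
            names.append(m.name)
    return names


def averaged_marker_names() -> list[str]:
    return [m.name for m in MARKER_CATALOGUE]


@dataclass
class MarkerVector:
    """All marker values for one recording.

    ``sided`` holds the 19 sided values, ``averaged`` the 12 side-averaged
    ones; undefined markers (e.g. surface markers without frames) are NaN,
    never zero.
    """

    sided: dict[str, float] = field(default_factory=dict)
    averaged: dict[str, float] = field(default_factory=dict)
    n_frames_used: int = 0

    def to_series(self, subject_id: str | None = None) -> pd.Series:
        data: dict[str, object] = {}
        if subject_id is not None:
            data["subject_id"] = subject_id
        for name in sided_marker_names():
            data[name] = self.sided.get(name, math.nan)
        for name in averaged_marker_names():
            data[f"avg_{name}"] = self.averaged.get(name, math.nan)
        data["n_frames_used"] = self.n_frames_used
        return pd.Series(data)


def sample_std(values: np.ndarray) -> float:
    """Sample (n-1 denominator) standard deviation; NaN below 2 values."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        return math.nan
    return float(np.std(values, ddof=1))


def _ied_series(coords: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(coords[:, INNER_EYE[0]] - coords[:, INNER_EYE[1]], axis=1)
    if np.any(d <= 0):
        raise ValueError("inner-eye-corner distance is zero in some frame")
    return d


def _pooled(seq: LandmarkSequence, fn, max_gap: float = 1.0,
            gap_policy: str = "interpolate") -> np.ndarray:
    """Apply a per-segment series function and pool values across segments."""
    parts = []
    for _, sub in usable_segments(seq, max_gap=max_gap, gap_policy=gap_policy):
        parts.append(np.asarray(fn(sub.coords), dtype=float))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def normalized_distance_marker(
    seq: LandmarkSequence, point_a: int, point_b: int,
    max_gap: float = 1.0, gap_policy: str = "interpolate",
) -> float:
    """SD of the IED-normalised distance between two landmarks.

    Normalising every frame's distance by that frame's inner-eye-corner
    distance cancels face scale and camera distance, so the marker is
    invariant to uniform scaling and rigid translation of the landmarks.
    """

    def series(coords: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(coords[:, point_a] - coords[:, point_b], axis=1)
        return d / _ied_series(coords)

    return sample_std(_pooled(seq, series, max_gap, gap_policy))


def _principal_direction(pts: np.ndarray) -> np.ndarray | None:
    """Total-least-squares line direction through a point cloud."""
    centred = pts - pts.mean(axis=0)
    if not np.any(np.abs(centred) > 1e-12):
        return None
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[0]


def eyebrow_tilt_marker(
    seq: LandmarkSequence, side: str,
    max_gap: float = 1.0, gap_policy: str = "interpolate",
) -> float:
    """SD (degrees) of the angle between the eyebrow line and the
    inter-canthal line.

    The eyebrow line is the total-least-squares fit through the five
    eyebrow landmarks; the angle is the unsigned acute angle, so rigid
    rotation of the whole face (both lines co-rotate) leaves it unchanged.
    Frames with a degenerate fit (coincident eyebrow points) are dropped.
    """
    idx = _SIDE_IDX[side]

    def series(coords: np.ndarray) -> np.ndarray:
        out = np.full(coords.shape[0], np.nan)
        for t in range(coords.shape[0]):
            u = _principal_direction(coords[t, idx["brow"]])
            if u is None:
                continue
            v = coords[t, INNER_EYE[1]] - coords[t, INNER_EYE[0]]
            nv = np.linalg.norm(v)
            if nv <= 0:
                continue
            cosang = abs(float(np.dot(u, v / nv)))
            out[t] = math.degrees(math.acos(min(1.0, cosang)))
        return out

    return sample_std(_pooled(seq, series, max_gap, gap_policy))


def eyebrow_shape_marker(
    seq: LandmarkSequence, side: str,
    max_gap: float = 1.0, gap_policy: str = "interpolate",
) -> float:
    """SD (degrees) of the eyebrow apex angle.

    Per frame, the angle at the eyebrow centre (apex) of the triangle
    formed with the two eyebrow endpoints: 180 deg for a straight brow,
    smaller when the brow arches.  Frames where the apex coincides with an
    endpoint are dropped.
    """
    idx = _SIDE_IDX[side]
    apex = idx["apex"]
    e1, e2 = idx["brow_ends"]

    def series(coords: np.ndarray) -> np.ndarray:
        v1 = coords[:, e1] - coords[:, apex]
        v2 = coords[:, e2] - coords[:, apex]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        out = np.full(coords.shape[0], np.nan)
        good = (n1 > 0) & (n2 > 0)
        cosang = np.clip(
            np.einsum("ij,ij->i", v1[good], v2[good]) / (n1[good] * n2[good]),
            -1.0, 1.0,
        )
        out[good] = np.degrees(np.arccos(cosang))
        return out

    return sample_std(_pooled(seq, series, max_gap, gap_policy))


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def palpebral_aperture_marker(
    seq: LandmarkSequence, side: str,
    max_gap: float = 1.0, gap_policy: str = "interpolate",
) -> float:
    """SD of the palpebral fissure (eye-opening) polygon area.

    The shoelace area of the six eye-contour landmarks, normalised by the
    squared inner-eye-corner distance (area scales as length squared), so
    blinking and eyelid motion register as variability regardless of face
    scale.  Self-intersecting contours fall back to the absolute area.
    """
    idx = _SIDE_IDX[side]["eye"]

    def series(coords: np.ndarray) -> np.ndarray:
        ied2 = _ied_series(coords) ** 2
        areas = np.array([_shoelace(coords[t, idx]) for t in range(coords.shape[0])])
        return areas / ied2

    return sample_std(_pooled(seq, series, max_gap, gap_policy))


def entropy_line_marker(
    frames: FrameSource, seq: LandmarkSequence, region: str | RegionSpec,
    max_gap: float = 1.0, region_specs: dict[str, RegionSpec] | None = None,
) -> float:
    """SD (bits) of per-frame edge entropy over a wrinkle region.

    Per frame: extract the region patch, highlight edges, take the Shannon
    entropy of the edge magnitudes.  Wrinkles appearing and fading (e.g.
    frontalis activation raising forehead lines) modulate the per-frame
    entropy; their variability is the marker.  Frames whose region falls
    mostly outside the image (coverage < 0.5) are skipped; with fewer than
    two usable frames the marker is undefined (NaN).
    """
    spec = _resolve_region(region, region_specs)
    values = []
    for segment, sub in usable_segments(seq, max_gap=max_gap):
        for off in range(len(segment)):
            t = segment.start_frame + off
            patch = extract_patch(frames.get(t), sub, off, spec)
            if patch.ok:
                values.append(patch_entropy(edge_highlight(patch)))
    return sample_std(np.asarray(values))


def cheek_surface_marker(
    frames: FrameSource, seq: LandmarkSequence, side: str,
    max_gap: float = 1.0, region_specs: dict[str, RegionSpec] | None = None,
) -> float:
    """SD (bits) of the entropy of consecutive-frame cheek differences.

    For each pair of consecutive frames within a segment, both cheek
    patches are resampled to the canonical grid, subtracted (absolute
    difference) and reduced to a Shannon entropy; the marker is the SD of
    that series over pairs.  Pairs never straddle an excluded gap, so gaps
    cannot fabricate motion.

    The difference histogram uses a fixed (0, 0.5) range: at video frame
    rates consecutive-frame luminance differences are much smaller than
    the full intensity range, and a full-range 64-bin histogram would
    collapse them into a single bin.  Half range doubles the resolution
    (bin width ~2 gray levels of 8-bit video) while keeping tracker-jitter
    flicker below one bin.
    """
    spec = _resolve_region(f"cheek_{side}", region_specs)
    values = []
    for segment, sub in usable_segments(seq, max_gap=max_gap):
        prev = None
        for off in range(len(segment)):
            t = segment.start_frame + off
            patch = extract_patch(frames.get(t), sub, off, spec)
            if not patch.ok:
                prev = None
                continue
            if prev is not None:
                values.append(patch_entropy(np.abs(patch.values - prev),
                                            value_range=(0.0, 0.5)))
            prev = patch.values
    return sample_std(np.asarray(values))


def _resolve_region(region: str | RegionSpec,
                    region_specs: dict[str, RegionSpec] | None) -> RegionSpec:
    if isinstance(region, RegionSpec):
        return region
    specs = region_specs or REGION_SPECS
    return specs[region]


def compute_marker_vector(
    seq: LandmarkSequence,
    frames: FrameSource | None = None,
    max_gap: float = 1.0,
    gap_policy: str = "interpolate",
    region_specs: dict[str, RegionSpec] | None = None,
) -> MarkerVector:
    """Compute all sided markers and their side averages for one recording.

    Without a frame source the four surface markers are NaN (missing),
    never zero.  Bilateral averages use (L+R)/2 when both sides are
    defined, or the single defined side otherwise.
    """
    kw = dict(max_gap=max_gap, gap_policy=gap_policy)
    sided: dict[str, float] = {}

    sided["eyebrow_elevation_L"] = normalized_distance_marker(seq, 24, NOSE_TIP, **kw)
    sided["eyebrow_elevation_R"] = normalized_distance_marker(seq, 19, NOSE_TIP, **kw)
    sided["upper_lip"] = normalized_distance_marker(seq, 51, NOSE_TIP, **kw)
    sided["lower_lip"] = normalized_distance_marker(seq, 57, NOSE_TIP, **kw)
    sided["mouth_corner_L"] = normalized_distance_marker(seq, 54, NOSE_TIP, **kw)
    sided["mouth_corner_R"] = normalized_distance_marker(seq, 48, NOSE_TIP, **kw)
    sided["jaw"] = normalized_distance_marker(seq, CHIN, NOSE_TIP, **kw)
    for side in ("L", "R"):
        sided[f"eyebrow_tilt_{side}"] = eyebrow_tilt_marker(seq, side, **kw)
        sided[f"eyebrow_shape_{side}"] = eyebrow_shape_marker(seq, side, **kw)
        sided[f"palpebral_aperture_{side}"] = palpebral_aperture_marker(seq, side, **kw)

    if frames is not None:
        if frames.n_frames != seq.n_frames:
            raise ValueError("frame source length must match the landmark sequence")
        sided["forehead_lines"] = entropy_line_marker(
            frames, seq, "forehead", max_gap, region_specs)
        sided["nose_root_lines"] = entropy_line_marker(
            frames, seq, "nose_root", max_gap, region_specs)
        for side in ("L", "R"):
            sided[f"lateral_canthal_lines_{side}"] = entropy_line_marker(
                frames, seq, f"lateral_canthal_{side}", max_gap, region_specs)
            sided[f"cheek_surface_{side}"] = cheek_surface_marker(
                frames, seq, side, max_gap, region_specs)
    else:
        for name in ("forehead_lines", "nose_root_lines",
                     "lateral_canthal_lines_L", "lateral_canthal_lines_R",
                     "cheek_surface_L", "cheek_surface_R"):
            sided[name] = math.nan

    averaged: dict[str, float] = {}
    for m in MARKER_CATALOGUE:
        if m.bilateral:
            left = sided[f"{m.name}_L"]
            right = sided[f"{m.name}_R"]
            if math.isnan(left):
                averaged[m.name] = right
            elif math.isnan(right):
                averaged[m.name] = left
            else:
                averaged[m.name] = 0.5 * (left + right)
        else:
            averaged[m.name] = sided[m.name]

    n_used = sum(len(s) for s, _ in usable_segments(seq, max_gap=max_gap))
    return MarkerVector(sided=sided, averaged=averaged, n_frames_used=n_used)


def markers_to_frame(rows: dict[str, MarkerVector]) -> pd.DataFrame:
    """Stack per-subject MarkerVectors into a table (one row per subject)."""
    return pd.DataFrame([mv.to_series(sid) for sid, mv in rows.items()]).reset_index(drop=True)


def write_marker_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_marker_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df
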