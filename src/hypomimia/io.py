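"""Reading, writing and quality-gating of facial landmark time series.

Landmark files are delimited text with one row per video frame::

    frame,x0,y0,x1,y1,...,x67,y67

Empty fields mark landmarks that were obscured or out of frame in that
frame.  An optional comment header (lines starting with ``#``) may carry
``fps``, ``width``, ``height`` and ``subject_id`` metadata, e.g.::

    # fps: 25
    # width: 1440
    # height: 1080

The landmark layout follows the iBUG 300-W 68-point convention
(0-based): jawline 0-16 with the chin at 8, subject-right eyebrow 17-21,
subject-left eyebrow 22-26, nose bridge 27-30 with the nose tip at 30,
nostrils 31-35, subject-right eye 36-41 (inner corner 39), subject-left
eye 42-47 (inner corner 42), outer mouth 48-59 (corners 48/54, upper-lip
centre 51, lower-lip centre 57), inner mouth 60-67.  "Left" and "right"
always refer to the subject's anatomical side in a frontal, non-mirrored
view.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_LANDMARKS",
    "LandmarkSequence",
    "ValidSegment",
    "FrameSource",
    "ArrayFrameSource",
    "ImageDirFrameSource",
    "read_landmark_series",
    "write_landmark_series",
    "read_cohort_table",
    "write_cohort_table",
    "gate_gaps",
    "interpolate_segment",
    "usable_segments",
]

N_LANDMARKS = 68

#: cohort-table columns; clinical fields are optional
COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex",
    "mds_updrs_iii", "brady_rigidity", "pigd", "moca", "bdi_ii",
    "caudate_sbr", "putamen_sbr", "perceptual",
]


@dataclass
class LandmarkSequence:
    """One recording's 68-point landmark trajectory.

    coords is a (T, 68, 2) float array of pixel coordinates (x rightward,
    y downward, origin top-left); valid is a (T, 68) boolean mask where
    False marks an obscured or out-of-frame landmark.
    """

    subject_id: str
    fps: float
    coords: np.ndarray
    valid: np.ndarray
    width: int
    height: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_LANDMARKS, 2):
            raise ValueError(
                f"coords must have shape (T, {N_LANDMARKS}, 2), got {self.coords.shape}"
            )
        if self.valid.shape != self.coords.shape[:2]:
            raise ValueError("valid mask shape must match coords (T, 68)")
        if self.n_frames < 2:
            raise ValueError("a landmark sequence needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def frame_ok(self) -> np.ndarray:
        """Boolean per-frame mask: True where all 68 landmarks are valid."""
        return self.valid.all(axis=1)


@dataclass(frozen=True)
class ValidSegment:
    """Half-open frame interval usable for marker computation.

    Frames listed in ``interpolated_frames`` had at least one invalid
    landmark and are to be filled by temporal interpolation; every other
    frame in the interval has all 68 landmarks valid.  The first and last
    frame of the interval are always fully valid.
    """

    start_frame: int
    end_frame: int
    interpolated_frames: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end_frame - self.start_frame < 2:
            raise ValueError("segments must span at least 2 frames")

    def __len__(self) -> int:
        return self.end_frame - self.start_frame


class FrameSource:
    """Contract for per-frame luminance access.

    Implementations yield, for any frame index, a (height, width) float
    array with levels in [0, 1].  When paired with a LandmarkSequence the
    frame count must match.
    """

    @property
    def n_frames(self) -> int:  # pragma: no cover - interface
        raise NotImplementedError

    def get(self, t: int) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __len__(self) -> int:
        return self.n_frames


class ArrayFrameSource(FrameSource):
    """Frames held in memory as a (T, H, W) array in [0, 1]."""

    def __init__(self, frames: np.ndarray):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("expected a (T, H, W) array")
        self._frames = frames

    @property
    def n_frames(self) -> int:
        return self._frames.shape[0]

    def get(self, t: int) -> np.ndarray:
        return self._frames[t]


class ImageDirFrameSource(FrameSource):
    """Directory of numbered still images (one image per frame)."""

    def __init__(self, directory: str | os.PathLike):
        self.directory = Path(directory)
        exts = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff", ".pgm"}
        self._paths = sorted(
            p for p in self.directory.iterdir() if p.suffix.lower() in exts
        )
        if not self._paths:
            raise FileNotFoundError(f"no image frames found in {directory}")

    @property
    def n_frames(self) -> int:
        return len(self._paths)

    def get(self, t: int) -> np.ndarray:
        import imageio.v3 as iio

        from .roi import luminance_normalize

        return luminance_normalize(iio.imread(self._paths[t]))


def _parse_metadata(lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
        elif "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_landmark_series(
    path: str | os.PathLike,
    fps: float | None = None,
    subject_id: str | None = None,
    width: int | None = None,
    height: int | None = None,
) -> LandmarkSequence:
    """Read a delimited-text landmark file into a LandmarkSequence.

    Explicit arguments override any ``# key: value`` metadata in the file.
    Rows must carry a frame index plus 68 coordinate pairs (137 fields);
    empty coordinate fields mark the landmark invalid for that frame.
    """
    path = Path(path)
    header_lines: list[str] = []
    with open(path) as fh:
        text_lines = fh.readlines()
    data_lines = []
    for line in text_lines:
        if line.startswith("#"):
            header_lines.append(line)
        elif line.strip():
            data_lines.append(line)
    meta = _parse_metadata(header_lines)

    if fps is None:
        fps = float(meta.get("fps", 25.0))
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    width = width if width is not None else int(float(meta.get("width", 1440)))
    height = height if height is not None else int(float(meta.get("height", 1080)))
    if subject_id is None:
        subject_id = meta.get("subject_id", path.stem)

    # optional non-comment header row
    if data_lines and data_lines[0].split(",")[0].strip().lower() in {"frame", "frame_index"}:
        data_lines = data_lines[1:]

    expected_fields = 1 + 2 * N_LANDMARKS
    rows = []
    for lineno, line in enumerate(data_lines, start=1):
        fields = [f.strip() for f in line.rstrip("\n").split(",")]
        if len(fields) != expected_fields:
            raise ValueError(
                f"{path}: line {lineno}: expected {expected_fields} fields "
                f"(frame index + 68 coordinate pairs), got {len(fields)}"
            )
        rows.append([float(f) if f != "" else np.nan for f in fields])
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 frames")

    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    coords = arr[order, 1:].reshape(-1, N_LANDMARKS, 2)
    valid = ~np.isnan(coords).any(axis=2)
    coords = np.nan_to_num(coords, nan=0.0)
    return LandmarkSequence(
        subject_id=subject_id, fps=fps, coords=coords, valid=valid,
        width=width, height=height,
    )


def write_landmark_series(seq: LandmarkSequence, path: str | os.PathLike) -> None:
    """Write a LandmarkSequence to delimited text (lossless round-trip).

    Coordinates are written with ``repr`` precision; invalid landmarks
    become empty fields.
    """
    buf = _io.StringIO()
    buf.write(f"# subject_id: {seq.subject_id}\n")
    buf.write(f"# fps: {seq.fps!r}\n")
    buf.write(f"# width: {seq.width}\n")
    buf.write(f"# height: {seq.height}\n")
    header = ["frame"]
    for i in range(N_LANDMARKS):
        header += [f"x{i}", f"y{i}"]
    buf.write(",".join(header) + "\n")
    for t in range(seq.n_frames):
        fields = [str(t)]
        for i in range(N_LANDMARKS):
            if seq.valid[t, i]:
                fields += [repr(float(seq.coords[t, i, 0])),
                           repr(float(seq.coords[t, i, 1]))]
            else:
                fields += ["", ""]
        buf.write(",".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the cohort metadata table (subject id, group, age, clinical scores)."""
    df = pd.read_csv(path, comment="#")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("cohort table must have 'subject_id' and 'group' columns")
    df["subject_id"] = df["subject_id"].astype(str)
    bad = set(df["group"].unique()) - {"PD", "HC"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)} (expected PD/HC)")
    if "perceptual" in df.columns:
        vals = df["perceptual"].dropna()
        if not vals.isin([0, 1, 2, 3]).all():
            raise ValueError("perceptual ratings must lie in {0, 1, 2, 3}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def gate_gaps(seq: LandmarkSequence, max_gap: float = 1.0) -> list[ValidSegment]:
    """Split a recording into usable segments around landmark dropouts.

    Frames where any landmark is invalid form gaps.  Gaps lasting at most
    ``max_gap`` seconds are retained and flagged for interpolation; longer
    gaps split the recording and their frames are excluded, as are
    leading/trailing invalid frames (which have no valid neighbour on one
    side).  Segments shorter than 2 frames are dropped.  Returns an empty
    list when no valid frame exists.
    """
    ok = seq.frame_ok()
    valid_idx = np.flatnonzero(ok)
    if valid_idx.size == 0:
        return []

    segments: list[ValidSegment] = []
    seg_start = valid_idx[0]
    interp: set[int] = set()
    prev = valid_idx[0]
    for idx in valid_idx[1:]:
        gap = idx - prev - 1
        if gap > 0 and gap / seq.fps > max_gap:
            if prev + 1 - seg_start >= 2:
                segments.append(ValidSegment(seg_start, prev + 1, frozenset(interp)))
            seg_start = idx
            interp = set()
        elif gap > 0:
            interp.update(range(prev + 1, idx))
        prev = idx
    if prev + 1 - seg_start >= 2:
        segments.append(ValidSegment(seg_start, prev + 1, frozenset(interp)))
    return segments


def interpolate_segment(seq: LandmarkSequence, segment: ValidSegment) -> LandmarkSequence:
    """Return the segment's frames with invalid landmarks filled in.

    Each invalid coordinate is linearly interpolated in time between its
    nearest valid neighbours (per landmark, per axis).  Segment endpoints
    must be fully valid, as gate_gaps guarantees.
    """
    s, e = segment.start_frame, segment.end_frame
    if not (seq.valid[s].all() and seq.valid[e - 1].all()):
        raise ValueError("segment endpoints must be fully valid frames")
    coords = seq.coords[s:e].copy()
    valid = seq.valid[s:e]
    tt = np.arange(e - s, dtype=float)
    for lm in range(N_LANDMARKS):
        bad = ~valid[:, lm]
        if bad.any():
            good = ~bad
            for ax in (0, 1):
                coords[bad, lm, ax] = np.interp(tt[bad], tt[good], coords[good, lm, ax])
    return LandmarkSequence(
        subject_id=seq.subject_id, fps=seq.fps, coords=coords,
        valid=np.ones_like(valid, dtype=bool), width=seq.width, height=seq.height,
    )


def usable_segments(
    seq: LandmarkSequence, max_gap: float = 1.0, gap_policy: str = "interpolate"
) -> list[tuple[ValidSegment, LandmarkSequence]]:
    """Gate gaps and materialise the per-segment interpolated sequences.

    gap_policy 'interpolate' fills sub-threshold gaps linearly;
    'drop' removes the gap frames instead (the series is then shorter).
    """
    out = []
    for segment in gate_gaps(seq, max_gap=max_gap):
        filled = interpolate_segment(seq, segment)
        if gap_policy == "drop" and segment.interpolated_frames:
            keep = np.array(
                [t + segment.start_frame not in segment.interpolated_frames
                 for t in range(len(segment))]
            )
            if keep.sum() < 2:
                continue
            filled = LandmarkSequence(
                subject_id=seq.subject_id, fps=seq.fps,
                coords=filled.coords[keep], valid=filled.valid[keep],
                width=seq.width, height=seq.height,
            )
        elif gap_policy not in ("interpolate", "drop"):
            raise ValueError(f"unknown gap_policy {gap_policy!r}")
        out.append((segment, filled))
    return out
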