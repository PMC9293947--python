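"""Synthetic face-motion recordings and cohorts with known severity.

Real recordings of this kind (one-minute monologues, 25 fps, 1440x1080)
are not publicly available, so every downstream stage is exercised on
simulated data with ground truth.  The generator animates a neutral
68-point face template with plausible expression dynamics:

* sparse eyebrow-raise, frown, blink and smile events (Poisson-timed
  smooth bumps, ~0.15-0.35 events/s),
* band-limited 2-7 Hz speech-like oscillation of jaw, lips and mouth
  corners (syllabic rate),
* slow rigid head translation plus white landmark jitter,
* occlusion gaps (runs of invalid frames) at a configurable rate.

Hypomimia severity s in [0, 1] acts multiplicatively: the effective
amplitude of each facial region's motion (and of its wrinkle-texture
modulation) is ``base * (1 - s * weight_region)``, modelling the reduced
amplitude of facial movements in Parkinson's disease.  Controls have
severity 0; patient covariates (MDS-UPDRS III, bradykinesia/rigidity,
DAT-SPECT binding ratios, perceptual rating) are generated from severity
through a linear model with noise, so severity correlates positively with
clinical scores and negatively with putaminal binding, as in the study
population this emulates.

Frames are rendered procedurally in grayscale: smooth face shading, a
static granular skin texture, wrinkle stripes in the forehead/glabellar/
canthal regions whose contrast follows the local expression signal, and a
cheek brightness bump following cheek raises.  Rendering is deliberately
low-fidelity: the surface markers consume texture *dynamics*, not
photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FrameSource, LandmarkSequence, write_cohort_table, write_landmark_series
from .roi import REGION_SPECS, region_rect

__all__ = [
    "SyntheticCohortConfig",
    "TextureConfig",
    "GroundTruth",
    "SyntheticCohort",
    "SyntheticFrameSource",
    "face_template",
    "animate_landmarks",
    "render_frames",
    "simulate_cohort",
]

#: default per-region severity-reduction weights (study conditions):
#: mouth/jaw most affected, lateral canthal least (its reduction is hard
#: to observe on video, so the simulated effect is kept weak).
DEFAULT_REDUCTION_WEIGHTS: dict[str, float] = {
    "forehead": 0.6,
    "nose_root": 0.6,
    "eyebrows": 0.5,
    "eyes": 0.4,
    "lateral_canthal": 0.2,
    "cheeks": 0.5,
    "mouth": 0.7,
    "jaw": 0.7,
}

#: base motion amplitudes in IED units (blink is a closure fraction)
DEFAULT_AMPLITUDES: dict[str, float] = {
    "brow_raise": 0.12,
    "frown": 0.06,
    "blink": 0.85,
    "jaw": 0.30,
    "upper_lip": 0.08,
    "lower_lip": 0.15,
    "mouth_corner": 0.12,
    "cheek_raise": 1.0,   # dimensionless drive for texture/cheek shading
}


@dataclass(frozen=True)
class TextureConfig:
    """Procedural rendering parameters (contrast units of [0,1] luminance)."""

    forehead_depth: float = 0.35
    nose_root_depth: float = 0.35
    canthal_depth: float = 0.30
    cheek_depth: float = 0.25
    static_baseline: float = 0.2   # wrinkle contrast present even when still
    static_noise: float = 0.04     # granular skin texture amplitude
    n_forehead_lines: int = 3
    n_nose_root_lines: int = 2
    n_canthal_lines: int = 3


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the target recording protocol (one minute at 25 fps,
    1440x1080) and a de-novo PD cohort of 91 patients vs 75 controls with
    ages ~61 +- 12.  ``ied_px`` (inner-eye-corner distance in pixels)
    defaults to height / 7.2, a face filling roughly half the frame.
    """

    n_controls: int = 75
    n_patients: int = 91
    duration: float = 60.0
    fps: float = 25.0
    width: int = 1440
    height: int = 1080
    ied_px: float | None = None
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    reduction_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REDUCTION_WEIGHTS))
    severity_range: tuple[float, float] = (0.2, 0.8)
    jitter_sd: float = 0.008        # IED units
    head_amplitude: float = 0.06    # IED units
    gap_rate: float = 0.05          # occlusion events per second
    gap_duration: tuple[float, float] = (0.2, 1.6)  # seconds, uniform
    age_mean: float = 61.0
    age_sd: float = 12.0
    texture: TextureConfig = field(default_factory=TextureConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 controls and 2 patients")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be non-negative")
        lo, hi = self.severity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("severity_range must lie within [0, 1]")

    @property
    def resolved_ied_px(self) -> float:
        return self.ied_px if self.ied_px is not None else self.height / 7.2

    @property
    def n_frames(self) -> int:
        return max(2, int(round(self.duration * self.fps)))


@dataclass
class GroundTruth:
    """Simulation truth for one subject (for recovery tests)."""

    subject_id: str
    severity: float
    region_factors: dict[str, float]          # 1 - severity * weight
    effective_amplitudes: dict[str, float]    # base * region factor, IED units
    signals: dict[str, np.ndarray]            # per-frame expression drives
    texture_seed: int


# ---------------------------------------------------------------------------
# face template

def face_template() -> np.ndarray:
    """Neutral 68-point face in IED units.

    Origin at the midpoint of the inner eye corners, IED = 1, x to the
    subject's left (image right), y down.  Subject-right features have
    negative x.
    """
    pts = np.zeros((68, 2))
    # jawline 0-16: ellipse from subject-right ear down around the chin
    ang = np.pi * np.arange(17) / 16.0
    pts[0:17, 0] = -2.0 * np.cos(ang)
    pts[0:17, 1] = -0.2 + 3.1 * np.sin(ang)
    # eyebrows (17-21 right, 22-26 left)
    bx = np.array([0.35, 0.60, 0.95, 1.30, 1.60])
    by = np.array([-0.45, -0.55, -0.60, -0.55, -0.45])
    pts[17:22, 0] = -bx[::-1]
    pts[17:22, 1] = by[::-1]
    pts[22:27, 0] = bx
    pts[22:27, 1] = by
    # nose bridge 27-30 (tip 30) and nostrils 31-35
    pts[27:31] = [(0, -0.10), (0, 0.25), (0, 0.60), (0, 0.95)]
    pts[31:36] = [(-0.30, 1.10), (-0.15, 1.15), (0, 1.18), (0.15, 1.15), (0.30, 1.10)]
    # eyes: right 36-41 (inner 39), left 42-47 (inner 42)
    pts[36:42] = [(-1.30, 0), (-1.10, -0.12), (-0.75, -0.12),
                  (-0.50, 0), (-0.75, 0.12), (-1.10, 0.12)]
    pts[42:48] = [(0.50, 0), (0.75, -0.12), (1.10, -0.12),
                  (1.30, 0), (1.10, 0.12), (0.75, 0.12)]
    # outer mouth 48-59 (corners 48 right / 54 left, lip centres 51/57)
    pts[48:60] = [(-0.75, 1.75), (-0.45, 1.62), (-0.18, 1.55), (0, 1.58),
                  (0.18, 1.55), (0.45, 1.62), (0.75, 1.75), (0.45, 1.92),
                  (0.20, 2.00), (0, 2.02), (-0.20, 2.00), (-0.45, 1.92)]
    # inner mouth 60-67
    pts[60:68] = [(-0.60, 1.75), (-0.20, 1.68), (0, 1.70), (0.20, 1.68),
                  (0.60, 1.75), (0.20, 1.85), (0, 1.87), (-0.20, 1.85)]
    return pts


# landmark groups moved by each drive
_BROWS = np.arange(17, 27)
_MEDIAL_BROWS = np.array([20, 21, 22, 23])
_UPPER_LIDS = np.array([37, 38, 43, 44])
_LOWER_LIDS = np.array([40, 41, 46, 47])
_CHIN_PTS = np.arange(4, 13)
_UPPER_LIP = np.array([49, 50, 51, 52, 53, 61, 62, 63])
_LOWER_LIP = np.array([55, 56, 57, 58, 59, 65, 66, 67])
_CORNERS_R = np.array([48, 60])
_CORNERS_L = np.array([54, 64])


def _event_signal(rng: np.random.Generator, n_frames: int, fps: float,
                  rate: float, width_s: float) -> np.ndarray:
    """Sum of unit-height smooth bumps at Poisson-distributed times."""
    t = np.arange(n_frames) / fps
    duration = n_frames / fps
    n_events = rng.poisson(rate * duration)
    signal = np.zeros(n_frames)
    times = np.sort(rng.uniform(0, duration, size=n_events))
    for ti in times:
        signal += np.exp(-0.5 * ((t - ti) / width_s) ** 2)
    return signal


def _bandlimited_signal(rng: np.random.Generator, n_frames: int, fps: float,
                        f_lo: float = 2.0, f_hi: float = 7.0,
                        n_components: int = 8) -> np.ndarray:
    """Unit-SD sum of sinusoids with random frequencies in [f_lo, f_hi]."""
    t = np.arange(n_frames) / fps
    freqs = rng.uniform(f_lo, f_hi, size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    amps = rng.uniform(0.5, 1.0, size=n_components)
    signal = np.sum(amps[:, None] * np.sin(
        2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0)
    sd = signal.std()
    return signal / sd if sd > 0 else signal


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def animate_landmarks(
    config: SyntheticCohortConfig,
    severity: float,
    seed: int,
    subject_id: str = "synthetic",
) -> tuple[LandmarkSequence, GroundTruth]:
    """Generate one recording's landmark trajectory for a given severity.

    Deterministic per seed; all random drives are drawn before amplitude
    scaling, so changing an amplitude rescales — never re-randomises — the
    motion.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    rng = np.random.default_rng(seed)
    (brow_rng, frown_rng, blink_rng, jaw_rng, ulip_rng, llip_rng,
     corner_rng, cheek_rng, head_rng, jitter_rng, gap_rng, tex_rng) = rng.spawn(12)

    T = config.n_frames
    fps = config.fps
    ied = config.resolved_ied_px
    factors = {r: 1.0 - severity * w for r, w in config.reduction_weights.items()}
    amp = config.amplitudes

    signals = {
        "brow_raise": _clip01(_event_signal(brow_rng, T, fps, 0.30, 0.35)),
        "frown": _clip01(_event_signal(frown_rng, T, fps, 0.20, 0.45)),
        "blink": _clip01(_event_signal(blink_rng, T, fps, 0.30, 0.08)),
        "jaw": _bandlimited_signal(jaw_rng, T, fps),
        "upper_lip": _bandlimited_signal(ulip_rng, T, fps),
        "lower_lip": _bandlimited_signal(llip_rng, T, fps),
        "mouth_corner": _clip01(_event_signal(corner_rng, T, fps, 0.25, 0.60)),
        "cheek_raise": _clip01(_event_signal(cheek_rng, T, fps, 0.25, 0.60)),
    }

    template = face_template()
    coords = np.broadcast_to(template, (T, 68, 2)).copy()

    # eyebrows: raises move both brows up, frowns pull medial ends in/down
    f_brow = factors["eyebrows"]
    coords[:, _BROWS, 1] -= (amp["brow_raise"] * f_brow
                             * signals["brow_raise"])[:, None]
    frown = amp["frown"] * f_brow * signals["frown"]
    coords[:, _MEDIAL_BROWS, 1] += 0.6 * frown[:, None]
    coords[:, _MEDIAL_BROWS, 0] -= (0.4 * frown[:, None]
                                    * np.sign(template[_MEDIAL_BROWS, 0])[None, :])

    # blinks: eyelid y-offsets shrink toward the corner line
    closure = _clip01(amp["blink"] * factors["eyes"] * signals["blink"])
    for lids in (_UPPER_LIDS, _LOWER_LIDS):
        offs = template[lids, 1][None, :]
        coords[:, lids, 1] = offs * (1.0 - closure[:, None])

    # speech-like lower-face motion
    coords[:, _CHIN_PTS, 1] += (amp["jaw"] * factors["jaw"]
                                * signals["jaw"][:, None]
                                * np.sin(np.pi * np.arange(4, 13) / 16.0)[None, :])
    f_mouth = factors["mouth"]
    coords[:, _UPPER_LIP, 1] += 0.5 * amp["upper_lip"] * f_mouth * signals["upper_lip"][:, None]
    coords[:, _LOWER_LIP, 1] += 0.5 * amp["lower_lip"] * f_mouth * signals["lower_lip"][:, None]
    spread = amp["mouth_corner"] * f_mouth * signals["mouth_corner"]
    coords[:, _CORNERS_R, 0] -= spread[:, None]
    coords[:, _CORNERS_L, 0] += spread[:, None]
    coords[:, np.concatenate([_CORNERS_R, _CORNERS_L]), 1] -= 0.3 * spread[:, None]

    # rigid head translation (slow) and white jitter
    if config.head_amplitude > 0:
        t = np.arange(T) / fps
        fx, fy = head_rng.uniform(0.08, 0.3, size=2)
        px, py = head_rng.uniform(0, 2 * np.pi, size=2)
        head = config.head_amplitude * np.column_stack(
            [np.sin(2 * np.pi * fx * t + px), np.sin(2 * np.pi * fy * t + py)])
        coords += head[:, None, :]
    if config.jitter_sd > 0:
        coords += jitter_rng.normal(0.0, config.jitter_sd, size=coords.shape)

    # to pixel coordinates
    centre = np.array([config.width / 2.0, config.height * 0.40])
    coords = coords * ied + centre

    # occlusion gaps: whole-frame landmark dropouts
    valid = np.ones((T, 68), dtype=bool)
    n_gaps = gap_rng.poisson(config.gap_rate * config.duration)
    for _ in range(n_gaps):
        start = gap_rng.uniform(0, config.duration)
        dur = gap_rng.uniform(*config.gap_duration)
        a = int(start * fps)
        b = min(T, int((start + dur) * fps) + 1)
        valid[a:b, :] = False

    seq = LandmarkSequence(
        subject_id=subject_id, fps=fps, coords=coords, valid=valid,
        width=config.width, height=config.height,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        severity=severity,
        region_factors=factors,
        effective_amplitudes={
            "brow_raise": amp["brow_raise"] * f_brow,
            "blink": amp["blink"] * factors["eyes"],
            "jaw": amp["jaw"] * factors["jaw"],
            "upper_lip": amp["upper_lip"] * f_mouth,
            "lower_lip": amp["lower_lip"] * f_mouth,
            "mouth_corner": amp["mouth_corner"] * f_mouth,
            "cheek_raise": amp["cheek_raise"] * factors["cheeks"],
        },
        signals=signals,
        texture_seed=int(tex_rng.integers(0, 2**31 - 1)),
    )
    return seq, truth


class SyntheticFrameSource(FrameSource):
    """Lazily rendered grayscale frames for a synthetic recording."""

    def __init__(self, seq: LandmarkSequence, truth: GroundTruth,
                 texture: TextureConfig = TextureConfig()):
        self.seq = seq
        self.truth = truth
        self.texture = texture
        h, w = seq.height, seq.width
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        ied = np.linalg.norm(seq.coords[0, 39] - seq.coords[0, 42])
        cx, cy = seq.coords[0, 27] + np.array([0.0, ied])
        base = 0.5 + 0.25 * np.exp(-(((xx - cx) / (2.3 * ied)) ** 2
                                     + ((yy - cy) / (3.2 * ied)) ** 2))
        noise_rng = np.random.default_rng(truth.texture_seed)
        grain = ndimage.gaussian_filter(noise_rng.standard_normal((h, w)), 1.5)
        sd = grain.std()
        if sd > 0:
            grain *= texture.static_noise / sd
        self._background = np.clip(base + grain, 0.0, 1.0)

    @property
    def n_frames(self) -> int:
        return self.seq.n_frames

    def get(self, t: int) -> np.ndarray:
        tx = self.texture
        fr = self.truth.region_factors
        sig = self.truth.signals
        img = self._background.copy()
        coords_t = self.seq.coords[t]

        def stripe_contrast(depth: float, signal_value: float, factor: float) -> float:
            return depth * (tx.static_baseline
                            + (1.0 - tx.static_baseline)
                            * min(1.0, max(0.0, signal_value)) * factor)

        self._draw_stripes(img, coords_t, "forehead", axis="y",
                           n=tx.n_forehead_lines,
                           contrast=stripe_contrast(tx.forehead_depth,
                                                    sig["brow_raise"][t],
                                                    fr["forehead"]))
        self._draw_stripes(img, coords_t, "nose_root", axis="x",
                           n=tx.n_nose_root_lines,
                           contrast=stripe_contrast(tx.nose_root_depth,
                                                    sig["frown"][t],
                                                    fr["nose_root"]))
        for side in ("L", "R"):
            self._draw_stripes(img, coords_t, f"lateral_canthal_{side}", axis="d",
                               n=tx.n_canthal_lines,
                               contrast=stripe_contrast(tx.canthal_depth,
                                                        sig["cheek_raise"][t],
                                                        fr["lateral_canthal"]))
            bump = (tx.cheek_depth * fr["cheeks"]
                    * min(1.0, max(0.0, sig["cheek_raise"][t])))
            self._draw_bump(img, coords_t, f"cheek_{side}", bump)
        np.clip(img, 0.0, 1.0, out=img)
        return img

    def _rect_slices(self, coords_t: np.ndarray, region: str):
        x0, x1, y0, y1 = region_rect(coords_t, REGION_SPECS[region])
        h, w = self._background.shape
        ix0, ix1 = max(0, int(np.floor(x0))), min(w, int(np.ceil(x1)))
        iy0, iy1 = max(0, int(np.floor(y0))), min(h, int(np.ceil(y1)))
        if ix1 - ix0 < 2 or iy1 - iy0 < 2:
            return None
        return (slice(iy0, iy1), slice(ix0, ix1)), (x0, x1, y0, y1)

    def _draw_stripes(self, img, coords_t, region: str, axis: str,
                      n: int, contrast: float) -> None:
        if contrast <= 0:
            return
        got = self._rect_slices(coords_t, region)
        if got is None:
            return
        (sy, sx), (x0, x1, y0, y1) = got
        yy = np.arange(sy.start, sy.stop, dtype=float)[:, None]
        xx = np.arange(sx.start, sx.stop, dtype=float)[None, :]
        if axis == "y":
            phase = (yy - y0) / (y1 - y0) + 0.0 * xx
        elif axis == "x":
            phase = (xx - x0) / (x1 - x0) + 0.0 * yy
        else:  # diagonal
            phase = ((xx - x0) + (yy - y0)) / ((x1 - x0) + (y1 - y0))
        img[sy, sx] -= contrast * np.sin(np.pi * n * phase) ** 4

    def _draw_bump(self, img, coords_t, region: str, amount: float) -> None:
        if amount <= 0:
            return
        got = self._rect_slices(coords_t, region)
        if got is None:
            return
        (sy, sx), (x0, x1, y0, y1) = got
        yy = np.arange(sy.start, sy.stop, dtype=float)[:, None]
        xx = np.arange(sx.start, sx.stop, dtype=float)[None, :]
        bump = (np.sin(np.pi * np.clip((xx - x0) / (x1 - x0), 0, 1))
                * np.sin(np.pi * np.clip((yy - y0) / (y1 - y0), 0, 1)))
        img[sy, sx] += amount * bump


def render_frames(seq: LandmarkSequence, truth: GroundTruth,
                  texture: TextureConfig = TextureConfig()) -> SyntheticFrameSource:
    """Frame source rendering the recording's grayscale frames on demand."""
    return SyntheticFrameSource(seq, truth, texture)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticCohort:
    """A simulated cohort: metadata table plus per-subject recordings."""

    config: SyntheticCohortConfig
    cohort: pd.DataFrame
    recordings: dict[str, LandmarkSequence]
    truths: dict[str, GroundTruth]

    def frame_source(self, subject_id: str) -> SyntheticFrameSource:
        return render_frames(self.recordings[subject_id],
                             self.truths[subject_id], self.config.texture)

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for sid, gt in self.truths.items():
            row = {"subject_id": sid, "severity": gt.severity}
            row.update({f"factor_{r}": v for r, v in gt.region_factors.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir, frames: bool = False, overwrite: bool = False) -> None:
        """Materialise landmark files, cohort table and ground truth.

        With ``frames=True`` also writes one PNG per frame per subject
        (large; intended for small fixture configs only).
        """
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
        (out / "landmarks").mkdir(parents=True, exist_ok=True)
        for sid, seq in self.recordings.items():
            write_landmark_series(seq, out / "landmarks" / f"{sid}.csv")
        write_cohort_table(self.cohort, out / "cohort.csv")
        self.ground_truth_table().to_csv(out / "ground_truth.csv", index=False)
        if frames:
            import imageio.v3 as iio

            for sid in self.recordings:
                fdir = out / "frames" / sid
                fdir.mkdir(parents=True, exist_ok=True)
                src = self.frame_source(sid)
                for t in range(src.n_frames):
                    iio.imwrite(fdir / f"{t:06d}.png",
                                (src.get(t) * 255).astype(np.uint8))


def _patient_covariates(rng: np.random.Generator, severity: float) -> dict:
    """Clinical covariates from severity via a noisy linear model.

    Coefficients chosen so the marginals match the emulated cohort
    (brady-rigidity ~20 +- 9, MDS-UPDRS III ~30 +- 12, putamen SBR
    ~1.5 +- 0.4, caudate ~3.0 +- 0.6) and binding ratios decrease with
    severity while motor scores increase.
    """
    brady = float(np.clip(3.0 + 35.0 * severity + rng.normal(0, 5.0), 3, 46))
    pigd = float(np.clip(round(4.0 * severity + rng.normal(0, 1.2)), 0, 7))
    updrs = float(np.clip(round(brady + pigd + 5.0 + rng.normal(0, 3.0)), 6, 63))
    return {
        "mds_updrs_iii": int(updrs),
        "brady_rigidity": int(round(brady)),
        "pigd": int(pigd),
        "moca": int(np.clip(round(rng.normal(25.0, 3.9)), 17, 30)),
        "bdi_ii": int(np.clip(round(rng.normal(7.8, 4.7)), 0, 19)),
        "caudate_sbr": float(np.clip(3.6 - 1.2 * severity + rng.normal(0, 0.3), 1.3, 4.3)),
        "putamen_sbr": float(np.clip(2.1 - 1.1 * severity + rng.normal(0, 0.2), 0.9, 2.3)),
        "perceptual": int(np.clip(round(3.2 * severity - 0.2 + rng.normal(0, 0.5)), 0, 3)),
    }


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Simulate a full cohort: controls at severity 0, patients drawn from
    the configured severity range.

    Per-subject randomness comes from documented substreams
    ``SeedSequence([config.seed, subject_index])``, so subjects are
    independent and the cohort is bit-identical under the same seed.
    """
    n_total = config.n_controls + config.n_patients
    rows = []
    recordings: dict[str, LandmarkSequence] = {}
    truths: dict[str, GroundTruth] = {}
    lo, hi = config.severity_range

    for i in range(n_total):
        is_patient = i >= config.n_controls
        sid = (f"PD{i - config.n_controls + 1:03d}" if is_patient
               else f"HC{i + 1:03d}")
        sub_ss = np.random.SeedSequence([config.seed, i])
        sub_seed = int(sub_ss.generate_state(1)[0] % 2**31)
        cov_rng = np.random.default_rng(sub_ss.spawn(1)[0])

        severity = float(cov_rng.uniform(lo, hi)) if is_patient else 0.0
        seq, truth = animate_landmarks(config, severity, sub_seed, subject_id=sid)
        recordings[sid] = seq
        truths[sid] = truth

        row = {
            "subject_id": sid,
            "group": "PD" if is_patient else "HC",
            "age": float(np.clip(cov_rng.normal(config.age_mean, config.age_sd), 34, 86)),
            "sex": "M" if cov_rng.uniform() < 0.6 else "F",
        }
        if is_patient:
            row.update(_patient_covariates(cov_rng, severity))
        else:
            row["perceptual"] = int(np.clip(round(cov_rng.normal(0.3, 0.5)), 0, 2))
        rows.append(row)

    cohort = pd.DataFrame(rows)
    return SyntheticCohort(config=config, cohort=cohort,
                           recordings=recordings, truths=truths)
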