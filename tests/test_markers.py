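"""The twelve hypomimia markers: closed forms, invariances, dispatch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypomimia.io import ArrayFrameSource
from hypomimia.markers import (
    MARKER_CATALOGUE,
    REGION_MARKERS,
    REGIONS,
    averaged_marker_names,
    cheek_surface_marker,
    compute_marker_vector,
    eyebrow_shape_marker,
    eyebrow_tilt_marker,
    normalized_distance_marker,
    palpebral_aperture_marker,
    sample_std,
    sided_marker_names,
)
from hypomimia.synth import face_template

from conftest import make_sequence


def seq_from_frames(frames_pts, **kw):
    return make_sequence(np.stack(frames_pts), **kw)


@pytest.fixture
def template():
    return face_template() * 100.0 + np.array([720.0, 400.0])


class TestCatalogueStructure:
    def test_twelve_markers_eight_regions_seven_bilateral(self):
        assert len(MARKER_CATALOGUE) == 12
        assert len({m.region for m in MARKER_CATALOGUE}) == 8
        assert sum(m.bilateral for m in MARKER_CATALOGUE) == 7
        assert len(sided_marker_names()) == 19
        assert len(averaged_marker_names()) == 12

    def test_region_pooling_covers_all_markers(self):
        pooled = [m for names in REGION_MARKERS.values() for m in names]
        assert sorted(pooled) == sorted(averaged_marker_names())
        assert REGION_MARKERS["mouth"] == ["upper_lip", "lower_lip", "mouth_corner"]
        assert len(REGION_MARKERS["eyebrows"]) == 3


class TestSampleStd:
    def test_closed_form_1_2_3(self):
        assert sample_std(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_two_pass_oracle(self, values):
        arr = np.asarray(values)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        expected = math.sqrt(var)
        got = sample_std(arr)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_fewer_than_two_values_is_missing(self):
        assert math.isnan(sample_std(np.array([5.0])))


class TestNormalizedDistance:
    def test_static_face_zero(self, template):
        seq = seq_from_frames([template] * 6)
        assert normalized_distance_marker(seq, 8, 30) == pytest.approx(0.0)

    def test_scale_and_translation_invariance(self, template):
        rng = np.random.default_rng(0)
        frames = [template + rng.normal(0, 2, size=(68, 2)) for _ in range(8)]
        seq = seq_from_frames(frames)
        base = normalized_distance_marker(seq, 8, 30)
        for k, shift in [(3.7, np.array([11.0, -4.0])), (0.25, np.array([0.0, 9.0]))]:
            seq2 = seq_from_frames([k * f + shift for f in frames])
            assert normalized_distance_marker(seq2, 8, 30) == pytest.approx(base, rel=1e-9)

    def test_known_normalized_distances_give_unit_sd(self):
        # craft frames where dist(8,30)/IED = 1, 2, 3 exactly
        frames = []
        base = face_template() * 100.0 + 500.0
        for d in (1.0, 2.0, 3.0):
            f = base.copy()
            ied = np.linalg.norm(f[39] - f[42])
            f[8] = f[30] + np.array([0.0, d * ied])
            frames.append(f)
        seq = seq_from_frames(frames)
        assert normalized_distance_marker(seq, 8, 30) == pytest.approx(1.0)

    def test_zero_ied_raises(self, template):
        f = template.copy()
        f[42] = f[39]
        with pytest.raises(ValueError, match="inner-eye"):
            normalized_distance_marker(seq_from_frames([f, f]), 8, 30)


class TestEyebrowTilt:
    def test_collinear_parallel_brow_gives_zero(self, template):
        f = template.copy()
        # brow points on a horizontal line, parallel to the inter-canthal line
        f[17:22, 1] = 300.0
        f[22:27, 1] = 300.0
        seq = seq_from_frames([f] * 5)
        assert eyebrow_tilt_marker(seq, "L") == pytest.approx(0.0)
        assert eyebrow_tilt_marker(seq, "R") == pytest.approx(0.0)

    def test_rigid_rotation_invariance(self, template):
        rng = np.random.default_rng(1)
        frames = []
        for t in range(8):
            theta = rng.uniform(-0.5, 0.5)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            frames.append(template @ rot.T)
        seq = seq_from_frames(frames)
        assert eyebrow_tilt_marker(seq, "L") == pytest.approx(0.0, abs=1e-9)

    def test_alternating_angles_match_hand_computed_sd(self, template):
        # 10 frames alternating brow-line angles of 5 and 9 degrees
        frames = []
        for t in range(10):
            f = template.copy()
            ang = math.radians(5.0 if t % 2 == 0 else 9.0)
            for side_slice in (slice(17, 22), slice(22, 27)):
                pts = f[side_slice]
                x = pts[:, 0] - pts[:, 0].mean()
                f[side_slice, 1] = 300.0 + x * math.tan(ang)
            frames.append(f)
        seq = seq_from_frames(frames)
        expected = sample_std(np.array([5.0, 9.0] * 5))  # = 2.1081...
        assert expected == pytest.approx(2.10819, abs=1e-4)
        assert eyebrow_tilt_marker(seq, "L") == pytest.approx(expected, rel=1e-6)


class TestEyebrowShape:
    def test_straight_brow_constant_180_gives_zero(self, template):
        f = template.copy()
        for sl in (slice(17, 22), slice(22, 27)):
            f[sl, 1] = 310.0  # collinear horizontal brow
        seq = seq_from_frames([f] * 5)
        assert eyebrow_shape_marker(seq, "L") == pytest.approx(0.0)

    def test_right_isosceles_apex_angle(self, template):
        # apex above the endpoint midpoint at height = half the separation: 90 deg
        f = template.copy()
        f[22], f[26] = np.array([800.0, 300.0]), np.array([900.0, 300.0])
        f[24] = np.array([850.0, 250.0])
        f2 = f.copy()
        f2[24] = np.array([850.0, 300.0])  # collinear: 180 deg
        seq = seq_from_frames([f, f2])
        expected = sample_std(np.array([90.0, 180.0]))  # = 63.6396
        assert expected == pytest.approx(63.6396, abs=1e-3)
        assert eyebrow_shape_marker(seq, "L") == pytest.approx(expected, rel=1e-9)


class TestPalpebralAperture:
    def test_static_eyes_zero(self, template):
        seq = seq_from_frames([template] * 4)
        assert palpebral_aperture_marker(seq, "L") == pytest.approx(0.0)

    def test_shoelace_unit_square(self):
        # degenerate 6-point unit square: area must be 1 before normalisation
        from hypomimia.markers import _shoelace

        square = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1], [0, 1]], dtype=float)
        assert _shoelace(square) == pytest.approx(1.0)

    def test_blink_amplitude_halving_halves_marker(self, small_config):
        from dataclasses import replace

        from hypomimia.synth import animate_landmarks

        base = replace(small_config, jitter_sd=0.0, head_amplitude=0.0, gap_rate=0.0)
        amps_full = dict(base.amplitudes, blink=0.6)
        amps_half = dict(base.amplitudes, blink=0.3)
        seq_a, _ = animate_landmarks(replace(base, amplitudes=amps_full), 0.0, seed=7)
        seq_b, _ = animate_landmarks(replace(base, amplitudes=amps_half), 0.0, seed=7)
        ra = palpebral_aperture_marker(seq_a, "L")
        rb = palpebral_aperture_marker(seq_b, "L")
        assert ra / rb == pytest.approx(2.0, rel=1e-9)


class TestSurfaceMarkers:
    def _static_frames(self, n, h=1080, w=1440, fill=0.5):
        return ArrayFrameSource(np.full((n, h, w), fill))

    def test_static_video_zero_line_markers(self, template):
        seq = seq_from_frames([template] * 5)
        rng = np.random.default_rng(2)
        frame = rng.uniform(0, 1, size=(1080, 1440))
        frames = ArrayFrameSource(np.broadcast_to(frame, (5, 1080, 1440)).copy())
        mv = compute_marker_vector(seq, frames)
        for name in ("forehead_lines", "nose_root_lines",
                     "lateral_canthal_lines_L", "lateral_canthal_lines_R",
                     "cheek_surface_L", "cheek_surface_R"):
            assert mv.sided[name] == pytest.approx(0.0, abs=1e-12), name

    def test_constant_images_give_zero_entropy_marker(self, template):
        from hypomimia.markers import entropy_line_marker

        seq = seq_from_frames([template] * 5)
        assert entropy_line_marker(self._static_frames(5), seq,
                                   "forehead") == pytest.approx(0.0)

    def test_alternating_frames_give_zero_cheek_marker(self, template):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, size=(1080, 1440))
        b = rng.uniform(0, 1, size=(1080, 1440))
        frames = ArrayFrameSource(np.stack([a, b, a, b, a, b]))
        seq = seq_from_frames([template] * 6)
        # per-pair difference images alternate |a-b|, |b-a|: constant series
        assert cheek_surface_marker(frames, seq, "L") == pytest.approx(0.0, abs=1e-12)

    def test_wrinkle_contrast_oscillation_monotonicity(self, small_config):
        from dataclasses import replace

        from hypomimia.markers import entropy_line_marker
        from hypomimia.synth import TextureConfig, animate_landmarks, render_frames

        cfg = replace(small_config, jitter_sd=0.0, head_amplitude=0.0, gap_rate=0.0)
        seq, gt = animate_landmarks(cfg, 0.0, seed=11)
        moving = render_frames(seq, gt, cfg.texture)
        frozen = render_frames(seq, gt, TextureConfig(forehead_depth=0.0))
        m_on = entropy_line_marker(moving, seq, "forehead")
        m_off = entropy_line_marker(frozen, seq, "forehead")
        assert m_on > m_off

    def test_cheek_raise_amplitude_monotonicity(self, small_config):
        from dataclasses import replace

        from hypomimia.synth import TextureConfig, animate_landmarks, render_frames

        cfg = replace(small_config, jitter_sd=0.0, head_amplitude=0.0, gap_rate=0.0)
        # seed chosen so the 4 s recording contains cheek-raise events
        seq, gt = animate_landmarks(cfg, 0.0, seed=3)
        assert gt.signals["cheek_raise"].max() > 0.5
        strong = render_frames(seq, gt, TextureConfig(cheek_depth=0.3))
        weak = render_frames(seq, gt, TextureConfig(cheek_depth=0.15))
        m_strong = cheek_surface_marker(strong, seq, "L")
        m_weak = cheek_surface_marker(weak, seq, "L")
        assert m_strong > m_weak


class TestComputeMarkerVector:
    def test_landmarks_only_surface_markers_missing(self, template):
        rng = np.random.default_rng(4)
        frames = [template + rng.normal(0, 1.5, size=(68, 2)) for _ in range(10)]
        mv = compute_marker_vector(seq_from_frames(frames))
        surface = [n for n in mv.sided
                   if n.startswith(("forehead", "nose_root", "lateral", "cheek"))]
        assert len(surface) == 6 and all(math.isnan(mv.sided[n]) for n in surface)
        euclidean = set(mv.sided) - set(surface)
        assert len(euclidean) == 13
        assert all(mv.sided[n] >= 0 for n in euclidean)

    def test_full_synthetic_recording_all_19_present(self, small_config):
        from hypomimia.synth import animate_landmarks, render_frames

        seq, gt = animate_landmarks(small_config, 0.2, seed=5)
        mv = compute_marker_vector(seq, render_frames(seq, gt))
        assert len(mv.sided) == 19
        assert all(not math.isnan(v) for v in mv.sided.values())
        assert len(mv.averaged) == 12

    def test_bilateral_average_is_mean_of_sides(self, small_config):
        from hypomimia.synth import animate_landmarks, render_frames

        seq, gt = animate_landmarks(small_config, 0.3, seed=6)
        mv = compute_marker_vector(seq, render_frames(seq, gt))
        for m in MARKER_CATALOGUE:
            if m.bilateral:
                assert mv.averaged[m.name] == pytest.approx(
                    0.5 * (mv.sided[f"{m.name}_L"] + mv.sided[f"{m.name}_R"]))
            else:
                assert mv.averaged[m.name] == mv.sided[m.name]

    def test_segmentation_does_not_change_pooled_markers(self, template):
        # identical content, split by a long gap vs a separate short recording:
        # pooled Euclidean markers must agree (no cross-boundary coupling)
        rng = np.random.default_rng(7)
        frames = [template + rng.normal(0, 2, size=(68, 2)) for _ in range(40)]
        whole = seq_from_frames(frames)

        valid = np.ones((70, 68), dtype=bool)
        valid[20:50, :] = False  # 1.2 s gap at 25 fps
        coords = np.concatenate([
            np.stack(frames[:20]),
            np.zeros((30, 68, 2)),
            np.stack(frames[20:]),
        ])
        split = make_sequence(coords, valid=valid)
        for a, b in [(normalized_distance_marker(whole, 8, 30),
                      normalized_distance_marker(split, 8, 30)),
                     (palpebral_aperture_marker(whole, "L"),
                      palpebral_aperture_marker(split, "L"))]:
            assert b == pytest.approx(a, rel=1e-12)

    def test_rotation_invariance_of_angle_markers(self, template):
        rng = np.random.default_rng(8)
        frames = [template + rng.normal(0, 2, size=(68, 2)) for _ in range(8)]
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        rotated = [f @ rot.T + 200.0 for f in frames]
        for side in ("L", "R"):
            assert eyebrow_tilt_marker(seq_from_frames(rotated), side) == pytest.approx(
                eyebrow_tilt_marker(seq_from_frames(frames), side), rel=1e-9)
            assert eyebrow_shape_marker(seq_from_frames(rotated), side) == pytest.approx(
                eyebrow_shape_marker(seq_from_frames(frames), side), rel=1e-9)
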