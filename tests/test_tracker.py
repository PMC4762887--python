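"""Detection, merged-blob resolution, ellipse fitting and association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skimage import draw

import flypref as fp
from flypref.tracker import (
    TrackerConfig,
    binarize_and_clean,
    compute_kinematics,
    fit_ellipses,
    match_frames,
    measure_particles,
    resolve_merged,
    score_likelihood,
    signed_angle_diff,
)

from conftest import render_single_fly


def _multi_fly_frame(positions, orientations, cfg=None, **kw):
    cfg = cfg or fp.ArenaConfig(duration=0.1, frames_per_second=10)
    n = len(positions)
    truth = pd.DataFrame(
        {
            "frame": [0] * n,
            "id": range(n),
            "x_mm": [p[0] for p in positions],
            "y_mm": [p[1] for p in positions],
            "orientation_deg": orientations,
            "state": ["free_walk"] * n,
            "side": ["sugar"] * n,
        }
    )
    frames, background = fp.render_frames(truth, cfg, noise_sd=0.0, seed=0, **kw)
    return truth, frames[0], background, cfg


class TestBinarizeAndClean:
    def test_frame_equal_to_background_has_no_particles(self):
        bg = np.full((50, 50), 200, dtype=np.uint8)
        labels = binarize_and_clean(bg, bg, 128)
        assert labels.max() == 0

    def test_single_fly_gives_one_particle(self):
        _, frame, background, _ = render_single_fly()
        labels = binarize_and_clean(frame, background, 128)
        assert labels.max() == 1

    def test_salt_noise_removed_by_morphology(self):
        _, frame, background, _ = render_single_fly()
        noisy = frame.copy()
        rng = np.random.default_rng(0)
        rr = rng.integers(5, frame.shape[0] - 5, 30)
        cc = rng.integers(5, frame.shape[1] - 5, 30)
        keep = np.hypot(rr - frame.shape[0] / 2, cc - frame.shape[1] / 2) > 30
        noisy[rr[keep], cc[keep]] = 0  # isolated dark single pixels
        labels = binarize_and_clean(noisy, background, 128, morphology_radius=1)
        assert labels.max() == 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            binarize_and_clean(np.zeros((10, 10)), np.zeros((5, 5)), 128)


class TestMeasureParticles:
    def test_filled_circle_has_near_zero_eccentricity(self):
        img = np.zeros((80, 80), dtype=int)
        rr, cc = draw.disk((40, 40), 25)
        img[rr, cc] = 1
        (p,) = measure_particles(img)
        assert p.eccentricity <= 0.05

    def test_ellipse_eccentricity_matches_analytic_value(self):
        # generating semi-axes a=20, b=10 px: e = sqrt(1 - (b/a)^2) = 0.866
        img = np.zeros((100, 100), dtype=int)
        rr, cc = draw.ellipse(50, 50, 10, 20)
        img[rr, cc] = 1
        (p,) = measure_particles(img)
        assert p.eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_empty_image_gives_empty_list(self):
        assert measure_particles(np.zeros((20, 20), dtype=int)) == []


class TestScoreLikelihood:
    def _particles(self, with_merge=False):
        rng = np.random.default_rng(4)
        pos = [(x, y) for x, y in zip(rng.uniform(-30, 30, 10), rng.uniform(-20, 20, 10))]
        ang = list(rng.uniform(0, 180, 10))
        if with_merge:
            pos += [(0.0, 25.0), (1.9, 25.0)]  # overlapping pair -> merged blob
            ang += [0.0, 0.0]
        _, frame, background, _ = _multi_fly_frame(pos, ang)
        labels = binarize_and_clean(frame, background, 128)
        return measure_particles(labels, min_area=3)

    def test_well_separated_single_flies_all_high(self):
        parts = score_likelihood(self._particles())
        assert all(p.cls == "high" for p in parts)

    def test_merged_blob_is_low_likelihood_outlier(self):
        parts = score_likelihood(self._particles(with_merge=True))
        assert len(parts) == 11
        merged = max(parts, key=lambda p: p.area)
        singles = [p for p in parts if p is not merged]
        assert merged.cls == "low"
        assert all(p.cls == "high" for p in singles)

    def test_single_particle_is_high_by_fallback(self):
        parts = self._particles()[:1]
        (p,) = score_likelihood(parts)
        assert p.cls == "high"

    def test_degenerate_reference_warns_and_classifies_high(self):
        parts = self._particles()[:1] * 5  # identical copies: zero spread
        with pytest.warns(UserWarning, match="degenerate"):
            out = score_likelihood(list(parts))
        assert all(p.cls == "high" for p in out)


class TestResolveMerged:
    def _setup(self, positions, orientations):
        _, frame, background, cfg = _multi_fly_frame(positions, orientations)
        labels = binarize_and_clean(frame, background, 128)
        parts = measure_particles(labels, min_area=3)
        return frame, background, parts

    def test_two_touching_flies_split_within_iteration_cap(self):
        frame, background, parts = self._setup([(0.0, 0.0), (2.0, 0.0)], [0.0, 0.0])
        assert len(parts) == 1  # merged by construction
        single_area = 107.0  # mean area of one rendered fly at this calibration
        cfg = TrackerConfig()
        split = resolve_merged(frame, background, parts[0], single_area, cfg)
        assert split is not None and len(split) == 2
        cents = sorted(p.centroid[1] for p in split)
        assert cents[1] - cents[0] == pytest.approx(2.0 / 0.12, abs=4)

    def test_single_odd_blob_returned_as_is(self):
        frame, background, parts = self._setup([(0.0, 0.0)], [45.0])
        cfg = TrackerConfig()
        out = resolve_merged(frame, background, parts[0], parts[0].area * 1.1, cfg)
        assert out is not None and len(out) == 1
        assert out[0].area == parts[0].area

    def test_inseparable_uniform_blob_is_excluded(self):
        # a uniform-intensity blob has no darker cores: no threshold splits it
        background = np.full((60, 60), 200, dtype=np.uint8)
        frame = background.copy()
        rr, cc = draw.ellipse(30, 30, 8, 20)
        frame[rr, cc] = 60
        labels = binarize_and_clean(frame, background, 128)
        (p,) = measure_particles(labels, min_area=3)
        cfg = TrackerConfig()
        out = resolve_merged(frame, background, p, p.area / 2.0, cfg)
        assert out is None


class TestFitEllipses:
    def test_known_pose_recovered_within_reported_accuracy(self):
        # bounds are the published mean errors of the original pipeline
        _, frame, background, cfg = render_single_fly(x_mm=4.0, y_mm=7.0, orientation=32.0)
        labels = binarize_and_clean(frame, background, 128)
        parts = measure_particles(labels)
        det = fit_ellipses(parts, cfg)
        assert len(det) == 1
        d = det.iloc[0]
        assert abs(signed_angle_diff(32.0, d.orientation_deg)) <= 2.2
        assert np.hypot(d.x_mm - 4.0, d.y_mm - 7.0) <= 0.108

    def test_circle_has_equal_axes(self):
        img = np.zeros((60, 60), dtype=int)
        rr, cc = draw.disk((30, 30), 12)
        img[rr, cc] = 1
        det = fit_ellipses(measure_particles(img), fp.ArenaConfig())
        d = det.iloc[0]
        assert d.major_mm == pytest.approx(d.minor_mm, rel=0.05)

    def test_rotating_the_fly_by_90_shifts_orientation_by_90(self):
        def fit_at(angle):
            _, frame, background, cfg = render_single_fly(orientation=angle)
            labels = binarize_and_clean(frame, background, 128)
            return fit_ellipses(measure_particles(labels), cfg).iloc[0].orientation_deg

        a0, a90 = fit_at(20.0), fit_at(110.0)
        assert abs(signed_angle_diff(a0 + 90.0, a90)) < 1.0

    def test_tiny_particle_skipped_with_warning(self):
        img = np.zeros((20, 20), dtype=int)
        img[5, 5] = 1
        img[5, 6] = 1
        parts = measure_particles(img)
        with pytest.warns(UserWarning, match="area"):
            det = fit_ellipses(parts, fp.ArenaConfig())
        assert len(det) == 0


def _dets(rows):
    return pd.DataFrame(rows, columns=["x_mm", "y_mm", "orientation_deg"])


class TestMatchFrames:
    def test_small_displacement_is_paired(self):
        pairs, u0, u1 = match_frames(_dets([(0, 0, 10)]), _dets([(1, 0, 12)]))
        assert len(pairs) == 1 and not u0 and not u1
        assert pairs.iloc[0].delta_position_mm == pytest.approx(1.0)

    def test_displacement_beyond_gate_is_unmatched(self):
        pairs, u0, u1 = match_frames(_dets([(0, 0, 10)]), _dets([(10, 0, 10)]))
        assert len(pairs) == 0
        assert u0 == [0] and u1 == [0]

    def test_greedy_matches_brute_force_optimum(self):
        d0 = _dets([(0, 0, 0), (5, 0, 0)])
        d1 = _dets([(1, 0, 0), (6, 0, 0)])
        pairs, _, _ = match_frames(d0, d1)
        greedy = {(r.index_t, r.index_t1) for r in pairs.itertuples()}

        p0 = d0[["x_mm", "y_mm"]].to_numpy()
        p1 = d1[["x_mm", "y_mm"]].to_numpy()
        best = min(
            itertools.permutations(range(2)),
            key=lambda perm: sum(np.hypot(*(p0[i] - p1[j])) for i, j in enumerate(perm)),
        )
        assert greedy == {(i, j) for i, j in enumerate(best)}

    def test_pairing_is_symmetric_in_frame_order(self):
        rng = np.random.default_rng(3)
        d0 = _dets([(x, y, a) for x, y, a in zip(rng.uniform(-20, 20, 8), rng.uniform(-20, 20, 8), rng.uniform(0, 180, 8))])
        d1 = d0.copy()
        d1[["x_mm", "y_mm"]] += rng.normal(0, 1.0, (8, 2))
        fwd, _, _ = match_frames(d0, d1)
        bwd, _, _ = match_frames(d1, d0)
        assert {(r.index_t, r.index_t1) for r in fwd.itertuples()} == {
            (r.index_t1, r.index_t) for r in bwd.itertuples()
        }

    def test_each_detection_used_at_most_once(self, tracked_video):
        _, _, steps, _ = tracked_video
        for col in ("index_t", "index_t1"):
            frame_col = "frame_t" if col == "index_t" else "frame_t1"
            assert not steps.duplicated([frame_col, col]).any()


class TestKinematics:
    def test_velocities(self):
        steps = pd.DataFrame(
            {"delta_position_mm": [0.0, 0.5], "delta_angle_deg": [0.0, -3.0]}
        )
        out = compute_kinematics(steps, fps=10.0)
        assert list(out["linear_velocity"]) == [0.0, 5.0]
        assert list(out["angular_velocity"]) == [0.0, -30.0]
        assert list(out["abs_angular_velocity"]) == [0.0, 30.0]

    def test_angle_difference_wraps_mod_180(self):
        assert signed_angle_diff(178.0, 2.0) == pytest.approx(4.0)
        assert signed_angle_diff(2.0, 178.0) == pytest.approx(-4.0)
        assert abs(signed_angle_diff(0.0, 90.0)) == pytest.approx(90.0)
        assert abs(signed_angle_diff(10.0, 100.0)) <= 90.0
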