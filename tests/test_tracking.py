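"""Frame preprocessing, background model, detection and trajectory linking."""

import numpy as np
import pytest

from ciona_visuomotor.synthetic_data import SwimSceneConfig, simulate_swim_video
from ciona_visuomotor.tracking import (
    DetectedObject,
    FrameStack,
    TrackingParams,
    background_mean,
    detect_objects,
    link_trajectories,
    preprocess_frames,
    track_stack,
)


def blob_frame(H, W, centers, amplitude=100.0, sigma=1.5, base=10.0):
    r, c = np.mgrid[0:H, 0:W]
    img = np.full((H, W), base)
    for (cr, cc) in centers:
        img += amplitude * np.exp(-((r - cr) ** 2 + (c - cc) ** 2)
                                  / (2 * sigma ** 2))
    return img


class TestPreprocess:
    def test_constant_stack_becomes_uniform_max(self):
        stack = FrameStack(np.full((3, 8, 8), 7, dtype=np.uint8), 5.0, 0.1)
        out = preprocess_frames(stack)
        assert np.all(out.frames == 255)

    def test_moving_dot_preserved_background_removed(self):
        frames = np.stack([blob_frame(32, 32, [(8, 8 + 4 * t)], base=40.0)
                           for t in range(4)])
        stack = FrameStack(frames, 5.0, 0.1)
        out = preprocess_frames(stack)
        # background floor removed: far corner is at the inverted maximum
        top = out.frames.max()
        assert out.frames[0, -1, -1] == pytest.approx(top, rel=1e-6)
        # the dot survives as the darkest spot of each inverted frame
        for t in range(4):
            rr, cc = np.unravel_index(np.argmin(out.frames[t]), (32, 32))
            assert (rr, cc) == (8, 8 + 4 * t)

    def test_single_frame_and_nan_rejected(self):
        with pytest.raises(ValueError):
            FrameStack(np.zeros((1, 4, 4)), 5.0, 0.1)
        bad = np.zeros((3, 4, 4))
        bad[1, 2, 2] = np.nan
        with pytest.raises(ValueError):
            preprocess_frames(FrameStack(bad, 5.0, 0.1))


class TestBackground:
    def test_identical_frames_give_that_frame(self):
        f = blob_frame(16, 16, [(8, 8)])
        stack = FrameStack(np.stack([f, f, f]), 5.0, 0.1)
        np.testing.assert_allclose(background_mean(stack), f)

    def test_pixelwise_mean(self):
        a = np.zeros((4, 4))
        b = np.full((4, 4), 10.0)
        stack = FrameStack(np.stack([a, b]), 5.0, 0.1)
        np.testing.assert_allclose(background_mean(stack), 5.0)

    def test_transient_dot_contributes_one_over_T(self):
        T = 10
        frames = np.stack([blob_frame(16, 16, [(8, 8)]) if t == 0
                           else np.full((16, 16), 10.0) for t in range(T)])
        bg = background_mean(FrameStack(frames, 5.0, 0.1))
        peak = blob_frame(16, 16, [(8, 8)])[8, 8]
        assert bg[8, 8] == pytest.approx(10.0 + (peak - 10.0) / T)


class TestDetect:
    def test_blank_frame_empty(self):
        frame = np.full((16, 16), 5.0)
        assert detect_objects(frame, frame, threshold=1.0) == []

    def test_two_blobs_subpixel_centroids(self):
        centers = [(10.0, 10.0), (25.0, 30.0)]
        frame = blob_frame(40, 40, centers)
        bg = np.full((40, 40), 10.0)
        objs = detect_objects(frame, bg, threshold=10.0, min_area=5)
        assert len(objs) == 2
        found = sorted(o.centroid for o in objs)
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) < 0.5 and abs(fc - tc) < 0.5

    def test_min_area_excludes_small_blob(self):
        frame = np.full((16, 16), 0.0)
        frame[4, 4] = 100.0  # single-pixel spike
        objs = detect_objects(frame, np.zeros((16, 16)), threshold=10.0,
                              min_area=5)
        assert objs == []

    def test_roi_filters_centroids(self):
        frame = blob_frame(40, 40, [(5, 5), (30, 30)])
        bg = np.full((40, 40), 10.0)
        objs = detect_objects(frame, bg, threshold=10.0, roi=(20, 20, 40, 40))
        assert len(objs) == 1
        assert objs[0].centroid[0] > 20


def detections_from_path(path_px, fps=8.9):
    """Synthetic detection stream for a single object."""
    return [[DetectedObject(t, tuple(p), 9)] for t, p in enumerate(path_px)]


class TestLinking:
    def test_straight_swimmer_is_complete(self):
        # 1 mm/s at 0.1 mm/px, 8.9 fps -> 1.124 px/frame
        fps, mmpp = 8.9, 0.1
        step = 1.0 / mmpp / fps
        path = [(50.0, 10.0 + step * t) for t in range(60)]
        stack = FrameStack(np.zeros((60, 100, 100), dtype=np.uint8), fps, mmpp)
        trajs = link_trajectories(stack, detections_from_path(path),
                                  TrackingParams())
        assert len(trajs) == 1
        assert trajs[0].status == "complete"
        assert np.max(trajs[0].speeds_mm_s(fps, mmpp)) <= 6.5

    def test_teleport_rejected_for_speed(self):
        fps, mmpp = 8.9, 0.1
        path = [(50.0, 10.0)] * 10 + [(50.0, 110.0)] * 10  # 10 mm jump
        stack = FrameStack(np.zeros((20, 200, 200), dtype=np.uint8), fps, mmpp)
        trajs = link_trajectories(stack, detections_from_path(path),
                                  TrackingParams())
        assert trajs[0].status == "rejected_speed"

    def test_stationary_object_rejected_after_one_minute(self):
        fps, mmpp = 5.0, 0.1
        T = int(75 * fps)
        path = [(20.0 + 0.2 * np.sin(t), 20.0) for t in range(T)]  # sub-px
        stack = FrameStack(np.zeros((T, 64, 64), dtype=np.uint8), fps, mmpp)
        trajs = link_trajectories(stack, detections_from_path(path),
                                  TrackingParams())
        assert trajs[0].status == "rejected_stationary"
        # rejected at (not before) the 60 s mark
        assert len(trajs[0].positions) >= int(60 * fps)

    def test_roi_exit_rejected(self):
        fps, mmpp = 8.9, 0.1
        path = [(10.0, 5.0 + 2.0 * t) for t in range(30)]
        stack = FrameStack(np.zeros((30, 64, 64), dtype=np.uint8), fps, mmpp,
                           roi=(0, 0, 64, 40))
        trajs = link_trajectories(stack, detections_from_path(path),
                                  TrackingParams())
        assert trajs[0].status == "rejected_roi"

    def test_contact_flagging(self):
        fps, mmpp = 8.9, 0.1
        a = [(10.0, 10.0 + t) for t in range(20)]
        b = [(10.0, 40.0 - t) for t in range(20)]
        dets = [[DetectedObject(t, a[t], 9), DetectedObject(t, b[t], 9)]
                for t in range(20)]
        stack = FrameStack(np.zeros((20, 64, 64), dtype=np.uint8), fps, mmpp)
        trajs = link_trajectories(stack, dets,
                                  TrackingParams(contact_radius_px=4.0))
        assert all(t.contact for t in trajs)


class TestEndToEnd:
    def test_rendered_larvae_recovered(self):
        """A rendered non-colliding scene yields one complete trajectory per
        larva with sub-pixel positional error."""
        cfg = SwimSceneConfig(n_larvae=4, duration_s=20, seed=5,
                              confine_half_px=14)
        stack, truth = simulate_swim_video(cfg)
        trajs = track_stack(stack, TrackingParams(threshold=12))
        complete = [t for t in trajs if t.status == "complete"]
        assert len(complete) == 4
        for tr in complete:
            p = np.asarray(tr.positions)
            i = int(np.argmin(np.linalg.norm(
                truth.positions_px[:, 0, :] - p[0], axis=1)))
            rmse = np.sqrt(np.mean(np.sum(
                (truth.positions_px[i, :len(p)] - p) ** 2, axis=1)))
            assert rmse <= 1.0

    def test_invariant_to_additive_intensity_offset(self):
        """Background subtraction absorbs a global intensity offset."""
        cfg = SwimSceneConfig(n_larvae=2, duration_s=10, seed=2,
                              confine_half_px=14, noise_sd=0.0)
        stack, _ = simulate_swim_video(cfg)
        shifted = FrameStack(
            np.clip(stack.frames.astype(float) + 30, 0, 255).astype(np.uint8),
            stack.fps, stack.mm_per_pixel)
        t1 = track_stack(stack, TrackingParams(threshold=12))
        t2 = track_stack(shifted, TrackingParams(threshold=12))
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            np.testing.assert_allclose(np.asarray(a.positions),
                                       np.asarray(b.positions), atol=0.2)
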