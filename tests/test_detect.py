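"""Background training, subtraction and blob segmentation."""

import numpy as np
import pytest

import fintrack as ft
from fintrack.detect import BackgroundModel, centered_crop_offsets


def _flat_stack(value=200, shape=(3, 30, 40)):
    return ft.FrameStack(frames=np.full(shape, value, dtype=np.uint8))


def _disk_mask(shape, cx, cy, radius):
    yy, xx = np.indices(shape)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# cropping


def test_crop_to_recording_geometry():
    """640x480 frames crop to the 380x380 tank window; the centered
    window starts at (130, 50)."""
    stack = ft.FrameStack(frames=np.zeros((4, 480, 640), dtype=np.uint8))
    assert centered_crop_offsets(640, 480, 380) == (130, 50)
    cropped = ft.crop_frames(stack, 130, 50, 380)
    assert cropped.frames.shape == (4, 380, 380)


def test_crop_identity_and_origin_shift():
    rng = np.random.default_rng(0)
    frames = rng.integers(0, 255, size=(2, 20, 30), dtype=np.uint8)
    stack = ft.FrameStack(frames=frames)
    full = ft.crop_frames(stack, 0, 0, 20)
    assert np.array_equal(full.frames, frames[:, :20, :20])
    sub = ft.crop_frames(stack, 5, 3, 10)
    assert sub.frames[0, 0, 0] == frames[0, 3, 5]


def test_crop_window_out_of_bounds_rejected():
    stack = _flat_stack()
    with pytest.raises(ValueError):
        ft.crop_frames(stack, 30, 0, 20)


# ---------------------------------------------------------------------------
# background model


def test_background_of_identical_frames_is_that_frame():
    stack = _flat_stack(123)
    model = ft.train_background(stack)
    assert np.all(model.reference == 123)


def test_background_is_per_pixel_median():
    frames = np.stack([np.full((5, 5), v, dtype=np.uint8) for v in (10, 10, 200)])
    model = ft.train_background(ft.FrameStack(frames=frames))
    assert np.all(model.reference == 10)


def test_background_needs_three_frames():
    with pytest.raises(ValueError):
        ft.train_background(_flat_stack(shape=(2, 10, 10)))


def test_background_recovers_clean_synthetic_scene():
    """On a noise-free clip where the fish covers each pixel in fewer
    than half the frames, the median reference equals the generator's
    flat background exactly."""
    cfg = ft.TankSimConfig(width_px=60, height_px=60, n_frames=31, n_fish=1,
                           noise_sigma=0.0, speed_scale_px=3.0,
                           velocity_persistence=0.5, fish_axes_px=(5.0, 3.0),
                           seed=5)
    stack, _ = ft.simulate_tank(cfg)
    coverage = (stack.frames != cfg.background_intensity).sum(axis=0)
    assert coverage.max() < cfg.n_frames / 2  # precondition
    model = ft.train_background(stack)
    assert np.array_equal(model.reference,
                          np.full((60, 60), float(cfg.background_intensity)))


# ---------------------------------------------------------------------------
# detection


def test_frame_identical_to_reference_yields_nothing():
    stack = _flat_stack(200)
    model = ft.train_background(stack)
    assert ft.detect(stack.frames[0], model) == []


def test_single_disk_against_pixel_count_oracle():
    """One dark disk on a flat background: exactly one detection whose
    centroid and area match the rasterized mask."""
    frame = np.full((200, 200), 200, dtype=np.uint8)
    mask = _disk_mask(frame.shape, cx=100, cy=120, radius=5)
    frame[mask] = 40
    model = BackgroundModel(reference=np.full(frame.shape, 200.0),
                            diff_threshold=50.0)
    dets = ft.detect(frame, model, min_area=10, median_filter=False)
    assert len(dets) == 1
    d = dets[0]
    assert abs(d.centroid_x - 100) <= 0.5 and abs(d.centroid_y - 120) <= 0.5
    assert d.area_px == int(mask.sum())


def test_two_disks_sorted_by_row_then_column():
    frame = np.full((200, 200), 200, dtype=np.uint8)
    m1 = _disk_mask(frame.shape, cx=150, cy=40, radius=5)
    m2 = _disk_mask(frame.shape, cx=60, cy=100, radius=5)
    frame[m1 | m2] = 40
    model = BackgroundModel(reference=np.full(frame.shape, 200.0),
                            diff_threshold=50.0)
    dets = ft.detect(frame, model, min_area=10, median_filter=False)
    assert len(dets) == 2
    assert (dets[0].centroid_y, dets[0].centroid_x) < (dets[1].centroid_y,
                                                       dets[1].centroid_x)
    assert dets[0].area_px == int(m1.sum()) and dets[1].area_px == int(m2.sum())


def test_detection_counts_and_centroids_on_synthetic_clip(
        two_fish_clip, two_fish_detections):
    """Every frame of a well-separated two-fish clip yields exactly two
    detections, each within 1 px of the true fish center."""
    _, _, truth = two_fish_clip
    for t, dets in enumerate(two_fish_detections):
        assert len(dets) == 2
        det_xy = np.array([[d.centroid_x, d.centroid_y] for d in dets])
        for fish in range(2):
            err = np.linalg.norm(det_xy - truth.positions[fish, t], axis=1).min()
            assert err <= 1.0


def test_detection_count_monotone_in_min_area_and_threshold():
    rng = np.random.default_rng(3)
    frame = np.full((120, 120), 200, dtype=np.uint8)
    for _ in range(6):
        cx, cy = rng.integers(15, 105, size=2)
        r = rng.integers(2, 7)
        frame[_disk_mask(frame.shape, cx, cy, r)] = rng.integers(0, 120)
    model = BackgroundModel(reference=np.full(frame.shape, 200.0),
                            diff_threshold=30.0)
    counts_area = [len(ft.detect(frame, model, min_area=a, median_filter=False))
                   for a in (1, 5, 20, 60, 200)]
    assert counts_area == sorted(counts_area, reverse=True)
    counts_thr = []
    for thr in (10, 40, 80, 140, 250):
        m = BackgroundModel(reference=model.reference, diff_threshold=thr)
        counts_thr.append(len(ft.detect(frame, m, min_area=5, median_filter=False)))
    assert counts_thr == sorted(counts_thr, reverse=True)


def test_centroids_are_translation_equivariant():
    frame = np.full((100, 100), 200, dtype=np.uint8)
    frame[_disk_mask(frame.shape, cx=30, cy=40, radius=6)] = 40
    reference = np.full(frame.shape, 200.0)
    dx, dy = 17, 9
    shifted = np.roll(np.roll(frame, dy, axis=0), dx, axis=1)
    m0 = BackgroundModel(reference=reference, diff_threshold=50.0)
    d0 = ft.detect(frame, m0, min_area=10)[0]
    d1 = ft.detect(shifted, m0, min_area=10)[0]
    assert d1.centroid_x == pytest.approx(d0.centroid_x + dx)
    assert d1.centroid_y == pytest.approx(d0.centroid_y + dy)


def test_geometry_mismatch_rejected():
    model = BackgroundModel(reference=np.zeros((10, 10)), diff_threshold=30.0)
    with pytest.raises(ValueError):
        ft.detect(np.zeros((12, 10)), model)
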