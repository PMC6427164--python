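import numpy as np
import pytest

import fintrack as ft


@pytest.fixture(scope="session")
def two_fish_clip():
    """Seeded 300-frame two-fish clip whose fish stay well separated
    (minimum inter-fish distance exceeds twice the maximum per-frame
    step), with moderate sensor noise."""
    cfg = ft.TankSimConfig(n_fish=2, n_frames=300, seed=7, noise_sigma=3.0)
    stack, truth = ft.simulate_tank(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def two_fish_detections(two_fish_clip):
    _, stack, _ = two_fish_clip
    model = ft.train_background(stack)
    return ft.detect_stack(stack, model)


@pytest.fixture(scope="session")
def two_fish_tracks(two_fish_detections):
    return ft.build_tracks(two_fish_detections, n_fish=2)
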