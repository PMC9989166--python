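import numpy as np
import pytest

import aggrebout as ab


@pytest.fixture(scope="session")
def tiny_videos():
    """Three short, small-frame labeled sessions with frequent bouts —
    enough signal for fast classifier tests."""
    videos = []
    for seed in (11, 12, 13):
        params = ab.SimVideoParams(
            width_px=32, height_px=32, blob_radius_px=4, duration_s=30.0,
            attack_rate=4.0, contact_distance_px=7.0, seed=seed,
        )
        v, _ = ab.simulate_ri_video(params)
        videos.append(v)
    return videos


@pytest.fixture(scope="session")
def tiny_training(tiny_videos):
    """Leave-one-video-out training on the tiny sessions."""
    config = ab.TrainingConfig(epochs=8, neg_pos_ratio=5.0, seed=7)
    model, folds = ab.train_frame_classifier(tiny_videos, config)
    return model, folds


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
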