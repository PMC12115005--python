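import numpy as np
import pytest

import surgloc as sl


@pytest.fixture(scope="session")
def balanced_scene_config():
    """Balanced prevalences so every class appears in a small fixture dataset."""
    return sl.SceneConfig(
        class_prevalences=tuple([0.45] * 7),
        max_tools_per_frame=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, balanced_scene_config):
    """64 frames over 4 videos, written once per session."""
    out = tmp_path_factory.mktemp("scenes")
    manifest = sl.generate_dataset(balanced_scene_config, 64, 4, out)
    return out, manifest


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """Surrogate trained on the whole small fixture dataset (in-sample use only)."""
    data_dir, manifest = small_dataset
    config = sl.surrogate_train_config(seed=0)
    return sl.train(
        "surrogate_small", manifest, manifest.video_ids(), config, data_dir, zero_count_policy="unit"
    )


@pytest.fixture(scope="session")
def fixture_frames(small_dataset):
    """Decoded frames of the fixture dataset, aligned with manifest records."""
    from PIL import Image

    data_dir, manifest = small_dataset
    return [np.asarray(Image.open(data_dir / r.frame_path).convert("RGB")) for r in manifest.records]
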