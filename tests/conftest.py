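import numpy as np
import pytest

import spheroidquant as sq
from spheroidquant.volumes import VoxelSpacing

UNIT_SPACING = VoxelSpacing(1.0, 1.0, 1.0)


def digital_ball(radius: int, margin: int = 1) -> np.ndarray:
    """Boolean ball of the given voxel radius centered in a cubic array."""
    n = 2 * radius + 1 + 2 * margin
    c = (n - 1) / 2
    zz, yy, xx = np.ogrid[:n, :n, :n]
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius * radius


@pytest.fixture(scope="session")
def unit_spacing():
    return UNIT_SPACING


@pytest.fixture(scope="session")
def default_config():
    return sq.AnalysisConfig()


@pytest.fixture(scope="session")
def train_scene():
    """Default-condition co-culture scene used as the training image."""
    return sq.generate_scene(sq.SceneParams(seed=0))


@pytest.fixture(scope="session")
def train_records(train_scene, default_config):
    records, _ = sq.build_cell_table(train_scene.image, train_scene.labels, default_config)
    return records


@pytest.fixture(scope="session")
def test_scene():
    """Held-out scene from the same conditions, different seed."""
    return sq.generate_scene(sq.SceneParams(seed=1))


@pytest.fixture(scope="session")
def test_records(test_scene, default_config):
    records, _ = sq.build_cell_table(test_scene.image, test_scene.labels, default_config)
    return records


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, blur-free scene: rendered channels are exact."""
    params = sq.SceneParams(seed=3, noise_sd=0.0, blur_sigma=0.0)
    return sq.generate_scene(params)


@pytest.fixture(scope="session")
def clean_records(clean_scene, default_config):
    records, _ = sq.build_cell_table(clean_scene.image, clean_scene.labels, default_config)
    return records


def truth_by_id(scene):
    return scene.truth.set_index("id")


def true_flags(scene, records, column):
    t = truth_by_id(scene)
    return [bool(t.loc[r.id, column]) for r in records]
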