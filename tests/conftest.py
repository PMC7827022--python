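import numpy as np
import pytest

from stereokit.synthetic import NO_NOISE, NoiseModel, generate_dataset, make_templates
from stereokit.types import CleanSkeleton


@pytest.fixture(scope="session")
def templates():
    return make_templates()


@pytest.fixture(scope="session")
def small_clean_dataset():
    """A small noise-free dataset for fast classifier/baseline unit tests."""
    return generate_dataset(n_per_class=12, noise=NO_NOISE, seed=42)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    return generate_dataset(n_per_class=12, noise=NoiseModel(), seed=42)


def random_clean_skeleton(rng, frame_index=0, n_valid=None):
    """A random 13-joint skeleton in scaled coordinates with a valid Neck."""
    joints = np.column_stack([rng.uniform(0, 656 / 368, 13), rng.uniform(0, 1, 13)])
    valid = np.ones(13, dtype=bool)
    if n_valid is not None:
        off = rng.choice(12, size=13 - n_valid, replace=False) + 1  # keep the Neck
        valid[off] = False
    return CleanSkeleton(joints=joints, valid=valid, frame_index=frame_index)
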