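import numpy as np
import pytest
from hypothesis import settings

from crossmvpa.evaluation import prepare_session
from crossmvpa.preprocessing import TrialFeatureMatrix
from crossmvpa.synthetic_data import (
    DesignSpec,
    NoiseSpec,
    make_ground_truth,
    make_participant,
)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

TINY_GRID = (8, 8, 4)


@pytest.fixture(scope="session")
def tiny_truth():
    return make_ground_truth(TINY_GRID, n_shared=16, n_specific_per_session=16,
                             effect_size=0.25, seed=7)


@pytest.fixture(scope="session")
def tiny_pair(tiny_truth):
    """One simulated participant (audio, ortho) at a small grid, default design."""
    return make_participant(DesignSpec(), tiny_truth, noise=NoiseSpec(sigma=1.0), seed=11)


@pytest.fixture(scope="session")
def tiny_mask():
    return np.ones(TINY_GRID, dtype=bool)


@pytest.fixture(scope="session")
def prepared_pair(tiny_pair, tiny_mask):
    audio, ortho = tiny_pair
    return prepare_session(audio, tiny_mask), prepare_session(ortho, tiny_mask)


def make_fm(features, labels, **kw) -> TrialFeatureMatrix:
    """Wrap plain arrays into a TrialFeatureMatrix for unit tests."""
    features = np.asarray(features, dtype=float)
    n = len(features)
    labels = np.asarray(labels).astype(str)
    defaults = dict(
        stimulus_ids=np.array([f"s{i}" for i in range(n)]),
        repetitions=np.ones(n, dtype=int),
        runs=np.ones(n, dtype=int),
        voxel_coords=np.zeros((features.shape[1], 3), dtype=int),
        kept_rows=np.arange(n),
    )
    defaults.update(kw)
    return TrialFeatureMatrix(features=features, labels=labels, **defaults)
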