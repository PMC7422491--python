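import numpy as np
import pytest

from eegemotion import DatasetDesign, EmotionSignature, generate_dataset


@pytest.fixture(scope="session")
def unit_design() -> DatasetDesign:
    """1 subject x 1 video x 1 segment x 1 channel, 4 emotions."""
    return DatasetDesign(
        n_subjects=1,
        videos_per_emotion=1,
        segments_per_video=1,
        channels=("FP1-F7",),
    )


@pytest.fixture(scope="session")
def small_design() -> DatasetDesign:
    return DatasetDesign(
        n_subjects=2,
        videos_per_emotion=2,
        segments_per_video=3,
        channels=("FP2-F4", "FP1-F7"),
    )


@pytest.fixture(scope="session")
def flat_signatures(small_design):
    """One identical broadband signature per emotion (no separability)."""
    sig = EmotionSignature(
        band_weights={"delta": 5, "theta": 4, "alpha": 6, "beta": 5, "gamma": 4},
        noise_uv=2.0,
        subject_sd=0.05,
    )
    return {e: sig for e in small_design.emotions}


@pytest.fixture(scope="session")
def small_dataset(small_design, flat_signatures):
    return generate_dataset(small_design, flat_signatures, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
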