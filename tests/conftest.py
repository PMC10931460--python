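import numpy as np
import pytest

from ccanet.backbone import BackboneConfig
from ccanet.model import build_model
from ccanet.synthetic import make_regression_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small labelled video collection shared by training-layer tests."""
    videos, table = make_regression_dataset(
        12, frames_per_video=3, seed=7, height=32, width=32)
    return videos, table


def tiny_model(variant: str = "cca", seed: int = 0, **kw):
    return build_model(BackboneConfig.tiny(), attention_variant=variant,
                       fpn_channels=16, seed=seed, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
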