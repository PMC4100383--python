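"""Shared fixtures: the synthetic study configuration and a trained
DAB classifier.

Phantoms are generated at the working resolution the pipeline normally
reaches after downscaling real slides, so the study configuration keeps
the image size as-is (downscale factor 1) while retaining the standard
sigma-2 smoothing.
"""

import numpy as np
import pytest

from stainseg.config import PipelineConfig
from stainseg.pipeline import train_default_classifier


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig(downscale_factor=1.0)


@pytest.fixture(scope="session")
def classifier(cfg):
    return train_default_classifier(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
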