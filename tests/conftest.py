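"""Shared fixtures: synthetic training image, trained classifier, rngs.

Heavy artifacts (feature stacks, the trained model) are session-scoped so
the texture and end-to-end tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from fazkit.script_segmenter import ScriptPipelineConfig, center_crop
from fazkit.synthetic import SyntheticSpec, simulate_angiogram, training_annotations
from fazkit.texture_segmenter import compute_features, rasterize_annotations, train_classifier

TRAIN_SEED = 500


@pytest.fixture(scope="session")
def script_cfg() -> ScriptPipelineConfig:
    return ScriptPipelineConfig()


@pytest.fixture(scope="session")
def train_pair(script_cfg):
    """(cropped training image, ground truth) for the classifier."""
    angio, truth = simulate_angiogram(SyntheticSpec(seed=TRAIN_SEED))
    return center_crop(angio.pixels, script_cfg), truth


@pytest.fixture(scope="session")
def trained_model(train_pair):
    crop, truth = train_pair
    stack = compute_features(crop)
    labeled = rasterize_annotations(training_annotations(truth), crop.shape)
    return train_classifier(stack, labeled, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
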