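"""Shared fixtures: the reference two-view confusion matrices and score vectors.

The two 5x5 column-normalized confusion matrices below summarize the
validation behavior of the stem-end and flower-end view classifiers on the
five ordinal ripeness stages (Turning, Pink, Light Red, Red, Deep Red);
every column sums to 1 and the diagonal entry of column m is class-m
precision. The paired score vectors are the canonical disagreement case:
the stem-end view calls Turning, the flower-end view calls Pink.
"""

import numpy as np
import pytest

from sdfuse import ConfusionMatrix, ScoreVector, default_stages

STEM_CONFUSION = np.array(
    [
        [0.90, 0.04, 0.00, 0.00, 0.00],
        [0.10, 0.92, 0.05, 0.00, 0.00],
        [0.00, 0.04, 0.90, 0.02, 0.02],
        [0.00, 0.00, 0.05, 0.90, 0.08],
        [0.00, 0.00, 0.00, 0.08, 0.90],
    ]
)

FLOWER_CONFUSION = np.array(
    [
        [0.80, 0.10, 0.03, 0.00, 0.00],
        [0.15, 0.80, 0.06, 0.00, 0.00],
        [0.05, 0.10, 0.82, 0.10, 0.05],
        [0.00, 0.00, 0.06, 0.80, 0.10],
        [0.00, 0.00, 0.03, 0.10, 0.85],
    ]
)


@pytest.fixture(scope="session")
def stem_confusion() -> ConfusionMatrix:
    return ConfusionMatrix(STEM_CONFUSION)


@pytest.fixture(scope="session")
def flower_confusion() -> ConfusionMatrix:
    return ConfusionMatrix(FLOWER_CONFUSION)


@pytest.fixture(scope="session")
def stem_scores() -> ScoreVector:
    return ScoreVector(np.array([0.8, 0.1, 0.05, 0.025, 0.025]))


@pytest.fixture(scope="session")
def flower_scores() -> ScoreVector:
    return ScoreVector(np.array([0.1, 0.8, 0.1, 0.0, 0.0]))


@pytest.fixture(scope="session")
def stages():
    return default_stages(5)
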