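import numpy as np
import pytest

from phenonet import SurveyDataset, working_dog_survey
from phenonet.simulate import (
    GroupConfig,
    TrueNetworkSpec,
    generate_survey,
    generate_true_network,
    thresholds_from_probs,
)


@pytest.fixture(scope="session")
def fixture_survey():
    """The study-shaped synthetic dataset (117 + 54 dogs, 20 descriptors)."""
    return working_dog_survey(0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_survey():
    """Quick 120-subject, 6-descriptor strong-signal dataset, fully observed."""
    spec = TrueNetworkSpec(p=6, density=0.4, weight_low=0.4, weight_high=0.5,
                           seed=11)
    W = generate_true_network(spec)
    thr = thresholds_from_probs(np.tile([0.1, 0.2, 0.3, 0.25, 0.15], (6, 1)))
    groups = [
        GroupConfig(name="a", n_subjects=80, n_raters=50, thresholds=thr,
                    rater_sd=0.0, missing_rate=0.0),
        GroupConfig(name="b", n_subjects=40, n_raters=30, thresholds=thr,
                    rater_sd=0.0, missing_rate=0.0),
    ]
    return generate_survey(W, groups, seed=7, truth=spec)


def make_survey(responses, **kw):
    """SurveyDataset from a plain response matrix with default metadata."""
    responses = np.asarray(responses)
    n = responses.shape[0]
    defaults = dict(
        group=np.array(["g1"] * n),
        rater_id=np.array([f"r{i}" for i in range(n)]),
        descriptor_labels=[f"d{j}" for j in range(responses.shape[1])],
    )
    defaults.update(kw)
    return SurveyDataset(responses=responses, **defaults)
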