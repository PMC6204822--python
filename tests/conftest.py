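import numpy as np
import pytest

from sealteb import classifier as clf
from sealteb import generate_captive_session
from sealteb.features import EpochConfig, epoch_features


@pytest.fixture(scope="session")
def captive_session():
    """A 4-h balanced captive session at 1 Hz (deterministic)."""
    return generate_captive_session(seed=3, duration_s=4 * 3600)


@pytest.fixture(scope="session")
def captive_features(captive_session):
    trace, labels = captive_session
    return epoch_features(trace, labels, EpochConfig(1, 21))


@pytest.fixture(scope="session")
def trained_model(captive_features):
    """A quick grid-searched model on the shared session."""
    cfg = clf.TrainConfig(
        parameter_grid={"max_depth": (3,), "learning_rate": (0.3,),
                        "n_estimators": (50,), "subsample": (1.0,)},
        cv_folds=3, seed=3,
    )
    return clf.train_gbm(captive_features, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
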