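import numpy as np
import pytest
from hypothesis import settings

import myolock as ml

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_system() -> ml.TrainedSystem:
    """Classifier + thresholds trained on a default synthetic offline session."""
    return ml.train_system(ml.GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def separable_features() -> ml.FeatureMatrix:
    """Per-class offline feature matrix from the separable configuration."""
    rec = ml.generate_session(ml.offline_protocol(), ml.separable_params(seed=3))
    return ml.per_class_feature_matrix(rec)


@pytest.fixture(scope="session")
def online_result(default_system) -> ml.OnlineResult:
    """One online session, all scenarios, with burst-corrupted OCO."""
    return ml.run_online_session(
        default_system, session_seed=42, corrupt=(0.2, 3, 4242)
    )


def random_stream(rng, n, hysteresis):
    """A random (detector, OCO, thresholds) triple exercising all states."""
    onset = 1.0
    offset = 1.6 if hysteresis else 1.0
    detector = rng.choice(
        [0.2, 0.8, 1.05, 1.3, 1.8, 3.0], size=n,
        p=[0.15, 0.15, 0.15, 0.2, 0.2, 0.15],
    )
    classes = list(ml.ACTIVE_CLASSES) + ["NM"]
    oco = rng.choice(classes, size=n, p=[0.12] * 6 + [0.28])
    if hysteresis:
        thresholds = ml.ThresholdSet(
            kind="MMG", onset=onset,
            offset_map={c: offset for c in ml.ACTIVE_CLASSES},
        )
    else:
        thresholds = ml.ThresholdSet(kind="MAV", onset=onset, offset=offset)
    return detector, oco, thresholds
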