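"""Shared fixtures: small synthetic cohorts and preprocessed feature sets."""

import numpy as np
import pandas as pd
import pytest

from mirtoo.matrix import ExpressionMatrix
from mirtoo.preprocess import (
    exclude_mirnas,
    log_transform,
    merge_classes,
    normalize_median,
)
from mirtoo.synthetic import (
    SimulationConfig,
    make_class_profiles,
    simulate_metastases,
    simulate_reference_cohort,
)


def preprocess_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standard raw -> classifier-ready chain used across tests."""
    return log_transform(exclude_mirnas(normalize_median(matrix)))


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def reference_cohort(study_config):
    """17-class training cohort: profiles, raw matrix, metadata."""
    profiles = make_class_profiles(17, config=study_config)
    matrix, meta = simulate_reference_cohort(profiles, study_config)
    return profiles, matrix, meta


@pytest.fixture(scope="session")
def training_set(reference_cohort):
    """Classifier-ready features X (87 miRNAs) and merged labels y."""
    _, matrix, meta = reference_cohort
    feats = preprocess_features(matrix)
    y = merge_classes(meta["class_label"]).to_numpy()
    return feats.data, y


@pytest.fixture(scope="session")
def heldout_metastases(reference_cohort, study_config):
    """One held-out metastasis per class, preprocessed, with hidden truth."""
    profiles, _, _ = reference_cohort
    labels = [p.class_label for p in profiles]
    assignments = [
        (f"HOLD{i:02d}", labels[i % len(labels)], "lymph node")
        for i in range(2 * len(labels))
    ]
    matrix, meta = simulate_metastases(
        profiles, study_config, assignments, role="known_metastasis"
    )
    return preprocess_features(matrix).data, meta["true_class"].to_numpy()


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    """Tiny hand-checkable raw matrix."""
    data = pd.DataFrame(
        [[2.0, 4.0, 6.0], [5.0, 5.0, 5.0], [1.0, 2.0, 8.0]],
        index=["s1", "s2", "s3"],
        columns=["miR-a", "miR-b", "miR-c"],
    )
    return ExpressionMatrix(data)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
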