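"""Shared fixtures: tiny hand-built tables and one cached pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from imagene import (
    ExperimentConfig,
    FeatureTable,
    SyntheticDesign,
    run_train,
    write_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_tables():
    """5 samples, 3 imaging features, 2 omics features; no special structure."""
    rng = np.random.default_rng(7)
    imaging = FeatureTable(
        sample_ids=[f"S{i}" for i in range(5)],
        feature_names=["F1", "F2", "F3"],
        values=rng.normal(size=(5, 3)),
        role="imaging",
    )
    omics = FeatureTable(
        sample_ids=[f"S{i}" for i in range(5)],
        feature_names=["G1", "G2"],
        values=rng.normal(size=(5, 2)),
        role="omics",
    )
    return imaging, omics


#: A small but fully featured design: strong plant, a few decoys.
SMALL_DESIGN = dict(
    n_samples=80,
    n_imaging_features=12,
    n_omics_labels=10,
    n_informative_features=3,
    n_planted_labels=3,
    n_drivers_per_label=2,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """CSV pair + manifest for the small planted design (seed 42)."""
    out = tmp_path_factory.mktemp("small_data")
    return write_dataset(SyntheticDesign(seed=42, **SMALL_DESIGN), out)


@pytest.fixture(scope="session")
def train_run(tmp_path_factory, small_dataset):
    """One complete Train-mode run (both scenarios, plots, report), cached."""
    job_dir = tmp_path_factory.mktemp("job")
    config = ExperimentConfig(
        seed=42,
        train_size=0.8,
        test_size=0.2,
        n_permutations=25,
        model_type="decision_tree",
        output_dir=str(job_dir),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        artifacts = run_train(config, small_dataset[0], small_dataset[1])
    return config, artifacts
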