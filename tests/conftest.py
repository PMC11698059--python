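"""Shared fixtures: small synthetic rosters and tiny trained-ish models."""

from __future__ import annotations

import numpy as np
import pytest

import ethoseg as es
from ethoseg.synthetic import StudyConfig


@pytest.fixture(scope="session")
def small_study() -> es.synthetic.StudyDatasets:
    """A reduced roster (3 source / 3 target individuals, 5 min each) for
    unit tests that need real-looking recordings."""
    cfg = StudyConfig(n_source=3, n_target=3, source_duration_s=300.0,
                      target_duration_s=300.0, master_seed=11)
    return es.make_study_datasets(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_study) -> list[es.PreprocessedRecording]:
    return [es.preprocess(r) for r in small_study.source]


@pytest.fixture()
def tiny_model() -> es.SegModel:
    """Small V-Net used wherever only shapes/gradients matter."""
    spec = es.ArchitectureSpec("vnet", ws=32, nb_desc=3, nb_behaviors=4, depth=2)
    return es.build_model(spec, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
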