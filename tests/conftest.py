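"""Shared fixtures: one clean synthetic session and small constructed cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from turngait.features import FeatureMatrix
from turngait.preprocess import resample_50hz, segment_session, synchronize
from turngait.synthgait import GaitProfile, simulate_session


@pytest.fixture(scope="session")
def clean_session():
    """A 2-minute symmetric, noise-free session (default profile)."""
    return simulate_session(GaitProfile(), duration=120, label="NF", seed=11)


@pytest.fixture(scope="session")
def clean_bundle(clean_session):
    """The clean session taken through resampling, sync and segmentation."""
    recs = [resample_50hz(r) for r in clean_session.recordings.values()]
    session = synchronize(recs)
    steps, turns, straights = segment_session(session)
    return clean_session, session, steps, turns, straights


def _gaussian_matrix(n_per_class: int, n_features: int, shift: float,
                     seed: int) -> FeatureMatrix:
    """Two Gaussian classes; the first three features carry the class shift."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    labels = np.array(["NF"] * n_per_class + ["PF"] * n_per_class)
    X[labels == "PF", :3] += shift
    ids = [f"P{i:03d}" for i in range(n)]
    df = pd.DataFrame(X, index=ids,
                      columns=[f"f{j:03d}" for j in range(n_features)])
    return FeatureMatrix(X=df, labels=pd.Series(labels, index=ids, name="label"))


@pytest.fixture(scope="session")
def separable_matrix() -> FeatureMatrix:
    """Widely separated classes: every sensible classifier should be perfect."""
    return _gaussian_matrix(n_per_class=10, n_features=12, shift=8.0, seed=21)


@pytest.fixture(scope="session")
def null_matrix() -> FeatureMatrix:
    """Label-independent features: no class signal at all."""
    return _gaussian_matrix(n_per_class=20, n_features=20, shift=0.0, seed=22)


@pytest.fixture(scope="session")
def weak_matrix() -> FeatureMatrix:
    """Moderately separated classes for rank-behaviour tests."""
    return _gaussian_matrix(n_per_class=10, n_features=12, shift=0.8, seed=23)
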