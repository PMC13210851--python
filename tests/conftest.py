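"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gaitshift.conditions import build_condition_profiles
from gaitshift.pipeline import preprocess_manifest
from gaitshift.synth import CohortConfig, sample_participant, simulate_cohort, simulate_traversal


@pytest.fixture(scope="session")
def participant():
    return sample_participant("p01", seed=11)


@pytest.fixture(scope="session")
def sober_profile():
    return build_condition_profiles(["none"])[0]


@pytest.fixture(scope="session")
def impaired_profile():
    return build_condition_profiles(["orange"])[0]


@pytest.fixture(scope="session")
def sober_traversal(participant, sober_profile):
    return simulate_traversal(participant, sober_profile, length=1500, seed=21)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """2 participants x 6 conditions, short walks; manifest plus directory."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(n_participants=2, active_length_range=(1900, 2400),
                       active_length_mean=2050, seed=42)
    manifest = simulate_cohort(cfg, out)
    return cfg, manifest


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    _, manifest = small_cohort
    return preprocess_manifest(manifest)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
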