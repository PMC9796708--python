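"""Shared fixtures: small synthetic cohorts and kinectome builders."""

from __future__ import annotations

import numpy as np
import pytest

import kinectome as kc


def build_kinectomes(pairs, quantity, axis, session_index=0):
    """Test-session (or retest) kinectomes for every subject, sorted by id."""
    return [
        kc.build_kinectome(
            kc.axis_series(pairs[sid][session_index], quantity, axis)
        )
        for sid in sorted(pairs)
    ]


def edge_vectors(pairs, quantity, axis):
    """(test, retest) edge-vector lists for a paired cohort."""
    test = [kc.vectorize(k) for k in build_kinectomes(pairs, quantity, axis, 0)]
    retest = [kc.vectorize(k) for k in build_kinectomes(pairs, quantity, axis, 1)]
    return test, retest


@pytest.fixture(scope="session")
def healthy_cohort():
    trials, subjects = kc.generate_cohort(
        kc.CohortSpec(n_subjects=10, mode="healthy", seed=11)
    )
    return kc.validate_session(trials, subjects), subjects


@pytest.fixture(scope="session")
def pd_cohort():
    trials, subjects = kc.generate_cohort(
        kc.CohortSpec(n_subjects=10, mode="parkinsonian", seed=12)
    )
    return kc.validate_session(trials, subjects), subjects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
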