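"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from semgrasp.pipeline import prepare_trial

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from semgrasp.simulate import SynthConfig, generate_dataset


def brute_force_filtered_posteriors(pi: np.ndarray, T: np.ndarray, logB: np.ndarray) -> np.ndarray:
    """Filtered posteriors by exhaustive summation over all state prefixes.

    Independent of the forward recursion: for each epoch e the posterior
    over the last state is the normalized sum of joint path probabilities
    over every state sequence of length e+1.
    """
    n, S = logB.shape
    posts = np.empty((n, S))
    for e in range(n):
        probs = np.zeros(S)
        for path in itertools.product(range(S), repeat=e + 1):
            lp = np.log(pi[path[0]]) + logB[0, path[0]]
            for i in range(1, e + 1):
                lp += np.log(T[path[i - 1], path[i]]) + logB[i, path[i]]
            probs[path[-1]] += np.exp(lp)
        posts[e] = probs / probs.sum()
    return posts


@pytest.fixture(scope="session")
def small_dataset():
    """Eight default-condition synthetic trials, featurized and labeled."""
    trials = generate_dataset(SynthConfig(), 8, seed=11)
    return [prepare_trial(t.as_trial_data()) for t in trials]


@pytest.fixture(scope="session")
def study_dataset():
    """Twenty default-condition trials: the study-scale synthetic dataset."""
    trials = generate_dataset(SynthConfig(), 20, seed=1)
    return [prepare_trial(t.as_trial_data()) for t in trials]


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated states: strong, low-jitter activation, labels aligned
    with the generator's activation window (lead-matched grasp/release)."""
    cfg = SynthConfig(
        flexor_amp=0.6,
        extensor_amp=0.45,
        extensor_tone=0.2,
        envelope_jitter=0.03,
        floor_amp=0.02,
    )
    trials = generate_dataset(cfg, 8, shift_schedule=("center",), seed=5)
    return [
        prepare_trial(t.as_trial_data(), release_len_ms=300.0, grasp_lead_ms=300.0)
        for t in trials
    ]
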