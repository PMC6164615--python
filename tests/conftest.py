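"""Shared fixtures: tiny random CRF instances and brute-force oracles.

The enumeration oracles deliberately re-derive every quantity by summing
over all 2^L label chains, independently of the dynamic-programming code
they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from disocrf.crf import CRFModel, ObservationSequence, sequence_score


def random_instance(rng: np.random.Generator, max_len: int = 10, max_feat: int = 5):
    """One random (model, observation) pair with small weights."""
    L = int(rng.integers(1, max_len + 1))
    F = int(rng.integers(1, max_feat + 1))
    X = rng.normal(size=(L, F))
    model = CRFModel(rng.normal(scale=0.8, size=(2, 2)), rng.normal(scale=0.8, size=(F, 2)))
    return model, ObservationSequence(f"rand-L{L}-F{F}", X)


def enumerate_chains(L: int):
    for chain in itertools.product("OD", repeat=L):
        yield "".join(chain)


def brute_log_partition(model: CRFModel, obs: ObservationSequence) -> float:
    scores = [sequence_score(model, obs, chain) for chain in enumerate_chains(obs.length)]
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def brute_marginals(model: CRFModel, obs: ObservationSequence) -> np.ndarray:
    L = obs.length
    logZ = brute_log_partition(model, obs)
    marg = np.zeros((L, 2))
    for chain in enumerate_chains(L):
        p = math.exp(sequence_score(model, obs, chain) - logZ)
        for i, c in enumerate(chain):
            marg[i, 0 if c == "O" else 1] += p
    return marg


def brute_viterbi(model: CRFModel, obs: ObservationSequence) -> tuple[str, float]:
    best, best_score = None, -math.inf
    for chain in enumerate_chains(obs.length):  # 'O...' enumerated before 'D...' per position
        s = sequence_score(model, obs, chain)
        if s > best_score:
            best, best_score = chain, s
    return best, best_score


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
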