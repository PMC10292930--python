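"""Shared fixtures: an exhaustive-enumeration oracle for small chains and
toy parameter factories."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from readphases.hsmc import HSMCParams
from readphases.sojourn import absorbing, shifted_binomial, shifted_negative_binomial


def brute_force(params: HSMCParams, seq):
    """Enumerate every segmentation of ``seq`` into state runs.

    Returns a dict with the exact log-likelihood, MAP state path, smoothed
    marginals, expected initial/transition counts and expected
    completed/censored sojourn counts — all computed independently of the
    recursive implementation.
    """
    seq = np.asarray(seq)
    T = len(seq)
    K = params.n_states
    tot = 0.0
    best_p, best_states = -np.inf, None
    marg = np.zeros((T, K))
    init = np.zeros(K)
    trans = np.zeros((K, K))
    dur_comp = np.zeros((K, T))
    dur_cens = np.zeros((K, T))
    for R in range(1, T + 1):
        for cuts in itertools.combinations(range(1, T), R - 1):
            bounds = [0, *cuts, T]
            durs = [bounds[i + 1] - bounds[i] for i in range(R)]
            for states in itertools.product(range(K), repeat=R):
                p = params.initial[states[0]]
                for r in range(R):
                    j = states[r]
                    law = params.sojourns[j]
                    if r < R - 1:
                        if law.family == "absorbing":
                            p = 0.0
                            break
                        p *= law.pmf(np.array([durs[r]]))[0]
                        p *= params.transitions[j, states[r + 1]]
                    else:
                        p *= law.sf(np.array([float(durs[r])]))[0]
                    for t in range(bounds[r], bounds[r + 1]):
                        p *= params.emissions[j, seq[t]]
                    if p == 0.0:
                        break
                if p > 0.0:
                    tot += p
                    full = np.concatenate(
                        [[states[r]] * durs[r] for r in range(R)])
                    init[states[0]] += p
                    for t in range(T):
                        marg[t, full[t]] += p
                    for r in range(R - 1):
                        trans[states[r], states[r + 1]] += p
                        dur_comp[states[r], durs[r] - 1] += p
                    dur_cens[states[-1], durs[-1] - 1] += p
                    if p > best_p:
                        best_p, best_states = p, full
    if tot == 0.0:
        return {"loglik": -np.inf}
    return {
        "loglik": math.log(tot),
        "map_states": best_states,
        "smoothed": marg / tot,
        "initial": init / tot,
        "transitions": trans / tot,
        "dur_complete": dur_comp / tot,
        "dur_censored": dur_cens / tot,
    }


def random_toy_params(rng, K: int, M: int = 4,
                      with_absorbing: bool = False) -> HSMCParams:
    """A random valid small chain for oracle comparisons."""
    pi = rng.dirichlet(np.ones(K))
    A = np.zeros((K, K))
    sojourns = []
    for j in range(K):
        if K == 1 or (with_absorbing and j == K - 1):
            sojourns.append(absorbing())
            continue
        row = rng.dirichlet(np.ones(K - 1))
        A[j, [i for i in range(K) if i != j]] = row
        if rng.random() < 0.5:
            sojourns.append(
                shifted_binomial(int(rng.integers(1, 4)), rng.uniform(0.2, 0.8)))
        else:
            sojourns.append(
                shifted_negative_binomial(rng.uniform(0.5, 3.0),
                                          rng.uniform(0.3, 0.8)))
    em = rng.dirichlet(np.ones(M), size=K)
    return HSMCParams(pi, A, sojourns, em)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by pipeline tests."""
    from readphases.synthetic import GeneratorConfig, simulate_cohort

    return simulate_cohort(GeneratorConfig(n_participants=4, n_texts=9, seed=11))
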