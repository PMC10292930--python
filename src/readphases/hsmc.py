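"""Hidden semi-Markov chains with categorical emissions.

The observed process is a short categorical sequence (Read modes); the hidden
process is a semi-Markov chain: a state is entered, occupied for a number of
steps drawn from a state-specific sojourn law, then left through a transition
matrix with no self-transitions.  The final sojourn is right-censored: the
trial ends by reader decision, not by state exit, so the survival function of
the sojourn law (identically 1 for an absorbing state) enters the likelihood
in place of its mass function.

Implementation notes
--------------------
All smoothing quantities are computed on the *countdown* augmentation of the
chain: the augmented state is (state, remaining occupancy), with remaining
occupancy capped at the sequence length and the tail mass of the sojourn law
lumped into the cap.  Because any path whose countdown is still positive at
the end of the sequence is exactly a right-censored final sojourn, this
representation reproduces the censored likelihood *exactly* — there is no
duration-truncation error.  The forward/backward recursions are scaled per
step and compiled with numba; sequences are processed individually (they are
short), so no padding is involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .readmodes import N_MODES
from .sojourn import ABSORBING, SojournLaw, fit_sojourn_law

__all__ = [
    "HSMCParams",
    "Posterior",
    "sequence_log_likelihood",
    "total_log_likelihood",
    "forward_backward",
    "viterbi_restore",
    "state_entropy",
    "bic",
    "n_free_parameters",
    "em_fit",
    "EMTrace",
]

_TOL = 1e-8


@dataclass
class HSMCParams:
    """Parameter set of a K-state hidden semi-Markov chain.

    Attributes
    ----------
    initial : (K,) array
        Initial state probabilities.
    transitions : (K, K) array
        Conditional-on-exit transition matrix.  Non-absorbing rows sum to 1
        and have a zero diagonal; an absorbing state has an all-zero row.
    sojourns : list of SojournLaw
        One occupancy law per state; the law of an absorbing state is the
        ``absorbing`` family.
    emissions : (K, M) array
        Categorical emission distribution per state over the Read modes.
    """

    initial: np.ndarray
    transitions: np.ndarray
    sojourns: list
    emissions: np.ndarray

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        K = self.initial.size
        if self.transitions.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if len(self.sojourns) != K:
            raise ValueError("need one sojourn law per state")
        if self.emissions.shape[0] != K:
            raise ValueError("emission matrix shape mismatch")
        if abs(self.initial.sum() - 1.0) > 1e-6:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(self.initial < -_TOL):
            raise ValueError("negative initial probability")
        n_abs = 0
        for j in range(K):
            row = self.transitions[j]
            if self.sojourns[j].family == ABSORBING:
                n_abs += 1
                if row.sum() > 1e-6:
                    raise ValueError(f"absorbing state {j} has outgoing mass")
            else:
                if abs(row.sum() - 1.0) > 1e-6:
                    raise ValueError(f"transition row {j} must sum to 1")
                if abs(row[j]) > 1e-6:
                    raise ValueError(f"state {j} has a self-transition")
            if abs(self.emissions[j].sum() - 1.0) > 1e-6:
                raise ValueError(f"emission row {j} must sum to 1")
        if n_abs > 1:
            raise ValueError("at most one absorbing state is supported")

    # ------------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return self.initial.size

    @property
    def n_symbols(self) -> int:
        return self.emissions.shape[1]

    def absorbing_states(self) -> list[int]:
        return [j for j in range(self.n_states)
                if self.sojourns[j].family == ABSORBING]

    def transitory_states(self, eps: float = 0.01) -> list[int]:
        """States never re-entered: all incoming transition probabilities
        below ``eps`` (the display threshold used for structure read-off)."""
        out = []
        for j in range(self.n_states):
            if self.sojourns[j].family == ABSORBING:
                continue
            if np.all(self.transitions[:, j] < eps):
                out.append(j)
        return out

    def sojourn_means(self) -> np.ndarray:
        return np.array([law.mean for law in self.sojourns])

    def duration_tables(self, D: int):
        """Tabulated sojourn pmf and survival over durations 1..D."""
        d = np.arange(1, D + 1)
        pmf = np.stack([law.pmf(d) for law in self.sojourns])
        sf = np.stack([law.sf(d.astype(float)) for law in self.sojourns])
        return pmf, sf

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "initial": self.initial.tolist(),
            "transitions": self.transitions.tolist(),
            "sojourns": [law.to_dict() for law in self.sojourns],
            "emissions": self.emissions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSMCParams":
        return cls(
            initial=np.array(d["initial"], dtype=float),
            transitions=np.array(d["transitions"], dtype=float),
            sojourns=[SojournLaw.from_dict(s) for s in d["sojourns"]],
            emissions=np.array(d["emissions"], dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "HSMCParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Posterior:
    """E-step container for one sequence: smoothed state probabilities,
    expected counts and the sequence log-likelihood."""

    smoothed: np.ndarray               # (T, K) marginal state probabilities
    expected_transitions: np.ndarray   # (K, K)
    expected_initial: np.ndarray       # (K,)
    duration_complete: np.ndarray      # (K, D) expected completed sojourns
    duration_censored: np.ndarray      # (K, D) expected censored sojourns
    log_likelihood: float


# ======================================================================
# compiled countdown forward/backward
# ======================================================================

@njit(cache=True)
def _kernel_forward(pi, A, pmf, sf, em, obs, alpha, c):
    """Scaled forward pass for one sequence on the countdown augmentation.

    ``alpha`` has shape (T, K, T): alpha[t, k, d-1] is the scaled joint
    probability of being in state k at t with remaining occupancy d; entry
    occupancies use pmf(d) for d < T and the survival tail at d = T.
    Returns 0 on success, -(t+1) when the observation at t has zero
    probability.
    """
    T = obs.shape[0]
    K = pi.shape[0]
    for k in range(K):
        e = em[k, obs[0]]
        for d in range(T):
            pe = pmf[k, d] if d < T - 1 else sf[k, T - 1]
            alpha[0, k, d] = pi[k] * pe * e
    s = 0.0
    for k in range(K):
        for d in range(T):
            s += alpha[0, k, d]
    c[0] = s
    if s <= 0.0:
        return -1
    inv = 1.0 / s
    for k in range(K):
        for d in range(T):
            alpha[0, k, d] *= inv
    for t in range(1, T):
        s = 0.0
        for i in range(K):
            g = 0.0
            for j in range(K):
                g += alpha[t - 1, j, 0] * A[j, i]
            e = em[i, obs[t]]
            for d in range(T):
                pe = pmf[i, d] if d < T - 1 else sf[i, T - 1]
                shift = alpha[t - 1, i, d + 1] if d + 1 < T else 0.0
                v = (shift + g * pe) * e
                alpha[t, i, d] = v
                s += v
        c[t] = s
        if s <= 0.0:
            return -(t + 1)
        inv = 1.0 / s
        for k in range(K):
            for d in range(T):
                alpha[t, k, d] *= inv
    return 0


@njit(cache=True)
def _kernel_backward(A, pmf, sf, em, obs, alpha, c,
                     init_c, trans_c, emis_c, dur_comp, dur_cens, smoothed):
    """Scaled backward pass accumulating E-step sufficient statistics.

    Expected initial, transition and emission counts, completed-sojourn
    counts ``dur_comp[k, d-1]`` and right-censored counts ``dur_cens[k, v-1]``
    are *added into* the supplied arrays; smoothed state marginals are
    written to ``smoothed`` (T, K).
    """
    T = obs.shape[0]
    K = A.shape[0]
    beta = np.ones((K, T))
    newbeta = np.empty((K, T))
    H = np.empty(K)
    for t in range(T - 1, -1, -1):
        if t < T - 1:
            inv = 1.0 / c[t + 1]
            for i in range(K):
                e = em[i, obs[t + 1]] * inv
                h = 0.0
                for d in range(T):
                    pe = pmf[i, d] if d < T - 1 else sf[i, T - 1]
                    h += pe * beta[i, d]
                H[i] = h * e
            # expected transitions and entry (sojourn-start) posteriors
            for i in range(K):
                g = 0.0
                for j in range(K):
                    aj = alpha[t, j, 0] * A[j, i]
                    trans_c[j, i] += aj * H[i]
                    g += aj
                e = em[i, obs[t + 1]] * inv
                # entries at time s = t+1: completed iff d < T - s
                lim = T - t - 2        # d index strictly below => complete
                for d in range(T):
                    pe = pmf[i, d] if d < T - 1 else sf[i, T - 1]
                    eta = g * pe * e * beta[i, d]
                    if d < lim:
                        dur_comp[i, d] += eta
                    else:
                        dur_cens[i, T - t - 2] += eta
            for i in range(K):
                b1 = 0.0
                for j in range(K):
                    b1 += A[i, j] * H[j]
                newbeta[i, 0] = b1
                e = em[i, obs[t + 1]] * inv
                for d in range(1, T):
                    newbeta[i, d] = e * beta[i, d - 1]
            for i in range(K):
                for d in range(T):
                    beta[i, d] = newbeta[i, d]
        for k in range(K):
            g = 0.0
            for d in range(T):
                g += alpha[t, k, d] * beta[k, d]
            smoothed[t, k] = g
            emis_c[k, obs[t]] += g
    for k in range(K):
        init_c[k] += smoothed[0, k]
        # initial entries: completed iff duration < T
        for d in range(T - 1):
            dur_comp[k, d] += alpha[0, k, d] * beta[k, d]
        dur_cens[k, T - 1] += alpha[0, k, T - 1] * beta[k, T - 1]
    return 0


def _as_sequences(sequences) -> list[np.ndarray]:
    out = []
    for s in sequences:
        a = np.ascontiguousarray(np.asarray(s, dtype=np.int64))
        if a.ndim != 1 or a.size < 1:
            raise ValueError("each sequence must be a non-empty 1-D array")
        out.append(a)
    return out


class _Counts:
    def __init__(self, K: int, M: int, D: int):
        self.initial = np.zeros(K)
        self.transitions = np.zeros((K, K))
        self.emissions = np.zeros((K, M))
        self.dur_complete = np.zeros((K, D))
        self.dur_censored = np.zeros((K, D))
        self.loglik = 0.0


def _check_alphabet(params: HSMCParams, seqs) -> None:
    for s in seqs:
        if s.min() < 0 or s.max() >= params.n_symbols:
            raise ValueError(
                f"symbol out of range 0..{params.n_symbols - 1}")


def _run_e_step(params: HSMCParams, seqs, keep_marginals: bool = False):
    """Full E-step over a list of sequences; returns (_Counts, marginals)."""
    _check_alphabet(params, seqs)
    K, M = params.n_states, params.n_symbols
    D = max(len(s) for s in seqs)
    pmf, sf = params.duration_tables(D)
    counts = _Counts(K, M, D)
    marginals = [] if keep_marginals else None
    pi, A, em = params.initial, params.transitions, params.emissions
    for s in seqs:
        T = s.size
        alpha = np.empty((T, K, T))
        c = np.empty(T)
        status = _kernel_forward(pi, A, pmf[:, :T].copy(), sf[:, :T].copy(),
                                 em, s, alpha, c)
        if status != 0:
            raise FloatingPointError(
                f"zero-probability observation at position {-status - 1}: "
                "some symbol cannot be emitted by any reachable state"
            )
        smoothed = np.empty((T, K))
        _kernel_backward(A, pmf[:, :T].copy(), sf[:, :T].copy(), em, s,
                         alpha, c,
                         counts.initial, counts.transitions, counts.emissions,
                         counts.dur_complete, counts.dur_censored, smoothed)
        counts.loglik += float(np.log(c).sum())
        if keep_marginals:
            marginals.append(smoothed)
    return counts, marginals


# ======================================================================
# public operations
# ======================================================================

def sequence_log_likelihood(params: HSMCParams, seq) -> float:
    """Right-censored log-likelihood of one Read-mode sequence.

    Sums over every segmentation of the sequence into state runs; the final
    run contributes the survival function of its sojourn law.  Returns
    ``-inf`` (without raising) when the observed symbols cannot be emitted.
    """
    s = _as_sequences([seq])[0]
    _check_alphabet(params, [s])
    T = s.size
    K = params.n_states
    pmf, sf = params.duration_tables(T)
    alpha = np.empty((T, K, T))
    c = np.empty(T)
    status = _kernel_forward(params.initial, params.transitions, pmf, sf,
                             params.emissions, s, alpha, c)
    if status != 0:
        return -np.inf
    return float(np.log(c).sum())


def total_log_likelihood(params: HSMCParams, sequences) -> float:
    return float(sum(sequence_log_likelihood(params, s)
                     for s in _as_sequences(sequences)))


def forward_backward(params: HSMCParams, seq) -> Posterior:
    """Smoothed state probabilities and expected counts for one sequence."""
    seqs = _as_sequences([seq])
    counts, marg = _run_e_step(params, seqs, keep_marginals=True)
    return Posterior(
        smoothed=marg[0],
        expected_transitions=counts.transitions,
        expected_initial=counts.initial,
        duration_complete=counts.dur_complete,
        duration_censored=counts.dur_censored,
        log_likelihood=counts.loglik,
    )


def state_entropy(params: HSMCParams, seq):
    """Entropy (nats) of the smoothed state distribution at each position.

    Returns ``(per_position, mean)``; low mean entropy indicates that the
    observed variable identifies the hidden states sharply.
    """
    post = forward_backward(params, seq)
    p = np.clip(post.smoothed, 1e-300, 1.0)
    h = -(post.smoothed * np.log(p)).sum(axis=1)
    h[np.abs(h) < 1e-15] = 0.0
    return h, float(h.mean())


def viterbi_restore(params: HSMCParams, seq) -> np.ndarray:
    """MAP state sequence by explicit-duration Viterbi.

    The final run is scored with the survival function of its sojourn law
    (right censoring).  Ties are broken toward the lower state index of the
    final run, then its shorter duration, then the lower preceding state at
    each segment boundary working backwards.
    """
    seq = _as_sequences([seq])[0]
    _check_alphabet(params, [seq])
    T = seq.size
    K = params.n_states
    with np.errstate(divide="ignore"):
        logpi = np.where(params.initial > 0,
                         np.log(np.clip(params.initial, 1e-300, None)), -np.inf)
        logA = np.where(params.transitions > 0,
                        np.log(np.clip(params.transitions, 1e-300, None)), -np.inf)
        # a large finite floor keeps cumulative sums free of -inf - -inf
        logB = np.where(params.emissions > 0,
                        np.log(np.clip(params.emissions, 1e-300, None)), -1e30)
        dvals = np.arange(1, T + 1)
        logd = np.stack([law.logpmf(dvals) for law in params.sojourns])
        logsf = np.stack([law.logsf(dvals) for law in params.sojourns])

    ce = np.zeros((K, T + 1))
    ce[:, 1:] = np.cumsum(logB[:, seq], axis=1)

    W = np.full((T, K), -np.inf)      # W[s, j]: best score entering j at s
    W[0] = logpi
    bp_prev = np.zeros((T, K), dtype=np.int64)
    V = np.full((T, K), -np.inf)      # V[t, j]: best completed run ending at t
    bp_u = np.zeros((T, K), dtype=np.int64)

    for t in range(T - 1):
        u = np.arange(1, t + 2)                         # durations ending at t
        seg = ce[:, t + 1][:, None] - ce[:, t + 1 - u]
        cand = seg + logd[:, u - 1] + W[t + 1 - u].T    # entry s = t+1-u
        bp_u[t] = np.argmax(cand, axis=1)               # first max: shortest u
        V[t] = cand[np.arange(K), bp_u[t]]
        nxt = V[t][:, None] + logA                      # (prev, next)
        bp_prev[t + 1] = np.argmax(nxt, axis=0)         # first max: lowest state
        W[t + 1] = nxt[bp_prev[t + 1], np.arange(K)]

    u = np.arange(1, T + 1)
    segF = ce[:, T][:, None] - ce[:, T - u]
    final = segF + logsf[:, u - 1] + W[T - u].T         # (K, T)
    j, ui = np.unravel_index(np.argmax(final), final.shape)
    if np.isneginf(final[j, ui]):
        raise FloatingPointError("sequence has zero probability under params")
    states = np.empty(T, dtype=np.int64)
    s = T - (ui + 1)
    states[s:] = j
    while s > 0:
        i = bp_prev[s, j]
        u_prev = bp_u[s - 1, i] + 1
        states[s - u_prev: s] = i
        j, s = i, s - u_prev
    return states


def n_free_parameters(params: HSMCParams) -> int:
    """Independently estimated parameters: K-1 initial probabilities, free
    off-diagonal transition entries minus one row constraint per
    non-absorbing row, two parameters per parametric sojourn law and M-1
    emission probabilities per state."""
    K = params.n_states
    d = K - 1
    for j in range(K):
        if params.sojourns[j].family == ABSORBING:
            continue
        free = int(np.sum(params.transitions[j] > 1e-12))
        d += max(free - 1, 0)
        d += 2
    d += K * (params.n_symbols - 1)
    return d


def bic(params: HSMCParams, sequences) -> float:
    """-2 log L + d log N with N the total number of observed symbols."""
    seqs = _as_sequences(sequences)
    N = sum(len(s) for s in seqs)
    ll = total_log_likelihood(params, seqs)
    return -2.0 * ll + n_free_parameters(params) * math.log(N)


# ======================================================================
# EM estimation
# ======================================================================

@dataclass
class EMTrace:
    log_likelihoods: list = field(default_factory=list)
    restart_log_likelihoods: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _symbol_frequencies(seqs, M):
    freq = np.bincount(np.concatenate(seqs), minlength=M).astype(float)
    freq = np.maximum(freq, 1.0)
    freq /= freq.sum()
    return freq


def _crude_init(seqs, K, M, rng, transition_mask=None) -> HSMCParams:
    """Starting point from a crude symbol-based segmentation.

    A random surjective symbol-to-state assignment hard-labels every
    fixation; smoothed emission, transition, initial and mean-run-length
    statistics of that segmentation seed the parameters.
    """
    freq = _symbol_frequencies(seqs, M)
    if K == 1:
        return HSMCParams(np.ones(1), np.zeros((1, 1)),
                          [SojournLaw(ABSORBING)], freq[None, :].copy())

    sym_state = np.empty(M, dtype=np.int64)
    perm = rng.permutation(M)
    for i, m in enumerate(perm):
        sym_state[m] = i % K if i < K else rng.integers(K)
    if K > M:
        sym_state = rng.integers(0, K, size=M)
        sym_state[rng.permutation(M)[: min(K, M)]] = np.arange(min(K, M))

    em_counts = np.full((K, M), 0.5)
    tr_counts = np.full((K, K), 0.2)
    init_counts = np.full(K, 0.5)
    run_sum = np.full(K, 1.0)
    run_n = np.full(K, 1.0)
    for s in seqs:
        hard = sym_state[s]
        if K > M:
            hard = hard.copy()
            extra = rng.integers(0, K, size=len(hard))
            swap = rng.random(len(hard)) < 0.2
            hard[swap] = extra[swap]
        init_counts[hard[0]] += 1.0
        np.add.at(em_counts, (hard, s), 1.0)
        change = np.flatnonzero(np.diff(hard) != 0)
        bounds = np.concatenate([[-1], change, [len(hard) - 1]])
        runs = np.diff(bounds)
        starts = hard[np.concatenate([[0], change + 1])]
        np.add.at(run_sum, starts, runs)
        np.add.at(run_n, starts, 1.0)
        if change.size:
            np.add.at(tr_counts, (hard[change], hard[change + 1]), 1.0)

    em_counts *= rng.gamma(8.0, 1.0, size=(K, M))  # decorrelate restarts
    em = em_counts / em_counts.sum(axis=1, keepdims=True)
    pi = init_counts / init_counts.sum()
    means = np.maximum(run_sum / run_n * rng.uniform(0.8, 1.5, size=K), 1.05)
    return _assemble_init(pi, tr_counts, means, em, transition_mask)


def _alternation_init(seqs, K, M, rng, pair, transition_mask=None,
                      mixture_state: bool = False) -> HSMCParams:
    """Starting point seeding a short alternation cycle between two states.

    States 0 and 1 are biased toward the two symbols of ``pair`` with high
    mutual transition probability and near-1 mean sojourns; remaining states
    start near the global symbol frequencies with spread-out sojourn means.
    Short high-probability alternation cycles are precisely the regime the
    phase model targets, and plain random restarts rarely propose them.

    With ``mixture_state`` and K >= 3, state 2 starts as an *exact*
    two-symbol mixture of the pair (structural zeros elsewhere) — emission
    zeros are invariant under EM, so this proposes a boundary-supported
    state that interior starting points can never reach.
    """
    a, b = pair
    freq = _symbol_frequencies(seqs, M)
    em = np.tile(freq, (K, 1))
    em[0] = 0.55 * np.eye(M)[a] + 0.45 * freq
    em[1] = 0.55 * np.eye(M)[b] + 0.45 * freq
    for k in range(2, K):
        row = freq * rng.gamma(6.0, 1.0, size=M)
        em[k] = row / row.sum()
    if mixture_state and K >= 3:
        w = rng.uniform(0.35, 0.65)
        em[2] = w * np.eye(M)[a] + (1.0 - w) * np.eye(M)[b]

    A = np.ones((K, K))
    np.fill_diagonal(A, 0.0)
    A /= A.sum(axis=1, keepdims=True)
    A[0] *= 0.15
    A[0, 1] += 0.85
    A[0] /= A[0].sum()
    A[1] *= 0.15
    A[1, 0] += 0.85
    A[1] /= A[1].sum()

    means = np.empty(K)
    means[0] = means[1] = 1.25
    for k in range(2, K):
        means[k] = rng.uniform(2.0, 12.0)
    pi = rng.dirichlet(np.ones(K))
    return _assemble_init(pi, A, means, em, transition_mask)


def _assemble_init(pi, A, sojourn_means, em, transition_mask):
    A = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    if transition_mask is not None:
        A *= transition_mask
    rs = A.sum(axis=1)
    if np.any(rs <= 0):
        raise ValueError("transition mask leaves a state without exits")
    A /= rs[:, None]
    sojourns = []
    for mu in sojourn_means:
        p = min(max(1.0 / mu, 1e-3), 1 - 1e-3)  # shifted geometric, mean mu
        sojourns.append(SojournLaw("shifted_negative_binomial", (1.0, p)))
    return HSMCParams(pi, A, sojourns, em)


def _restart_inits(seqs, K, M, rng, n_restarts, transition_mask=None):
    """Alternate alternation-seeded and crude-segmentation starting points.

    Alternation pairs are ordered by the product of their symbol
    frequencies, so frequent-symbol cycles are proposed first.
    """
    freq = _symbol_frequencies(seqs, M)
    pairs = [(a, b) for a in range(M) for b in range(M) if a != b]
    pairs.sort(key=lambda ab: -(freq[ab[0]] * freq[ab[1]]))
    pair_i = 0
    for r in range(n_restarts):
        if K >= 2 and r % 2 == 0 and pair_i < len(pairs):
            yield _alternation_init(seqs, K, M, rng, pairs[pair_i],
                                    transition_mask)
            pair_i += 1
        else:
            yield _crude_init(seqs, K, M, rng, transition_mask)


def _m_step(counts: _Counts, transition_mask=None,
            sojourn_families: str = "all") -> HSMCParams:
    K, M = counts.emissions.shape
    occupancy = counts.emissions.sum(axis=1)
    if np.any(occupancy < 1e-3):
        raise RuntimeError(
            "degenerate EM solution: a state has vanishing occupancy; "
            "try a smaller number of states"
        )
    pi = counts.initial / counts.initial.sum()
    em = counts.emissions / occupancy[:, None]

    A = np.zeros((K, K))
    sojourns = []
    tc = counts.transitions.copy()
    if transition_mask is not None:
        tc *= transition_mask
    for j in range(K):
        exits = tc[j].sum()
        if exits < 1e-4 * occupancy[j]:
            # essentially never left: absorbing state
            sojourns.append(SojournLaw(ABSORBING))
        else:
            A[j] = tc[j] / exits
            sojourns.append(
                fit_sojourn_law(counts.dur_complete[j], counts.dur_censored[j],
                                allow_absorbing=False,
                                families=sojourn_families)
            )
    if sum(law.family == ABSORBING for law in sojourns) > 1:
        raise RuntimeError("degenerate EM solution: multiple absorbing states")
    return HSMCParams(pi, A, sojourns, em)


def _em_run(seqs, params, tol, max_iter, trace=None, transition_mask=None,
            sojourn_families: str = "all"):
    prev_ll = -np.inf
    for it in range(max_iter):
        counts, _ = _run_e_step(params, seqs)
        ll = counts.loglik
        if ll + 1e-6 * max(abs(ll), 1.0) < prev_ll:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
            )
        if trace is not None:
            trace.log_likelihoods.append(ll)
        new_params = _m_step(counts, transition_mask, sojourn_families)
        done = np.isfinite(prev_ll) and (ll - prev_ll) < tol * max(abs(ll), 1.0)
        prev_ll = ll
        params = new_params
        if done:
            if trace is not None:
                trace.converged = True
                trace.n_iter = it + 1
            break
    if trace is not None and not trace.converged:
        trace.n_iter = max_iter
    return params, prev_ll


def _consolidate_structure(seqs, params, ll, tol, transition_mask=None,
                           eps: float = 1e-3):
    """Turn numerically vanishing structure into exact structural zeros.

    Interior EM can only approach boundary solutions (a transitory state's
    zero column, an absorbing state's zero row) asymptotically; transition
    probabilities below ``eps`` are pruned to exact zeros, a state with
    essentially no expected exits becomes absorbing, and EM is re-run
    briefly.  The consolidated model is kept only if its log-likelihood is
    not worse — this is numerical cleanup, not model selection — so the
    reported fit and its free-parameter count describe the structure the
    estimate actually converged to.
    """
    counts, _ = _run_e_step(params, seqs)
    occupancy = counts.emissions.sum(axis=1)
    A = params.transitions.copy()
    sojourns = list(params.sojourns)
    changed = False
    for j in range(params.n_states):
        if sojourns[j].family == ABSORBING:
            continue
        if counts.transitions[j].sum() < eps * occupancy[j]:
            A[j] = 0.0
            sojourns[j] = SojournLaw(ABSORBING)
            changed = True
            continue
        small = (A[j] > 0) & (A[j] < eps)
        if small.any():
            A[j, small] = 0.0
            A[j] /= A[j].sum()
            changed = True
    if not changed or sum(s.family == ABSORBING for s in sojourns) > 1:
        return params, ll
    try:
        cand = HSMCParams(params.initial, A, sojourns, params.emissions)
        cand, cand_ll = _em_run(seqs, cand, tol, 100,
                                transition_mask=transition_mask)
    except (ValueError, RuntimeError, FloatingPointError, AssertionError):
        return params, ll
    if cand_ll >= ll - 1e-6 * abs(ll):
        return cand, cand_ll
    return params, ll


def em_fit(
    sequences,
    K: int,
    n_restarts: int = 10,
    seed=None,
    tol: float = 1e-7,
    max_iter: int = 500,
    init_iter: int = 40,
    n_symbols: int = N_MODES,
    transition_mask=None,
):
    """Maximum-likelihood estimation by EM with random restarts.

    Each restart runs a short exploratory EM (``init_iter`` iterations); the
    best restart by log-likelihood is then polished to convergence and its
    vanishing structure consolidated into exact zeros.  Returns
    ``(HSMCParams, EMTrace)``.
    """
    seqs = _as_sequences(sequences)
    if len(seqs) < 2:
        raise ValueError("EM needs at least two sequences")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    trace = EMTrace()
    best = None
    best_ll = -np.inf
    errors = []
    for start in _restart_inits(seqs, K, n_symbols, rng, max(1, n_restarts),
                                transition_mask):
        try:
            cand, ll = _em_run(seqs, start, tol, init_iter,
                               transition_mask=transition_mask,
                               sojourn_families="nb")
        except (RuntimeError, FloatingPointError) as exc:
            errors.append(exc)
            trace.restart_log_likelihoods.append(-np.inf)
            continue
        trace.restart_log_likelihoods.append(ll)
        if ll > best_ll:
            best, best_ll = cand, ll
    if best is None:
        raise RuntimeError(
            "all EM restarts degenerated; try a smaller number of states"
        ) from (errors[-1] if errors else None)
    params, ll = _em_run(seqs, best, tol, max_iter, trace=trace,
                         transition_mask=transition_mask)
    params, _ = _consolidate_structure(seqs, params, ll, tol,
                                       transition_mask=transition_mask)
    return params, trace
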