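"""Linear-chain CRF: log-likelihood, marginals and Viterbi decoding.

The score of a tag sequence y for a sentence of T tokens is

    s(y) = start[y_1] + sum_t P[t, y_t] + sum_t A[y_{t-1}, y_t] + end[y_T]

with unary potentials P (T x K), transition matrix A (K x K) and virtual
start/end potentials.  The log-partition is computed with the forward
algorithm in log space; gradients come from forward-backward marginals.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["crf_forward", "crf_log_likelihood", "crf_marginals", "viterbi_decode"]


def _check(potentials, transitions, start, end):
    potentials = np.asarray(potentials, dtype=float)
    if potentials.ndim != 2 or potentials.shape[0] == 0:
        raise ValueError("potentials must be a non-empty (T, K) matrix")
    K = potentials.shape[1]
    transitions = np.asarray(transitions, dtype=float)
    start = np.zeros(K) if start is None else np.asarray(start, dtype=float)
    end = np.zeros(K) if end is None else np.asarray(end, dtype=float)
    if transitions.shape != (K, K) or start.shape != (K,) or end.shape != (K,):
        raise ValueError("transition/start/end dimensions do not match potentials")
    return potentials, transitions, start, end


def crf_forward(potentials, transitions, start=None, end=None):
    """Forward algorithm; returns (logZ, alphas) with alphas of shape (T, K)."""
    potentials, transitions, start, end = _check(potentials, transitions, start, end)
    T, K = potentials.shape
    alphas = np.empty((T, K))
    alphas[0] = start + potentials[0]
    for t in range(1, T):
        alphas[t] = potentials[t] + logsumexp(alphas[t - 1][:, None] + transitions, axis=0)
    log_z = logsumexp(alphas[-1] + end)
    return log_z, alphas


def _backward(potentials, transitions, end):
    T, K = potentials.shape
    betas = np.empty((T, K))
    betas[-1] = end
    for t in range(T - 2, -1, -1):
        betas[t] = logsumexp(transitions + (potentials[t + 1] + betas[t + 1])[None, :], axis=1)
    return betas


def sequence_score(potentials, transitions, start, end, tags) -> float:
    potentials, transitions, start, end = _check(potentials, transitions, start, end)
    tags = np.asarray(tags, dtype=int)
    if tags.shape[0] != potentials.shape[0]:
        raise ValueError("tag sequence length does not match potentials")
    s = start[tags[0]] + potentials[np.arange(len(tags)), tags].sum() + end[tags[-1]]
    s += transitions[tags[:-1], tags[1:]].sum()
    return float(s)


def crf_log_likelihood(potentials, transitions, tags, start=None, end=None) -> float:
    """Log-probability of ``tags``: score(tags) - logZ.  Always <= 0."""
    potentials, transitions, start, end = _check(potentials, transitions, start, end)
    log_z, _ = crf_forward(potentials, transitions, start, end)
    return sequence_score(potentials, transitions, start, end, tags) - log_z


def crf_marginals(potentials, transitions, start=None, end=None):
    """Posterior tag and transition marginals via forward-backward.

    Returns ``(log_z, unary (T,K), pairwise (T-1,K,K), first (K,), last (K,))``
    where ``first``/``last`` are the tag marginals at the sequence ends (the
    gradients of logZ w.r.t. the start/end potentials).
    """
    potentials, transitions, start, end = _check(potentials, transitions, start, end)
    T, K = potentials.shape
    log_z, alphas = crf_forward(potentials, transitions, start, end)
    betas = _backward(potentials, transitions, end)
    unary = np.exp(alphas + betas - log_z)
    pairwise = np.empty((T - 1, K, K))
    for t in range(T - 1):
        m = (
            alphas[t][:, None]
            + transitions
            + (potentials[t + 1] + betas[t + 1])[None, :]
            - log_z
        )
        pairwise[t] = np.exp(m)
    return log_z, unary, pairwise, unary[0], unary[-1]


def viterbi_decode(potentials, transitions, start=None, end=None) -> list[int]:
    """Most likely tag sequence; ties broken by the lowest tag index.

    The backtracking pointer at each step is ``argmax`` over predecessors,
    which selects the smallest index among exact ties, so the decoded path is
    deterministic for any potentials.
    """
    potentials, transitions, start, end = _check(potentials, transitions, start, end)
    T, K = potentials.shape
    delta = start + potentials[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + transitions
        back[t] = np.argmax(scores, axis=0)
        delta = potentials[t] + scores[back[t], np.arange(K)]
    last = int(np.argmax(delta + end))
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]
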