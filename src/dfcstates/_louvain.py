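"""Louvain community detection for signed, weighted, undirected graphs.

Modularity uses the asymmetric signed formulation: with W = W+ - W-,
v+/- the total positive/negative weight (over ordered pairs) and s+/- the
node strengths,

    Q = Q+ - (v- / (v+ + v-)) * Q-,
    Q+/- = (1/v+/-) * sum_ij (W+/-_ij - gamma * s_i s_j / v+/-) delta(c_i, c_j).

Positive weight inside modules is rewarded at full rate while negative
weight inside modules is penalized at a rate discounted by its share of the
total weight.  The resolution parameter gamma scales both null terms.
"""

from __future__ import annotations

import numpy as np

_MIN_GAIN = 1e-12


def signed_modularity(adj: np.ndarray, partition: np.ndarray,
                      gamma: float = 1.0) -> float:
    """Direct evaluation of the asymmetric signed modularity."""
    A = np.asarray(adj, dtype=float)
    part = np.asarray(partition)
    P = np.clip(A, 0.0, None)
    N = np.clip(-A, 0.0, None)
    delta = part[:, None] == part[None, :]

    def _q(M: np.ndarray) -> float:
        v = M.sum()
        if v <= 0:
            return 0.0
        s = M.sum(axis=1)
        return float(((M - gamma * np.outer(s, s) / v) * delta).sum() / v)

    vp, vn = P.sum(), N.sum()
    if vp + vn == 0:
        return 0.0
    return _q(P) - (vn / (vp + vn)) * _q(N)


def _local_move(P: np.ndarray, N: np.ndarray, gamma: float,
                rng: np.random.Generator) -> np.ndarray:
    n = P.shape[0]
    vp, vn = P.sum(), N.sum()
    lam = vn / (vp + vn) if (vp + vn) > 0 else 0.0
    sp = P.sum(axis=1)
    sn = N.sum(axis=1)
    comm = np.arange(n)
    comm_sp = sp.copy()
    comm_sn = sn.copy()

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            # take node i out of its community
            comm_sp[ci] -= sp[i]
            comm_sn[ci] -= sn[i]
            # weights from i to each community (self-weight excluded)
            wp = np.bincount(comm, weights=P[i], minlength=n)
            wn = np.bincount(comm, weights=N[i], minlength=n)
            wp[comm[i]] -= P[i, i]
            wn[comm[i]] -= N[i, i]
            cand = np.unique(comm[(P[i] > 0) | (N[i] > 0)])
            best_c, best_gain = ci, 0.0
            for c in cand:
                gain = 0.0
                if vp > 0:
                    gain += 2.0 * (wp[c] - gamma * sp[i] * comm_sp[c] / vp) / vp
                if vn > 0:
                    gain -= lam * 2.0 * (wn[c] - gamma * sn[i]
                                         * comm_sn[c] / vn) / vn
                if gain > best_gain + _MIN_GAIN:
                    best_gain, best_c = gain, c
            comm[i] = best_c
            comm_sp[best_c] += sp[i]
            comm_sn[best_c] += sn[i]
            if best_c != ci:
                improved = True
    # renumber communities consecutively
    _, labels = np.unique(comm, return_inverse=True)
    return labels


def _aggregate(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    ind = np.zeros((labels.size, k))
    ind[np.arange(labels.size), labels] = 1.0
    return ind.T @ M @ ind


def louvain_signed(adj: np.ndarray, gamma: float = 1.0,
                   seed: int | None = None):
    """Louvain partition of a signed weighted graph.

    Returns ``(partition, Q)`` where ``partition`` is an integer label per
    node (0-based, consecutive) and ``Q`` the signed modularity of that
    partition.  An all-zero graph yields a single module with Q = 0.
    Deterministic for a given ``seed`` (which only sets the node visiting
    order).
    """
    A = np.asarray(adj, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if not np.any(A):
        return np.zeros(n, dtype=int), 0.0
    rng = np.random.default_rng(seed)
    P = np.clip(A, 0.0, None)
    N = np.clip(-A, 0.0, None)
    labels = np.arange(n)
    while True:
        sub = _local_move(P, N, gamma, rng)
        if sub.max() + 1 == P.shape[0]:
            break  # no merge happened at this level
        labels = sub[labels]
        P = _aggregate(P, sub)
        N = _aggregate(N, sub)
        if P.shape[0] == 1:
            break
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(int), signed_modularity(A, labels, gamma)
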