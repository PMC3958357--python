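"""Newman modularity maximization with run-to-run variability.

The maximizer is a Louvain-style greedy agglomeration (local node moves
followed by community aggregation, repeated over levels) with a final
Kernighan-Lin-style refinement pass over the original nodes.  Node visit
order is randomized per run, so repeated runs can land in different local
maxima — the run-to-run variability that the stability-based threshold
selection in :mod:`gimmesub.subgroups` exploits.  The hot loop is
numba-compiled; graphs here are small (nodes = individuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["Partition", "modularity_q", "modularity_partition"]


@dataclass
class Partition:
    """Community assignment of individuals with its modularity Q."""

    labels: np.ndarray
    Q: float

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.labels)))

    def canonical(self) -> tuple[int, ...]:
        """Labels relabeled by order of first appearance (for comparison)."""
        mapping: dict[int, int] = {}
        out = []
        for lab in self.labels:
            if lab not in mapping:
                mapping[lab] = len(mapping)
            out.append(mapping[lab])
        return tuple(out)


def modularity_q(A: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of Newman's Q for a given partition.

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j).
    """
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    m2 = A.sum()
    if m2 == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += A[np.ix_(idx, idx)].sum() / m2 - (k[idx].sum() / m2) ** 2
    return float(q)


@njit(cache=True)
def _local_move(M, labels, m2, nc):  # pragma: no cover - numba
    n = M.shape[0]
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            k[i] += M[i, j]
    tot = np.zeros(nc)
    for i in range(n):
        tot[labels[i]] += k[i]
    any_move = False
    improved = True
    while improved:
        improved = False
        order = np.random.permutation(n)
        for oi in range(n):
            i = order[oi]
            ci = labels[i]
            w = np.zeros(nc)
            for j in range(n):
                if j != i and M[i, j] != 0.0:
                    w[labels[j]] += M[i, j]
            tot[ci] -= k[i]
            best_c = ci
            best_gain = w[ci] - k[i] * tot[ci] / m2
            for c in range(nc):
                if c != ci and w[c] > 0.0:
                    gain = w[c] - k[i] * tot[c] / m2
                    if gain > best_gain + 1e-12:
                        best_gain = gain
                        best_c = c
            tot[best_c] += k[i]
            if best_c != ci:
                labels[i] = best_c
                improved = True
                any_move = True
    return any_move


@njit(cache=True)
def _compress(labels):  # pragma: no cover - numba
    n = labels.shape[0]
    mapping = -np.ones(labels.max() + 1, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    nxt = 0
    for i in range(n):
        if mapping[labels[i]] < 0:
            mapping[labels[i]] = nxt
            nxt += 1
        out[i] = mapping[labels[i]]
    return out, nxt


@njit(cache=True)
def _aggregate(M, labels, nc):  # pragma: no cover - numba
    n = M.shape[0]
    out = np.zeros((nc, nc))
    for i in range(n):
        li = labels[i]
        for j in range(n):
            out[li, labels[j]] += M[i, j]
    return out


@njit(cache=True)
def _louvain(W, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = W.shape[0]
    m2 = 0.0
    for i in range(n):
        for j in range(n):
            m2 += W[i, j]
    node_labels = np.arange(n)
    M = W.copy()
    while True:
        size = M.shape[0]
        lab = np.arange(size)
        moved = _local_move(M, lab, m2, size)
        lab, nc = _compress(lab)
        for i in range(n):
            node_labels[i] = lab[node_labels[i]]
        if not moved or nc == size:
            break
        M = _aggregate(M, lab, nc)
    # Kernighan-Lin-style fine-tuning on the original nodes
    node_labels, nc = _compress(node_labels)
    _local_move(W, node_labels, m2, n)
    node_labels, _ = _compress(node_labels)
    return node_labels


def modularity_partition(A: np.ndarray, rng: np.random.Generator) -> Partition:
    """One randomized modularity-maximization run on a binary adjacency."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.sum() == 0:
        warnings.warn("edgeless graph: every node is its own community, Q = 0")
        return Partition(labels=np.arange(n), Q=0.0)
    seed = int(rng.integers(1, 2**31 - 1))
    labels = _louvain(A, seed)
    return Partition(labels=labels, Q=modularity_q(A, labels))
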