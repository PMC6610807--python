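"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
formula evaluation, eigendecomposition — and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All canonical pseudoknot-free pair sets on ``seq`` (1-based pairs)."""

    def gen(i: int, j: int):
        if i > j:
            yield ()
            return
        for rest in gen(i + 1, j):
            yield rest
        for l in range(i + min_hairpin + 1, j + 1):
            if (seq[i - 1], seq[l - 1]) in CANONICAL:
                for inner in gen(i + 1, l - 1):
                    for outer in gen(l + 1, j):
                        yield ((i, l),) + inner + outer

    return list(gen(1, len(seq)))


def boltzmann_pair_matrix(structures, energies, rt: float):
    """Exact p_ij by direct Boltzmann summation over an enumerated ensemble."""
    n = max((j for st in structures for _, j in st), default=0)
    weights = [math.exp(-e / rt) for e in energies]
    Z = sum(weights)
    p = {}
    for st, w in zip(structures, weights):
        for ij in st:
            p[ij] = p.get(ij, 0.0) + w / Z
    return p, Z


def crossing(a, b) -> bool:
    i, j = a
    k, l = b
    return (i < k < j < l) or (k < i < l < j)


def brute_max_noncrossing(pairs):
    """Max-cardinality non-crossing subset by exhaustive subset search."""
    plist = sorted(pairs)
    best_len, best = -1, ()
    for r in range(len(plist), -1, -1):
        hits = [
            c
            for c in itertools.combinations(plist, r)
            if not any(crossing(a, b) for a, b in itertools.combinations(c, 2))
        ]
        if hits:
            return r, min(hits)
    return best_len, best


def brute_max_entropy(N: int, parts: int) -> float:
    """Max of -sum (c/N) log2 (c/N) over integer partitions of N into <= parts."""

    def partitions(n: int, cap: int, maxparts: int):
        if n == 0:
            yield ()
            return
        if maxparts == 0:
            return
        for first in range(min(n, cap), 0, -1):
            for rest in partitions(n - first, first, maxparts - 1):
                yield (first,) + rest

    best = -1.0
    for counts in partitions(N, N, parts):
        h = -sum((c / N) * math.log2(c / N) for c in counts)
        best = max(best, h)
    return best


def condition_index_eig(X: np.ndarray) -> float:
    """Condition index via eigendecomposition of the scaled cross-product."""
    Xs = X / np.linalg.norm(X, axis=0)
    lam = np.linalg.eigvalsh(Xs.T @ Xs)
    return math.sqrt(lam[-1] / lam[0])


def brute_top_k_by_max_distance(U: np.ndarray, P: np.ndarray, k: int):
    """All-pairs distance computation and explicit top-k (index tie-break)."""
    d = []
    for i, u in enumerate(U):
        d.append((max(np.linalg.norm(u - p) for p in P), i))
    order = sorted(range(len(U)), key=lambda i: (-d[i][0], i))
    return sorted(order[:k])


def random_pair_set(rng: np.random.Generator, n_positions: int, n_pairs: int):
    """A random valid pair set (each index used once)."""
    n_pairs = min(n_pairs, n_positions // 2)
    idx = rng.permutation(np.arange(1, n_positions + 1))[: 2 * n_pairs]
    return {
        tuple(sorted((int(idx[2 * k]), int(idx[2 * k + 1]))))
        for k in range(n_pairs)
    }
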