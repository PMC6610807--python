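"""Sequence Segment Entropy (SSE).

SSE is the Shannon entropy (in bits) of the empirical distribution of the
``n + 1 - w`` overlapping length-``w`` segments (k-mers) of a sequence.  It is
a thermodynamics-free measure of sequence diversity: a low-complexity sequence
such as ``GAAA...AAC`` has a strongly peaked segment distribution and hence a
low SSE, while a diverse sequence approaches the closed-form maximum and a
normalized SSE near 1.

The maximum for length ``n`` and window ``w`` has a closed form.  With
``N = n + 1 - w`` segments over an alphabet of ``4^w`` possible words, the most
uniform attainable count vector is either all-distinct (``N <= 4^w``) or a
two-level profile where ``b = N mod 4^w`` words occur ``a + 1`` times and the
remaining ``4^w - b`` words occur ``a = floor(N / 4^w)`` times.

The normalized values for a range of window sizes feed the foldability model;
``select_window_range`` recomputes, on a user corpus, how many windows can be
added before the columns become collinear (condition index above 30, the
conventional collinearity alarm).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .structure_io import RnaSequence

__all__ = [
    "SegmentProfile",
    "SseValue",
    "segment_profile",
    "sse",
    "max_sse",
    "normalized_sse",
    "sse_value",
    "condition_index",
    "select_window_range",
    "DEFAULT_WINDOW_RANGE",
    "CONDITION_INDEX_THRESHOLD",
]

#: Shipped default window range (recomputable via :func:`select_window_range`).
DEFAULT_WINDOW_RANGE: tuple[int, int] = (3, 8)
#: Conventional collinearity alarm for the condition index.
CONDITION_INDEX_THRESHOLD: float = 30.0
#: Sentinel reported for numerically rank-deficient design matrices.
COLLINEAR_SENTINEL: float = 1e12


class InvalidWindowError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentProfile:
    """Occurrence counts of the overlapping length-``w`` segments of a sequence."""

    w: int
    counts: dict[str, int]
    total: int


@dataclass(frozen=True)
class SseValue:
    v_ent: float
    v_max: float
    rv_ent: float


def _check_window(n: int, w: int) -> None:
    if not (1 <= w <= n):
        raise InvalidWindowError(f"window {w} invalid for sequence length {n}")


def segment_profile(seq: RnaSequence | str, w: int) -> SegmentProfile:
    s = seq.residues if isinstance(seq, RnaSequence) else seq
    _check_window(len(s), w)
    total = len(s) + 1 - w
    counts = Counter(s[k : k + w] for k in range(total))
    return SegmentProfile(w=w, counts=dict(counts), total=total)


def sse(seq: RnaSequence | str, w: int) -> float:
    """Segment entropy in bits: ``-sum p log2 p`` over distinct segments."""
    profile = segment_profile(seq, w)
    total = profile.total
    return -sum(
        (c / total) * math.log2(c / total) for c in profile.counts.values()
    )


def max_sse(n: int, w: int) -> float:
    """Closed-form maximum segment entropy for length ``n``, window ``w``."""
    _check_window(n, w)
    N = n + 1 - w
    words = 4**w
    if N <= words:
        return math.log2(N)
    a, b = divmod(N, words)
    high = (a + 1) / N
    low = a / N
    v = -b * high * math.log2(high)
    if a > 0:  # 0 * log 0 := 0
        v -= (words - b) * low * math.log2(low)
    return v


def normalized_sse(seq: RnaSequence | str, w: int) -> float:
    """``sse / max_sse`` in [0, 1]; defined as 0 where the maximum is 0."""
    return sse_value(seq, w).rv_ent


def sse_value(seq: RnaSequence | str, w: int) -> SseValue:
    s = seq.residues if isinstance(seq, RnaSequence) else seq
    v = sse(s, w)
    vmax = max_sse(len(s), w)
    rv = v / vmax if vmax > 0 else 0.0
    return SseValue(v_ent=v, v_max=vmax, rv_ent=rv)


def condition_index(feature_matrix: np.ndarray) -> tuple[float, bool]:
    """Largest condition index of a design matrix, with a collinearity flag.

    Columns are scaled to unit Euclidean length (no centering, the
    Belsley-style convention for collinearity diagnostics); the index is the
    ratio of the largest to the smallest singular value of the scaled matrix.
    Returns ``(index, collinear)`` where ``collinear`` is set when the matrix
    is rank-deficient to machine precision (index reported as a large
    sentinel) or the index exceeds the conventional threshold of 30.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many rows as columns")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("constant-zero column has no scaling")
    sv = np.linalg.svd(X / norms, compute_uv=False)
    eps_rank = sv[0] * max(X.shape) * np.finfo(float).eps
    if sv[-1] <= eps_rank:
        return COLLINEAR_SENTINEL, True
    idx = float(sv[0] / sv[-1])
    return idx, idx > CONDITION_INDEX_THRESHOLD


def select_window_range(
    seqs: list[RnaSequence | str],
    w_min: int = 3,
    w_max_cap: int = 12,
    threshold: float = CONDITION_INDEX_THRESHOLD,
) -> tuple[int, int]:
    """Grow the window set {w_min..k} until the SSE columns turn collinear.

    For each candidate upper window ``k`` the normalized-SSE columns for
    windows ``w_min..k`` are assembled over the corpus; the first ``k`` whose
    inclusion pushes the largest condition index above ``threshold`` is
    excluded and ``(w_min, k - 1)`` returned.  With the shipped defaults and a
    typical corpus this reproduces the stock 3..8 preset.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to assess collinearity")
    texts = [s.residues if isinstance(s, RnaSequence) else s for s in seqs]
    w_max_cap = min(w_max_cap, min(len(t) for t in texts))
    best = w_min
    for k in range(w_min + 1, w_max_cap + 1):
        ncols = k - w_min + 1
        if len(texts) < ncols:
            raise ValueError(
                f"corpus of {len(texts)} sequences cannot support {ncols} SSE columns; "
                "add sequences or lower w_max_cap"
            )
        X = np.array(
            [[normalized_sse(t, w) for w in range(w_min, k + 1)] for t in texts]
        )
        idx, _ = condition_index(X)
        if idx > threshold:
            break
        best = k
    return (w_min, best)
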