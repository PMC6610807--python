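"""Pseudoknot decomposition for energy scoring.

A pseudoknotted structure is treated as the result of two-step folding: a
pseudoknot-free *base substructure* (the maximum-cardinality non-crossing
subset of pairs, the skeleton) forms first, then the removed *knot* pairs
bridge loop bases to bases outside.  Each knot component is excised as the
minimal contiguous subsequence spanning its pairs and re-indexed into a
pseudoknot-free fold of its own; closing that excised segment creates one or
more artificial hairpin loops whose penalty is subtracted again when the
knot's free-energy contribution is reported, since those hairpins are
artifacts of the excision, not of the molecule.

Three free-energy features come out of the decomposition:

* ``V_bfe``  — free energy of the base substructure on the full sequence;
* ``V_bmfe`` — minimum free energy the sequence can reach without pseudoknots;
* ``V_kfe``  — summed knot-segment energies after hairpin correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy import EnergyModel, eval_energy, mfe
from .structure_io import (
    RnaSequence,
    SecondaryStructure,
    StructurePair,
    is_pseudoknotted,
)

__all__ = [
    "KnotSegment",
    "Decomposition",
    "max_noncrossing_subset",
    "decompose",
    "knot_energy_features",
]


@dataclass(frozen=True)
class KnotSegment:
    """One excised knot component, re-indexed onto its minimal spanning window."""

    span: tuple[int, int]  # 1-based inclusive window on the original sequence
    pairs: tuple[tuple[int, int], ...]  # original coordinates
    local: StructurePair  # re-indexed fold on the excised subsequence
    #: spans (local coordinates) of the artificial hairpin-closing pairs
    artificial_hairpins: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Decomposition:
    base: StructurePair
    knot_pairs: tuple[tuple[int, int], ...]
    segments: tuple[KnotSegment, ...]


def max_noncrossing_subset(
    pairs: frozenset[tuple[int, int]] | set[tuple[int, int]] | tuple[tuple[int, int], ...],
) -> tuple[tuple[int, int], ...]:
    """Maximum-cardinality mutually non-crossing subset of a pair set.

    Interval dynamic programming over sequence positions restricted to the
    given pairs.  Ties are broken toward the subset whose sorted pair list is
    lexicographically smallest (greedy leftmost inclusion with the nearest
    partner, which is lexicographically optimal because every pair chosen at
    position ``i`` precedes, in sorted order, any pair starting later).
    """
    plist = sorted(pairs)
    if not plist:
        return ()
    by_start: dict[int, list[int]] = {}
    for i, j in plist:
        by_start.setdefault(i, []).append(j)
    lo = plist[0][0]
    hi = max(j for _, j in plist)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i >= j:
            return 0
        score = best(i + 1, j)
        for l in by_start.get(i, ()):
            if l <= j:
                score = max(score, 1 + best(i + 1, l - 1) + best(l + 1, j))
        return score

    out: list[tuple[int, int]] = []
    stack = [(lo, hi)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = best(i, j)
            chosen = None
            for l in by_start.get(i, ()):  # ascending partner
                if l <= j and 1 + best(i + 1, l - 1) + best(l + 1, j) == target:
                    chosen = l
                    break
            if chosen is None:
                i += 1
                continue
            out.append((i, chosen))
            stack.append((chosen + 1, j))
            i, j = i + 1, chosen - 1
    best.cache_clear()
    return tuple(sorted(out))


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _knot_components(
    knot: tuple[tuple[int, int], ...]
) -> list[tuple[tuple[int, int], ...]]:
    """Group knot pairs into components by span overlap (nested or crossing)."""
    parent = list(range(len(knot)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(knot)):
        for b in range(a + 1, len(knot)):
            if _spans_overlap(knot[a], knot[b]):
                parent[find(a)] = find(b)
    groups: dict[int, list[tuple[int, int]]] = {}
    for idx, p in enumerate(knot):
        groups.setdefault(find(idx), []).append(p)
    return [tuple(sorted(g)) for g in sorted(groups.values())]


def _innermost_hairpin_spans(
    structure: SecondaryStructure,
) -> tuple[tuple[int, int], ...]:
    """Spans of pairs that close hairpin loops (no pair nested inside them)."""
    spans = []
    for i, j in structure.pairs:
        if not any(i < k and l < j for k, l in structure.pairs):
            spans.append((i, j))
    return tuple(spans)


def _excise_segment(
    pair: StructurePair, component: tuple[tuple[int, int], ...]
) -> KnotSegment:
    lo = min(i for i, _ in component)
    hi = max(j for _, j in component)
    sub = pair.sequence.residues[lo - 1 : hi]
    local_pairs = tuple((i - lo + 1, j - lo + 1) for i, j in component)
    structure = SecondaryStructure(n=hi - lo + 1, pairs=local_pairs)
    if is_pseudoknotted(structure):
        # components of mutually crossing knot pairs: keep the dominant
        # non-crossing subset so the segment itself is scoreable
        structure = SecondaryStructure(
            n=hi - lo + 1, pairs=max_noncrossing_subset(local_pairs)
        )
    local = StructurePair(
        RnaSequence(sub, id=f"knot-{lo}-{hi}"),
        structure,
        validate_pairs=pair.validate_pairs,
    )
    return KnotSegment(
        span=(lo, hi),
        pairs=component,
        local=local,
        artificial_hairpins=_innermost_hairpin_spans(structure),
    )


def decompose(pair: StructurePair) -> Decomposition:
    """Split a structure into a non-crossing base substructure and knot segments.

    Pseudoknot-free input yields the trivial decomposition (the structure
    itself, no knot segments), which makes ``decompose`` idempotent.
    """
    all_pairs = pair.structure.pairs
    base_pairs = max_noncrossing_subset(all_pairs)
    knot = tuple(sorted(set(all_pairs) - set(base_pairs)))
    base = StructurePair(
        pair.sequence,
        SecondaryStructure(n=pair.structure.n, pairs=base_pairs),
        validate_pairs=pair.validate_pairs,
    )
    segments = tuple(_excise_segment(pair, comp) for comp in _knot_components(knot))
    return Decomposition(base=base, knot_pairs=knot, segments=segments)


def knot_energy_features(
    pair: StructurePair, model: EnergyModel, decomposition: Decomposition | None = None
) -> tuple[float, float, float]:
    """``(V_bfe, V_bmfe, V_kfe)`` in kcal/mol for a (possibly knotted) structure.

    ``V_kfe`` sums, over knot segments, the segment fold energy minus the
    hairpin-loop penalties created by closing the excised segment.
    """
    d = decomposition if decomposition is not None else decompose(pair)
    v_bfe = eval_energy(d.base, model)
    v_bmfe, _ = mfe(pair.sequence, model)
    v_kfe = 0.0
    for seg in d.segments:
        e = eval_energy(seg.local, model)
        for span in seg.artificial_hairpins:
            e -= model.hairpin(span[1] - span[0] - 1)
        v_kfe += e
    return v_bfe, v_bmfe, v_kfe
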