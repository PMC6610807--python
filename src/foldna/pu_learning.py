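"""Positive-Unlabeled training-set construction.

Confirmed (sequence, structure) pairs form the positive set P.  Because
failed RNAs are essentially never published, the unlabeled set U is built
computationally: each positive structure serves as a seed, and candidate
sequences compatible with it are generated under three constraints —
permitted base pairings (Watson-Crick + wobble), a cap on identical-base run
length, and a GC-fraction band.  Candidates come from plain constrained
sampling and from a budget-bounded adaptive-walk inverse folder that mutates
a sampled start toward sequences whose MFE structure is close to the seed.

"Reliable" negatives are then mined from U by distance: after joint min-max
normalization of P and U features, each unlabeled row is scored by its
maximum Euclidean distance to the positive rows, and the top-k become the
negative class for the downstream logistic model.  (A min-distance variant is
available, since "furthest from the positives" can also be read as ranking
by nearest-positive distance; the max form is the default.)

All randomness flows from one master seed through named substreams, and every
generated record carries its provenance (seed structure id, generator name,
substream seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, mfe
from .structure_io import RnaSequence, SecondaryStructure, StructurePair

__all__ = [
    "GenerationConstraints",
    "UnlabeledRecord",
    "InfeasibleConstraintsError",
    "sample_sequence",
    "local_inverse_fold",
    "build_unlabeled",
    "minmax_normalize",
    "distance_to_positives",
    "select_reliable_negatives",
]

_PAIR_CHOICES = ("AU", "UA", "GC", "CG", "GU", "UG")
_BASES = "ACGU"


class InfeasibleConstraintsError(RuntimeError):
    """Sequence constraints could not be satisfied within the attempt budget."""


@dataclass(frozen=True)
class GenerationConstraints:
    """Sequence-generation constraints for unlabeled candidates.

    ``repetition_limit`` is the longest permitted run of identical bases:
    runs strictly longer than the limit are barred.
    """

    repetition_limit: int = 4
    gc_min: float = 0.2
    gc_max: float = 0.8
    pairing_rule: tuple[str, ...] = _PAIR_CHOICES

    def __post_init__(self) -> None:
        if self.repetition_limit < 1:
            raise ValueError("repetition_limit must be >= 1")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")


@dataclass(frozen=True)
class UnlabeledRecord:
    pair: StructurePair
    seed_structure_id: str
    generator: str
    substream_seed: int


def _substream(master_seed: int, *key: int | str) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    ints = [master_seed] + [
        k if isinstance(k, int) else int.from_bytes(k.encode()[:8], "little")
        for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _max_run(s: list[str]) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _gc_fraction(s: list[str]) -> float:
    return sum(c in "GC" for c in s) / len(s)


def sample_sequence(
    structure: SecondaryStructure,
    constraints: GenerationConstraints = GenerationConstraints(),
    rng_seed: int | np.random.Generator = 0,
    max_attempts: int = 2000,
) -> RnaSequence:
    """Draw a random sequence compatible with ``structure`` and the constraints.

    Paired positions receive a permitted pair, unpaired positions a uniform
    base; draws violating the run-length or GC band are repaired by re-drawing
    offending positions, with full restarts until the attempt budget runs out.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = structure.n
    pairs = structure.pairs
    unpaired = [i for i in range(1, n + 1) if i not in structure.partner()]

    for _ in range(max_attempts):
        s = [""] * n
        for i, j in pairs:
            choice = constraints.pairing_rule[rng.integers(len(constraints.pairing_rule))]
            s[i - 1], s[j - 1] = choice[0], choice[1]
        for i in unpaired:
            s[i - 1] = _BASES[rng.integers(4)]
        # repair loop: re-draw positions violating run length, nudge GC
        for _ in range(4 * n):
            ok_run = _max_run(s) <= constraints.repetition_limit
            gc = _gc_fraction(s)
            ok_gc = constraints.gc_min <= gc <= constraints.gc_max
            if ok_run and ok_gc:
                return RnaSequence("".join(s))
            if not ok_run:
                # find a violating run and re-draw one position inside it
                run_start, run = 0, 1
                for k in range(1, n):
                    run = run + 1 if s[k] == s[k - 1] else 1
                    if run > constraints.repetition_limit:
                        run_start = k
                        break
                pos = run_start + 1
            else:
                want_gc = gc < constraints.gc_min
                cands = [
                    k + 1
                    for k in range(n)
                    if (s[k] in "AU") == want_gc
                ]
                if not cands:
                    break
                pos = int(cands[rng.integers(len(cands))])
            partner = structure.partner().get(pos)
            if partner is None:
                s[pos - 1] = _BASES[rng.integers(4)]
            else:
                i, j = (pos, partner) if pos < partner else (partner, pos)
                choice = constraints.pairing_rule[
                    rng.integers(len(constraints.pairing_rule))
                ]
                s[i - 1], s[j - 1] = choice[0], choice[1]
    raise InfeasibleConstraintsError(
        "could not satisfy run-length and GC constraints within the budget"
    )


def _bp_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    return len(a.pair_set ^ b.pair_set)


def local_inverse_fold(
    structure: SecondaryStructure,
    model: EnergyModel,
    constraints: GenerationConstraints = GenerationConstraints(),
    rng_seed: int | np.random.Generator = 0,
    max_steps: int = 50,
    start: RnaSequence | None = None,
) -> RnaSequence:
    """Adaptive-walk inverse folding toward the target structure.

    Starting from a constrained sample (or ``start`` when given),
    single-position (unpaired) or pair-consistent (paired) mutations are
    proposed; a proposal is accepted when the base-pair distance between its
    MFE structure and the target does not increase.  Returns the best
    sequence seen within the step budget; a start whose MFE structure already
    is the target comes back unchanged.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    current = start if start is not None else sample_sequence(structure, constraints, rng)
    partner = structure.partner()
    _, folded = mfe(current, model)
    dist = _bp_distance(folded, structure)
    best_seq, best_dist = current, dist
    for _ in range(max_steps):
        if best_dist == 0:
            break
        s = list(current.residues)
        pos = int(rng.integers(1, structure.n + 1))
        mate = partner.get(pos)
        if mate is None:
            s[pos - 1] = _BASES[rng.integers(4)]
        else:
            i, j = (pos, mate) if pos < mate else (mate, pos)
            choice = constraints.pairing_rule[rng.integers(len(constraints.pairing_rule))]
            s[i - 1], s[j - 1] = choice[0], choice[1]
        if _max_run(s) > constraints.repetition_limit:
            continue
        gc = _gc_fraction(s)
        if not (constraints.gc_min <= gc <= constraints.gc_max):
            continue
        candidate = RnaSequence("".join(s))
        _, folded = mfe(candidate, model)
        cand_dist = _bp_distance(folded, structure)
        if cand_dist <= dist:
            current, dist = candidate, cand_dist
            if cand_dist < best_dist:
                best_seq, best_dist = candidate, cand_dist
    return best_seq


def build_unlabeled(
    seed_structures: list[tuple[str, SecondaryStructure]],
    model: EnergyModel,
    per_structure: int = 100,
    constraints: GenerationConstraints = GenerationConstraints(),
    rng_seed: int = 0,
    inverse_fold_fraction: float = 0.2,
    inverse_fold_steps: int = 30,
) -> list[UnlabeledRecord]:
    """Generate ``per_structure`` candidate pairs for every seed structure.

    A configurable fraction of candidates per seed comes from the adaptive
    walk, the rest from plain constrained sampling; each record keeps its
    seed id, generator name, and substream seed so the set is reproducible
    byte-for-byte from the master seed.
    """
    records: list[UnlabeledRecord] = []
    for sidx, (sid, structure) in enumerate(seed_structures):
        n_walk = int(round(per_structure * inverse_fold_fraction))
        for k in range(per_structure):
            rng = _substream(rng_seed, "unlabeled", sidx, k)
            sub_seed = int(rng.integers(2**31))
            gen_rng = np.random.default_rng(sub_seed)
            if k < n_walk:
                seq = local_inverse_fold(
                    structure, model, constraints, gen_rng, max_steps=inverse_fold_steps
                )
                generator = "adaptive-walk"
            else:
                seq = sample_sequence(structure, constraints, gen_rng)
                generator = "constrained-sample"
            records.append(
                UnlabeledRecord(
                    pair=StructurePair(seq, structure),
                    seed_structure_id=sid,
                    generator=generator,
                    substream_seed=sub_seed,
                )
            )
    return records


def minmax_normalize(
    positives: np.ndarray, unlabeled: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Joint per-feature min-max scaling of the P and U blocks.

    The min/max are taken over the union so both blocks land in [0, 1];
    constant features map to 0.  The returned record is stored with trained
    models and re-applied verbatim at prediction time.
    """
    P = np.asarray(positives, dtype=float)
    U = np.asarray(unlabeled, dtype=float)
    if P.shape[1] != U.shape[1]:
        raise ValueError("P and U feature columns differ")
    both = np.vstack([P, U])
    lo = both.min(axis=0)
    hi = both.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)

    def scale(X: np.ndarray) -> np.ndarray:
        out = (X - lo) / safe
        out[:, span == 0] = 0.0
        return out

    return scale(P), scale(U), {"min": lo, "max": hi}


def distance_to_positives(u: np.ndarray, P: np.ndarray, mode: str = "max") -> float:
    """Distance from one unlabeled row to the positive set.

    ``mode='max'`` (default) is the published form: the maximum Euclidean
    distance over positive rows.  ``mode='min'`` ranks by nearest positive
    instead.
    """
    P = np.asarray(P, dtype=float)
    if P.size == 0:
        raise ValueError("positive set is empty")
    d = np.sqrt(((P - np.asarray(u, dtype=float)) ** 2).sum(axis=1))
    return float(d.max() if mode == "max" else d.min())


def select_reliable_negatives(
    U: np.ndarray, P: np.ndarray, k: int, mode: str = "max"
) -> list[int]:
    """Indices of the k unlabeled rows furthest from the positives.

    Ties are broken by row index (ascending) so selection is deterministic.
    """
    U = np.asarray(U, dtype=float)
    if k > len(U):
        raise ValueError(f"k={k} exceeds |U|={len(U)}")
    if k == 0:
        return []
    dists = np.array([distance_to_positives(u, P, mode=mode) for u in U])
    order = sorted(range(len(U)), key=lambda i: (-dists[i], i))
    return sorted(order[:k])
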