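"""Synthetic structure-sequence corpora for testing every pipeline stage.

The generator draws nested stem-loop secondary structures (hairpins of at
least 3 unpaired bases, optional interior spacers) and, with a configurable
probability, injects one H-type pseudoknot: a stem pairing hairpin-loop bases
with bases downstream of the enclosing helix.  Sequences are then sampled
against each structure under the same constraints used for unlabeled-set
generation, so every record is a valid, canonically paired
:class:`~foldna.structure_io.StructurePair`.

Every corpus carries a manifest (seeds, constraints, per-record provenance):
fixtures are reproducible byte-for-byte from their spec and never exist
without their seed record.  The generator emulates sizes and pairing
geometry, not the family or length distributions of curated databases.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .pu_learning import GenerationConstraints, sample_sequence
from .structure_io import SecondaryStructure, StructurePair

__all__ = ["FixtureSpec", "random_structure", "make_corpus"]


@dataclass(frozen=True)
class FixtureSpec:
    n_records: int = 50
    length_min: int = 24
    length_max: int = 40
    stems: int = 2
    knot_probability: float = 0.0
    gc_min: float = 0.3
    gc_max: float = 0.7
    repetition_limit: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0 or self.stems < 1:
            raise ValueError("counts must be non-negative, stems >= 1")
        if not 0.0 <= self.knot_probability <= 1.0:
            raise ValueError("knot_probability must be in [0, 1]")
        if self.length_min < 8:
            raise ValueError("length_min must be >= 8")


def _nested_stems(
    length: int, stems: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Place side-by-side stem-loops on [1, length], hairpin loops >= 3 nt."""
    pairs: list[tuple[int, int]] = []
    cursor = 1
    remaining = stems
    while remaining > 0 and cursor + 7 <= length:
        budget = (length - cursor + 1) // remaining
        width = int(rng.integers(8, max(9, budget + 1)))
        width = min(width, length - cursor + 1)
        stem_len = max(2, (width - 4) // 2)
        stem_len = int(min(stem_len, rng.integers(2, 6)))
        loop = width - 2 * stem_len
        if loop < 3:
            stem_len = (width - 3) // 2
            loop = width - 2 * stem_len
        for k in range(stem_len):
            pairs.append((cursor + k, cursor + width - 1 - k))
        cursor += width + int(rng.integers(0, 3))
        remaining -= 1
    return pairs


def random_structure(
    length: int,
    stems: int = 2,
    knot_probability: float = 0.0,
    rng: np.random.Generator | int = 0,
    max_tries: int = 50,
) -> SecondaryStructure:
    """A random nested stem-loop structure, optionally with one H-type knot."""
    if length < 8:
        raise ValueError("length must be >= 8")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for _ in range(max_tries):
        pairs = _nested_stems(length, stems, rng)
        if not pairs:
            continue
        want_knot = rng.random() < knot_probability
        if want_knot:
            knot = _inject_h_knot(pairs, length, rng)
            if knot is None:
                continue
            pairs = pairs + knot
        return SecondaryStructure(n=length, pairs=tuple(sorted(pairs)))
    raise RuntimeError(f"could not draw a feasible structure of length {length}")


def _inject_h_knot(
    pairs: list[tuple[int, int]], length: int, rng: np.random.Generator
) -> list[tuple[int, int]] | None:
    """Pair hairpin-loop bases of an existing stem with free downstream bases."""
    used = {k for p in pairs for k in p}
    # innermost pair of each stem = hairpin
    hairpins = [
        (i, j) for (i, j) in pairs if not any(i < a and b < j for a, b in pairs)
    ]
    rng.shuffle(hairpins)
    for i, j in hairpins:
        loop = [k for k in range(i + 1, j) if k not in used]
        tail = [k for k in range(j + 1, length + 1) if k not in used]
        # need a 2-stack: two loop bases pairing two tail bases, crossing (j, ...)
        if len(loop) >= 2 and len(tail) >= 2:
            a, b = loop[0], loop[1]
            # partners chosen adjacent and descending so the knot stem nests
            d, c = tail[1], tail[0]
            if b < a:
                a, b = b, a
            knot = [(a, d), (b, c)]
            if all(x not in used for pr in knot for x in pr):
                return knot
    return None


def make_corpus(
    spec: FixtureSpec,
) -> tuple[list[StructurePair], dict]:
    """Generate a corpus of valid structure-sequence pairs plus its manifest."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    constraints = GenerationConstraints(
        repetition_limit=spec.repetition_limit,
        gc_min=spec.gc_min,
        gc_max=spec.gc_max,
    )
    records: list[StructurePair] = []
    manifest: dict = {"spec": asdict(spec), "records": []}
    for k in range(spec.n_records):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        struct_seed = int(rng.integers(2**31))
        seq_seed = int(rng.integers(2**31))
        structure = random_structure(
            length,
            stems=spec.stems,
            knot_probability=spec.knot_probability,
            rng=np.random.default_rng(struct_seed),
        )
        seq = sample_sequence(
            structure, constraints, np.random.default_rng(seq_seed)
        )
        records.append(StructurePair(seq, structure))
        manifest["records"].append(
            {
                "index": k,
                "length": length,
                "structure_seed": struct_seed,
                "sequence_seed": seq_seed,
                "n_pairs": len(structure.pairs),
            }
        )
    return records, manifest
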