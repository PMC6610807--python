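"""Sequence and secondary-structure data model with FASTA / dot-bracket / BPSEQ I/O.

Coordinates are 1-based inclusive throughout, matching the BPSEQ convention.
Pseudoknots are represented by assigning crossing base pairs to separate
bracket "pages": ``()``, ``[]``, ``{}``, ``<>`` in that order.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructurePair",
    "StructureFormatError",
    "parse_dotbracket",
    "to_dotbracket",
    "read_bpseq",
    "write_bpseq",
    "read_fasta",
    "read_dotbracket_records",
    "is_pseudoknotted",
    "CANONICAL_PAIRS",
]

ALPHABET = frozenset("ACGU")
#: Watson-Crick plus wobble combinations accepted in validated structures.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_OPEN = "([{<"
_CLOSE = ")]}>"
_PAGE_OF_OPEN = {c: k for k, c in enumerate(_OPEN)}
_PAGE_OF_CLOSE = {c: k for k, c in enumerate(_CLOSE)}


class StructureFormatError(ValueError):
    """Raised for malformed sequence or structure input."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, C, G, U}."""

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise StructureFormatError("empty sequence")
        for pos, c in enumerate(self.residues, start=1):
            if c not in ALPHABET:
                raise StructureFormatError(
                    f"invalid residue {c!r} at position {pos} in sequence {self.id!r}"
                )

    @property
    def n(self) -> int:
        return len(self.residues)

    @classmethod
    def from_text(cls, text: str, id: str = "") -> "RnaSequence":
        """Normalize raw text: uppercase, transliterate T->U, reject anything else."""
        up = text.strip().upper()
        for pos, c in enumerate(up, start=1):
            if c not in "ACGUT":
                raise StructureFormatError(
                    f"invalid character {c!r} at position {pos} in sequence {id!r}"
                )
        return cls(up.replace("T", "U"), id=id)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs on ``n`` positions; crossing pairs allowed across layers.

    ``pairs`` is stored as a sorted tuple of 1-based ``(i, j)`` with ``i < j``
    and each index used at most once.
    """

    n: int
    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise StructureFormatError("structure length must be >= 1")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise StructureFormatError(f"pair ({i},{j}) out of range for n={self.n}")
            if i in seen or j in seen:
                raise StructureFormatError(f"index reused by pair ({i},{j})")
            seen.update((i, j))
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)

    def partner(self) -> dict[int, int]:
        """Symmetric index -> partner map (absent keys are unpaired)."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def paired_fraction(self) -> float:
        return 2.0 * len(self.pairs) / self.n


@dataclass(frozen=True)
class StructurePair:
    """A sequence together with a secondary structure of matching length."""

    sequence: RnaSequence
    structure: SecondaryStructure
    #: when False, non-canonical pairings (e.g. A-G) are admitted.
    validate_pairs: bool = True

    def __post_init__(self) -> None:
        if self.sequence.n != self.structure.n:
            raise StructureFormatError(
                f"sequence length {self.sequence.n} != structure length {self.structure.n}"
            )
        if self.validate_pairs:
            s = self.sequence.residues
            for i, j in self.structure.pairs:
                if (s[i - 1], s[j - 1]) not in CANONICAL_PAIRS:
                    raise StructureFormatError(
                        f"non-canonical pair {s[i-1]}{s[j-1]} at ({i},{j}); "
                        "pass validate_pairs=False to admit it"
                    )


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string, one stack per bracket family.

    Crossing pairs are legal only across families; within a family the usual
    stack matching applies.
    """
    stacks: list[list[int]] = [[] for _ in _OPEN]
    pairs: list[tuple[int, int]] = []
    for pos, c in enumerate(text, start=1):
        if c == ".":
            continue
        if c in _PAGE_OF_OPEN:
            stacks[_PAGE_OF_OPEN[c]].append(pos)
        elif c in _PAGE_OF_CLOSE:
            stack = stacks[_PAGE_OF_CLOSE[c]]
            if not stack:
                raise StructureFormatError(
                    f"unmatched {c!r} at position {pos}"
                )
            pairs.append((stack.pop(), pos))
        else:
            raise StructureFormatError(f"invalid structure character {c!r} at position {pos}")
    for stack in stacks:
        if stack:
            raise StructureFormatError(f"unclosed bracket at position {stack[0]}")
    if not text:
        raise StructureFormatError("empty structure string")
    return SecondaryStructure(n=len(text), pairs=tuple(pairs))


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    i, j = a
    k, l = b
    return (i < k < j < l) or (k < i < l < j)


def _assign_layers(pairs: tuple[tuple[int, int], ...]) -> dict[tuple[int, int], int]:
    """Greedy first-fit page assignment so pairs within one page never cross."""
    layers: dict[tuple[int, int], int] = {}
    placed: list[list[tuple[int, int]]] = []
    for p in sorted(pairs):
        for page, members in enumerate(placed):
            if not any(_crosses(p, q) for q in members):
                members.append(p)
                layers[p] = page
                break
        else:
            placed.append([p])
            layers[p] = len(placed) - 1
    return layers


def to_dotbracket(structure: SecondaryStructure) -> str:
    """Render to dot-bracket; up to four mutually crossing pages are supported."""
    layers = _assign_layers(structure.pairs)
    if layers and max(layers.values()) >= len(_OPEN):
        raise StructureFormatError(
            "structure needs more than 4 mutually crossing layers; cannot render"
        )
    out = ["."] * structure.n
    for (i, j), page in layers.items():
        out[i - 1] = _OPEN[page]
        out[j - 1] = _CLOSE[page]
    return "".join(out)


def is_pseudoknotted(structure: SecondaryStructure) -> bool:
    """True iff some two pairs (i,j), (k,l) interleave as i < k < j < l."""
    pairs = structure.pairs
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if _crosses(pairs[a], pairs[b]):
                return True
    return False


def _open_stream(source, mode: str = "rt"):
    """Accept a path or an open text/binary stream; transparently gunzip paths."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        path = str(source)
        if path.endswith(".gz"):
            return gzip.open(path, mode), True
        return open(path, mode), True
    if isinstance(source, io.TextIOBase):
        return source, False
    # binary stream: sniff gzip magic
    if hasattr(source, "peek"):
        head = source.peek(2)[:2]
        if head == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.GzipFile(fileobj=source)), False
    return io.TextIOWrapper(source), False


def read_bpseq(source) -> StructurePair:
    """Read a BPSEQ record: lines of ``index base partner`` with partner 0 = unpaired."""
    stream, owned = _open_stream(source)
    try:
        bases: dict[int, str] = {}
        partners: dict[int, int] = {}
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise StructureFormatError(f"malformed BPSEQ line: {line!r}")
            idx, base, partner = int(fields[0]), fields[1], int(fields[2])
            if idx in bases:
                raise StructureFormatError(f"duplicate BPSEQ index {idx}")
            if partner == idx:
                raise StructureFormatError(f"self-pairing at BPSEQ index {idx}")
            bases[idx] = base
            partners[idx] = partner
        if not bases:
            raise StructureFormatError("empty BPSEQ input")
        n = max(bases)
        if sorted(bases) != list(range(1, n + 1)):
            raise StructureFormatError("BPSEQ indices have gaps")
        pairs = []
        for i in range(1, n + 1):
            j = partners[i]
            if j == 0:
                continue
            if not (1 <= j <= n) or partners.get(j) != i:
                raise StructureFormatError(
                    f"asymmetric partner claim: {i} -> {j} not reciprocated"
                )
            if i < j:
                pairs.append((i, j))
        seq = RnaSequence.from_text("".join(bases[i] for i in range(1, n + 1)))
        return StructurePair(seq, SecondaryStructure(n=n, pairs=tuple(pairs)))
    finally:
        if owned:
            stream.close()


def write_bpseq(pair: StructurePair, stream) -> None:
    partner = pair.structure.partner()
    for i, base in enumerate(pair.sequence.residues, start=1):
        stream.write(f"{i} {base} {partner.get(i, 0)}\n")


def read_fasta(source) -> list[RnaSequence]:
    """Read FASTA records as validated RNA sequences (T transliterated to U)."""
    from Bio import SeqIO

    stream, owned = _open_stream(source)
    try:
        records = [
            RnaSequence.from_text(str(rec.seq), id=rec.id)
            for rec in SeqIO.parse(stream, "fasta")
        ]
    finally:
        if owned:
            stream.close()
    if not records:
        raise StructureFormatError("no FASTA records found")
    return records


def read_dotbracket_records(source) -> list[StructurePair]:
    """Read Vienna-style records: ``>id`` line, sequence line, structure line."""
    stream, owned = _open_stream(source)
    try:
        lines = [ln.strip() for ln in stream if ln.strip()]
    finally:
        if owned:
            stream.close()
    out: list[StructurePair] = []
    k = 0
    while k < len(lines):
        if not lines[k].startswith(">"):
            raise StructureFormatError(f"expected '>' header, got {lines[k]!r}")
        if k + 2 >= len(lines):
            raise StructureFormatError(f"truncated record {lines[k]!r}")
        seq = RnaSequence.from_text(lines[k + 1], id=lines[k][1:].split()[0])
        structure = parse_dotbracket(lines[k + 2])
        out.append(StructurePair(seq, structure))
        k += 3
    if not out:
        raise StructureFormatError("no dot-bracket records found")
    return out
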