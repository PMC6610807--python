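"""Feature vectors for foldability modelling.

Two families of presets exist, one per structure class:

* pseudoknot-free: GC content, base-pair percentage, normalized segment
  entropies for windows 3..8, normalized free energy ``|V_fe - V_mfe| /
  |V_mfe|``, ensemble diversity and expected accuracy from the base-pair
  probability matrix (11 features);
* pseudoknotted: the same sequence/structure features plus the decomposition
  energies — base-substructure normalized free energy ``|V_bfe - V_bmfe| /
  |V_bmfe|``, knotted-substructure normalized free energy ``|V_bfe - V_kfe| /
  |V_bfe|`` — and the knot base-pair percentage (11 features).

The reduced "best" presets encode the published outcome of an exhaustive
feature-combination search: 5 features for pseudoknot-free inputs and 3 for
pseudoknotted ones.  (The source's prose labels the third pseudoknot feature
with the knotted-substructure symbol while describing the base-substructure
quantity; the base-substructure formula is used here.)

Feature order is frozen per preset and embedded in model files so training
and prediction cannot silently misalign.  Ratios with denominators below
``1e-9`` in magnitude are reported as 0 and flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy import (
    BasePairProbabilities,
    EnergyModel,
    eval_energy,
    mfe,
    pair_probabilities,
)
from .pseudoknot import Decomposition, decompose, knot_energy_features
from .sse import normalized_sse
from .structure_io import (
    RnaSequence,
    SecondaryStructure,
    StructurePair,
    is_pseudoknotted,
)

__all__ = [
    "FeatureVector",
    "PRESETS",
    "gc_content",
    "bp_percentage",
    "rv_fe",
    "ensemble_diversity",
    "expected_accuracy",
    "per_kbp",
    "featurize",
]

_SSE_NAMES = tuple(f"RV_ent_{w}" for w in range(3, 9))

#: Frozen feature order per preset.
PRESETS: dict[str, tuple[str, ...]] = {
    "pkfree-full": ("Per_GC", "Per_bp") + _SSE_NAMES + ("RV_fe", "V_ed", "V_ea"),
    "pkfree-best5": ("RV_ent_3", "Per_GC", "V_ed", "V_ea", "RV_fe"),
    "pk-full": ("Per_GC", "Per_bp") + _SSE_NAMES + ("RV_bfe", "RV_kfe", "Per_kbp"),
    "pk-best3": ("RV_ent_3", "RV_ent_8", "RV_bfe"),
}

_EPS = 1e-9


class PresetError(ValueError):
    """Preset does not match the input's pseudoknottedness."""


@dataclass(frozen=True)
class FeatureVector:
    preset: str
    values: dict[str, float]
    #: names whose ratio denominator was degenerate (reported as 0)
    degenerate: frozenset[str] = frozenset()

    def as_row(self) -> list[float]:
        return [self.values[name] for name in PRESETS[self.preset]]

    @property
    def names(self) -> tuple[str, ...]:
        return PRESETS[self.preset]


def gc_content(seq: RnaSequence | str) -> float:
    s = seq.residues if isinstance(seq, RnaSequence) else seq
    return (s.count("G") + s.count("C")) / len(s)


def bp_percentage(structure: SecondaryStructure) -> float:
    return 2.0 * len(structure.pairs) / structure.n


def _guarded_ratio(num: float, den: float) -> tuple[float, bool]:
    if abs(den) < _EPS:
        return (0.0, True)
    return (num / abs(den), False)


def rv_fe(v_fe: float, v_mfe: float) -> tuple[float, bool]:
    """Normalized free energy ``|V_fe - V_mfe| / |V_mfe|`` with division guard."""
    return _guarded_ratio(abs(v_fe - v_mfe), v_mfe)


def ensemble_diversity(
    bpp: BasePairProbabilities, structure: SecondaryStructure
) -> float:
    """Per-nucleotide expected base-pair distance between target and ensemble.

    ``[sum_{(i,j) in s} (1 - p_ij) + sum_{(i,j) not in s} p_ij] / n``; the
    second sum runs over the unordered pairs the partition function can
    populate, which is exactly the support of ``p``.
    """
    if bpp.n != structure.n:
        raise ValueError("probability matrix and structure lengths differ")
    in_s = structure.pair_set
    total = sum(1.0 - bpp.pair_prob(i, j) for i, j in in_s)
    total += sum(
        bpp.p[i, j]
        for i in range(1, structure.n + 1)
        for j in range(i + 1, structure.n + 1)
        if bpp.p[i, j] > 0.0 and (i, j) not in in_s
    )
    return total / structure.n


def expected_accuracy(
    bpp: BasePairProbabilities, structure: SecondaryStructure
) -> float:
    """Expected fraction of bases in the target pairing status under the ensemble."""
    if bpp.n != structure.n:
        raise ValueError("probability matrix and structure lengths differ")
    partner = structure.partner()
    total = sum(2.0 * bpp.pair_prob(i, j) for i, j in structure.pairs)
    total += sum(
        bpp.unpaired_prob(i) for i in range(1, structure.n + 1) if i not in partner
    )
    return total / structure.n


def per_kbp(decomposition: Decomposition) -> float:
    total = len(decomposition.base.structure.pairs) + len(decomposition.knot_pairs)
    if total == 0:
        return 0.0
    return len(decomposition.knot_pairs) / total


def featurize(
    pair: StructurePair,
    model: EnergyModel,
    preset: str = "pkfree-full",
    backend=None,
) -> FeatureVector:
    """Assemble the ordered feature vector for one sequence-structure pair.

    ``backend`` may be an external-engine adapter (same surface as the
    built-in operations); by default the built-in model computes everything.
    """
    if preset not in PRESETS:
        raise PresetError(f"unknown preset {preset!r}")
    knotted = is_pseudoknotted(pair.structure)
    if preset.startswith("pkfree") and knotted:
        raise PresetError(f"preset {preset!r} rejects pseudoknotted input")

    values: dict[str, float] = {}
    degenerate: set[str] = set()
    names = PRESETS[preset]

    if "Per_GC" in names:
        values["Per_GC"] = gc_content(pair.sequence)
    if "Per_bp" in names:
        values["Per_bp"] = bp_percentage(pair.structure)
    for name in names:
        if name.startswith("RV_ent_"):
            values[name] = normalized_sse(pair.sequence, int(name.rsplit("_", 1)[1]))

    if preset.startswith("pkfree"):
        if {"RV_fe", "V_ed", "V_ea"} & set(names):
            if backend is not None:
                v_fe = backend.eval_energy(pair)
                v_mfe, _ = backend.mfe(pair.sequence)
                bpp = backend.pair_probabilities(pair.sequence)
            else:
                v_fe = eval_energy(pair, model)
                v_mfe, _ = mfe(pair.sequence, model)
                bpp = pair_probabilities(pair.sequence, model)
            if "RV_fe" in names:
                values["RV_fe"], flag = rv_fe(v_fe, v_mfe)
                if flag:
                    degenerate.add("RV_fe")
            if "V_ed" in names:
                values["V_ed"] = ensemble_diversity(bpp, pair.structure)
            if "V_ea" in names:
                values["V_ea"] = expected_accuracy(bpp, pair.structure)
    else:
        d = decompose(pair)
        if backend is not None:
            v_bfe = backend.eval_energy(d.base)
            v_bmfe, _ = backend.mfe(pair.sequence)
            v_kfe = knot_energy_features(pair, model, d)[2]
        else:
            v_bfe, v_bmfe, v_kfe = knot_energy_features(pair, model, d)
        if "RV_bfe" in names:
            values["RV_bfe"], flag = _guarded_ratio(abs(v_bfe - v_bmfe), v_bmfe)
            if flag:
                degenerate.add("RV_bfe")
        if "RV_kfe" in names:
            values["RV_kfe"], flag = _guarded_ratio(abs(v_bfe - v_kfe), v_bfe)
            if flag:
                degenerate.add("RV_kfe")
        if "Per_kbp" in names:
            values["Per_kbp"] = per_kbp(d)

    return FeatureVector(
        preset=preset,
        values={name: float(values[name]) for name in names},
        degenerate=frozenset(degenerate),
    )
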