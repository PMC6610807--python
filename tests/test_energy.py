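import math

import numpy as np
import pytest

from foldna.energy import (
    BackendError,
    EnergyError,
    builtin_model,
    eval_energy,
    external_backend,
    mfe,
    pair_probabilities,
)
from foldna.structure_io import RnaSequence, SecondaryStructure, StructurePair

from oracles import boltzmann_pair_matrix, enumerate_structures


def _pair(seq, pairs):
    return StructurePair(RnaSequence(seq), SecondaryStructure(n=len(seq), pairs=pairs))


def test_empty_structure_scores_zero(model):
    assert eval_energy(_pair("ACGUACGU", ()), model) == 0.0


def test_too_small_hairpin_rejected(model):
    with pytest.raises(EnergyError, match="hairpin"):
        eval_energy(_pair("GAAC", ((1, 4),)), model)


def test_stem_loop_energy_is_stacks_plus_hairpin(model):
    # two GC/GC stack terms plus the hairpin(4) penalty of the frozen table
    e = eval_energy(_pair("GGGAAAACCC", ((1, 10), (2, 9), (3, 8))), model)
    expected = 2 * model.stack_energy("GC", "GC") + model.hairpin(4)
    assert e == pytest.approx(expected)
    assert e == pytest.approx(-6.0 + 4.5 + math.log(4.0))


def test_pseudoknotted_input_refused(model):
    knotted = StructurePair(
        RnaSequence("GGAAGGAACCAACC"),
        SecondaryStructure(n=14, pairs=((1, 10), (5, 14))),
    )
    with pytest.raises(EnergyError, match="decompose"):
        eval_energy(knotted, model)


def test_removing_stack_pairs_never_decreases_energy(model):
    # peeling outer pairs off a helix removes stabilizing stack terms
    seq = "GGGGAAAACCCC"
    pairs = [(1, 12), (2, 11), (3, 10), (4, 9)]
    energies = []
    while pairs:
        energies.append(eval_energy(_pair(seq, tuple(pairs)), model))
        pairs = pairs[1:]
    assert energies == sorted(energies)


def test_unpairable_sequence_has_zero_mfe(model):
    e, s = mfe(RnaSequence("AAAAAA"), model)
    assert e == 0.0 and not s.pairs


def test_mfe_matches_enumeration(model):
    rng = np.random.default_rng(7)
    for _ in range(8):
        n = int(rng.integers(8, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        structures = enumerate_structures(seq)
        energies = [
            eval_energy(_pair(seq, st), model) for st in structures
        ]
        e_dp, s_dp = mfe(RnaSequence(seq), model)
        assert e_dp == pytest.approx(min(energies), abs=1e-9)
        # returned structure really attains the optimum
        assert eval_energy(
            StructurePair(RnaSequence(seq), s_dp), model
        ) == pytest.approx(e_dp, abs=1e-9)
        # DP lower-bounds every enumerated structure
        assert all(e_dp <= e + 1e-9 for e in energies)


def test_mfe_handles_multiloop_sequences(model):
    seq = "GCGGAAACGCAAGGGAAACCC"
    structures = enumerate_structures(seq)
    energies = [eval_energy(_pair(seq, st), model) for st in structures]
    e_dp, _ = mfe(RnaSequence(seq), model)
    assert e_dp == pytest.approx(min(energies), abs=1e-9)


def test_mfe_deterministic(model):
    seq = RnaSequence("GGCGAAAGCGCC")
    assert mfe(seq, model) == mfe(seq, model)


def test_pair_probabilities_trivial_unpaired(model):
    bpp = pair_probabilities(RnaSequence("AAAA"), model)
    assert np.allclose(bpp.q[1:], 1.0)
    assert np.all(bpp.p == 0.0)


def test_pair_probabilities_match_boltzmann_enumeration(model):
    rng = np.random.default_rng(21)
    for _ in range(5):
        n = int(rng.integers(9, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        structures = enumerate_structures(seq)
        energies = [eval_energy(_pair(seq, st), model) for st in structures]
        p_exact, _ = boltzmann_pair_matrix(structures, energies, model.rt)
        bpp = pair_probabilities(RnaSequence(seq), model)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                assert bpp.p[i, j] == pytest.approx(
                    p_exact.get((i, j), 0.0), abs=1e-9
                )
        # q_i consistency
        for i in range(1, n + 1):
            assert bpp.q[i] == pytest.approx(
                1.0 - bpp.p[i, :].sum() - bpp.p[:, i].sum(), abs=1e-9
            )
            assert -1e-9 <= bpp.q[i] <= 1.0 + 1e-9


def test_high_temperature_limit_counts_structures(model):
    # as T grows the Boltzmann ensemble tends to the uniform ensemble
    from dataclasses import replace

    hot = replace(model, temperature=1e9)
    seq = "GGCGAAAGCC"
    structures = enumerate_structures(seq)
    counts = {}
    for st in structures:
        for ij in st:
            counts[ij] = counts.get(ij, 0) + 1
    bpp = pair_probabilities(RnaSequence(seq), hot)
    for ij, c in counts.items():
        assert bpp.p[ij] == pytest.approx(c / len(structures), rel=1e-4)


def test_external_backend_contract():
    with pytest.raises(BackendError):
        external_backend("no-such-engine")
    adapter = external_backend("viennarna", strict=False)
    if adapter is None:
        pytest.skip("ViennaRNA bindings not installed")
    seq = RnaSequence("GGGGAAAACCCC")
    e, s = adapter.mfe(seq)
    assert e < 0 and s.pairs
    bpp = adapter.pair_probabilities(seq)
    for i in range(1, seq.n + 1):
        assert bpp.q[i] == pytest.approx(
            1.0 - bpp.p[i, :].sum() - bpp.p[:, i].sum(), abs=1e-6
        )
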