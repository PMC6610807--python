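import numpy as np
import pytest

from foldna.pu_learning import (
    GenerationConstraints,
    InfeasibleConstraintsError,
    build_unlabeled,
    distance_to_positives,
    local_inverse_fold,
    minmax_normalize,
    sample_sequence,
    select_reliable_negatives,
)
from foldna.energy import mfe
from foldna.structure_io import RnaSequence, parse_dotbracket

from oracles import brute_top_k_by_max_distance

HAIRPIN = parse_dotbracket("((((....))))")


def _max_run(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def test_sample_sequence_satisfies_all_three_constraints():
    constraints = GenerationConstraints(repetition_limit=4, gc_min=0.4, gc_max=0.6)
    partner = HAIRPIN.partner()
    from foldna.structure_io import CANONICAL_PAIRS

    for seed in range(50):
        seq = sample_sequence(HAIRPIN, constraints, rng_seed=seed)
        s = seq.residues
        assert _max_run(s) <= 4
        assert "AAAAA" not in s  # runs longer than the limit are barred
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.4 <= gc <= 0.6
        for i, j in HAIRPIN.pairs:
            assert (s[i - 1], s[j - 1]) in CANONICAL_PAIRS
        assert partner  # structure has pairs to constrain


def test_sample_sequence_deterministic_under_seed():
    c = GenerationConstraints()
    assert sample_sequence(HAIRPIN, c, rng_seed=7) == sample_sequence(
        HAIRPIN, c, rng_seed=7
    )


def test_sample_sequence_infeasible_constraints_error():
    # AU-only pairing with gc_min = 1 can never reach full GC content
    c = GenerationConstraints(gc_min=1.0, gc_max=1.0, pairing_rule=("AU", "UA"))
    with pytest.raises(InfeasibleConstraintsError):
        sample_sequence(HAIRPIN, c, rng_seed=0, max_attempts=20)


def test_local_inverse_fold_improves_or_keeps_distance(model):
    target = parse_dotbracket("((((....))))")
    c = GenerationConstraints(gc_min=0.0, gc_max=1.0)
    improved = 0
    for seed in range(20):
        start = sample_sequence(target, c, rng_seed=seed)
        _, start_fold = mfe(start, model)
        d0 = len(start_fold.pair_set ^ target.pair_set)
        out = local_inverse_fold(target, model, c, rng_seed=seed, max_steps=40)
        _, out_fold = mfe(out, model)
        d1 = len(out_fold.pair_set ^ target.pair_set)
        assert d1 <= d0
        improved += d1 < d0
    # the walk must actually help on some starts, not merely not hurt
    assert improved > 0


def test_local_inverse_fold_keeps_perfect_start(model):
    # a start whose MFE structure already is the target comes back unchanged
    seq = RnaSequence("GGGGAAAACCCC")
    _, target = mfe(seq, model)
    out = local_inverse_fold(target, model, rng_seed=3, max_steps=10, start=seq)
    assert out == seq


def test_build_unlabeled_counts_provenance_and_determinism(model):
    seeds = [("h1", HAIRPIN), ("h2", parse_dotbracket("(((...)))..."))]
    recs = build_unlabeled(seeds, model, per_structure=5, rng_seed=17,
                           inverse_fold_fraction=0.4, inverse_fold_steps=5)
    assert len(recs) == 10
    assert {r.seed_structure_id for r in recs} == {"h1", "h2"}
    assert {r.generator for r in recs} == {"adaptive-walk", "constrained-sample"}
    again = build_unlabeled(seeds, model, per_structure=5, rng_seed=17,
                            inverse_fold_fraction=0.4, inverse_fold_steps=5)
    assert [r.pair.sequence.residues for r in recs] == [
        r.pair.sequence.residues for r in again
    ]
    assert build_unlabeled(seeds, model, per_structure=0, rng_seed=17) == []


def test_minmax_normalize_maps_to_unit_interval():
    P = np.array([[2.0, 1.0], [4.0, 1.0]])
    U = np.array([[3.0, 1.0]])
    Pn, Un, record = minmax_normalize(P, U)
    assert Un[0, 0] == pytest.approx(0.5)  # value 3 in span [2, 4]
    assert np.all(Pn[:, 1] == 0.0)  # constant column maps to 0
    assert ((0 <= Pn) & (Pn <= 1)).all() and ((0 <= Un) & (Un <= 1)).all()
    assert record["min"][0] == 2.0 and record["max"][0] == 4.0


def test_distance_to_positives_examples():
    P = np.array([[0.0, 0.0], [1.0, 1.0]])
    assert distance_to_positives(np.array([0.0, 0.0]), P) == pytest.approx(np.sqrt(2))
    assert distance_to_positives(np.array([0.5, 0.5]), np.array([[0.5, 0.5]])) == 0.0
    # max-monotonicity: adding a positive never decreases the value
    d_before = distance_to_positives(np.array([0.2, 0.2]), P)
    P3 = np.vstack([P, [5.0, 5.0]])
    assert distance_to_positives(np.array([0.2, 0.2]), P3) >= d_before
    with pytest.raises(ValueError):
        distance_to_positives(np.array([0.0]), np.empty((0, 1)))


def test_select_reliable_negatives_planted_geometry(rng):
    P = rng.uniform(0.4, 0.6, size=(20, 3))
    near = P[:10] + rng.normal(0, 0.01, size=(10, 3))
    far = rng.uniform(0.4, 0.6, size=(10, 3)) + 0.8
    U = np.vstack([near, far])
    chosen = select_reliable_negatives(U, P, k=10)
    assert chosen == list(range(10, 20))
    assert select_reliable_negatives(U, P, k=len(U)) == list(range(20))
    assert select_reliable_negatives(U, P, k=0) == []
    with pytest.raises(ValueError):
        select_reliable_negatives(U, P, k=21)


def test_select_matches_brute_force_and_min_mode(rng):
    for _ in range(20):
        P = rng.random((8, 4))
        U = rng.random((15, 4))
        k = int(rng.integers(1, 15))
        assert select_reliable_negatives(U, P, k) == brute_top_k_by_max_distance(U, P, k)
    # min-distance variant ranks by nearest positive instead
    P = np.array([[0.0, 0.0]])
    U = np.array([[3.0, 0.0], [1.0, 1.0]])
    assert select_reliable_negatives(U, P, 1, mode="min") == [0]
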