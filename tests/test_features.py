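import numpy as np
import pytest

from foldna.energy import BasePairProbabilities, eval_energy, mfe
from foldna.features import (
    PRESETS,
    PresetError,
    bp_percentage,
    ensemble_diversity,
    expected_accuracy,
    featurize,
    gc_content,
    per_kbp,
    rv_fe,
)
from foldna.pseudoknot import decompose
from foldna.structure_io import (
    RnaSequence,
    SecondaryStructure,
    StructurePair,
    is_pseudoknotted,
    parse_dotbracket,
)


def _bpp(n, entries):
    p = np.zeros((n + 1, n + 1))
    for (i, j), v in entries.items():
        p[i, j] = v
    q = np.ones(n + 1)
    for i in range(1, n + 1):
        q[i] = 1.0 - p[i, :].sum() - p[:, i].sum()
    return BasePairProbabilities(n=n, p=p, q=q)


def test_gc_content_values():
    assert gc_content("GAAAAAAAAAAAAAAAAAAC") == pytest.approx(0.10)
    assert gc_content("GACCGUCGUGAGACAGGUUA") == pytest.approx(0.55)
    assert gc_content("GGCC") == 1.0


def test_bp_percentage_values():
    assert bp_percentage(parse_dotbracket("((..))")) == pytest.approx(4 / 6)
    assert bp_percentage(SecondaryStructure(n=5)) == 0.0
    assert bp_percentage(parse_dotbracket("((((....))))")) == pytest.approx(8 / 12)


def test_rv_fe_formula_and_guard():
    assert rv_fe(-10.0, -10.0) == (0.0, False)
    value, flag = rv_fe(-8.0, -10.0)
    assert value == pytest.approx(0.2) and not flag
    value, flag = rv_fe(0.0, 0.0)
    assert value == 0.0 and flag  # degenerate denominator


def test_ensemble_diversity_examples():
    s = SecondaryStructure(n=4, pairs=((1, 4),))
    perfect = _bpp(4, {(1, 4): 1.0})
    assert ensemble_diversity(perfect, s) == pytest.approx(0.0)
    mixed = _bpp(4, {(1, 4): 0.8, (2, 3): 0.1})
    assert ensemble_diversity(mixed, s) == pytest.approx((0.2 + 0.1) / 4)
    empty = SecondaryStructure(n=4)
    assert ensemble_diversity(_bpp(4, {}), empty) == 0.0


def test_expected_accuracy_examples():
    s = SecondaryStructure(n=4, pairs=((1, 4),))
    assert expected_accuracy(_bpp(4, {(1, 4): 1.0}), s) == pytest.approx(1.0)
    mixed = _bpp(4, {(1, 4): 0.8, (2, 3): 0.1})
    # 2*0.8 for the pair, q_2 = q_3 = 0.9 for the unpaired bases
    assert expected_accuracy(mixed, s) == pytest.approx((1.6 + 0.9 + 0.9) / 4)
    assert expected_accuracy(_bpp(4, {}), SecondaryStructure(n=4)) == 1.0


def test_diversity_zero_iff_accuracy_one():
    s = SecondaryStructure(n=6, pairs=((1, 6), (2, 5)))
    concentrated = _bpp(6, {(1, 6): 1.0, (2, 5): 1.0})
    assert ensemble_diversity(concentrated, s) == pytest.approx(0.0)
    assert expected_accuracy(concentrated, s) == pytest.approx(1.0)


def test_bounded_features_on_randomized_ensembles(rng):
    # random consistent probability matrices: V_ed and V_ea stay in [0, 1]
    for _ in range(1000):
        n = int(rng.integers(4, 12))
        pairs = []
        entries = {}
        budget = np.ones(n + 1)
        for _ in range(int(rng.integers(0, 4))):
            i, j = sorted(rng.choice(np.arange(1, n + 1), size=2, replace=False))
            if i == j or (i, j) in entries:
                continue
            cap = min(budget[i], budget[j])
            if cap <= 0:
                continue
            v = rng.uniform(0, cap)
            entries[(i, j)] = v
            budget[i] -= v
            budget[j] -= v
        bpp = _bpp(n, entries)
        k = int(rng.integers(0, min(3, n // 4) + 1))
        used = set()
        spairs = []
        for _ in range(k):
            i, j = sorted(rng.choice(np.arange(1, n + 1), size=2, replace=False))
            if i != j and not {i, j} & used:
                spairs.append((i, j))
                used |= {i, j}
        s = SecondaryStructure(n=n, pairs=tuple(spairs))
        assert 0.0 - 1e-9 <= ensemble_diversity(bpp, s) <= 1.0 + 1e-9
        assert 0.0 - 1e-9 <= expected_accuracy(bpp, s) <= 1.0 + 1e-9


def test_per_kbp_fractions():
    s = list("A" * 16)
    for i, j in [(2, 11), (3, 10), (6, 15), (7, 14)]:
        s[i - 1], s[j - 1] = "G", "C"
    knotted = StructurePair(
        RnaSequence("".join(s)),
        SecondaryStructure(n=16, pairs=((2, 11), (3, 10), (6, 15), (7, 14))),
    )
    assert per_kbp(decompose(knotted)) == pytest.approx(0.5)
    free = StructurePair(
        RnaSequence("GGGAAAACCC"),
        SecondaryStructure(n=10, pairs=((1, 10), (2, 9), (3, 8))),
    )
    assert per_kbp(decompose(free)) == 0.0


def test_preset_feature_lists():
    assert PRESETS["pkfree-best5"] == ("RV_ent_3", "Per_GC", "V_ed", "V_ea", "RV_fe")
    assert PRESETS["pk-best3"] == ("RV_ent_3", "RV_ent_8", "RV_bfe")
    assert len(PRESETS["pkfree-full"]) == 11
    assert len(PRESETS["pk-full"]) == 11


def test_featurize_shapes_ranges_and_determinism(model, small_corpus):
    for pair in small_corpus:
        knotted = is_pseudoknotted(pair.structure)
        preset = "pk-full" if knotted else "pkfree-full"
        fv = featurize(pair, model, preset=preset)
        assert tuple(fv.values) == PRESETS[preset]
        for name in ("Per_GC", "Per_bp"):
            assert 0.0 <= fv.values[name] <= 1.0
        for w in range(3, 9):
            assert 0.0 <= fv.values[f"RV_ent_{w}"] <= 1.0 + 1e-12
        if knotted:
            assert fv.values["RV_bfe"] >= 0.0
            assert fv.values["RV_kfe"] >= 0.0
            assert 0.0 <= fv.values["Per_kbp"] < 1.0
        else:
            assert fv.values["RV_fe"] >= 0.0
            assert 0.0 - 1e-9 <= fv.values["V_ed"] <= 1.0 + 1e-9
            assert 0.0 - 1e-9 <= fv.values["V_ea"] <= 1.0 + 1e-9
        again = featurize(pair, model, preset=preset)
        assert fv.values == again.values


def test_featurize_rejects_preset_mismatch(model, small_corpus):
    knotted = next(p for p in small_corpus if is_pseudoknotted(p.structure))
    with pytest.raises(PresetError):
        featurize(knotted, model, preset="pkfree-best5")
    with pytest.raises(PresetError):
        featurize(knotted, model, preset="not-a-preset")


def test_featurize_rv_fe_zero_at_mfe_structure(model):
    seq = RnaSequence("GGGGAAAACCCC")
    _, s = mfe(seq, model)
    fv = featurize(StructurePair(seq, s), model, preset="pkfree-best5")
    assert fv.values["RV_fe"] == pytest.approx(0.0, abs=1e-9)
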