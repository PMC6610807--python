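# foldna

Foldability scoring for RNA sequence–structure pairs.

Most RNA design tools assume a sequence folds into its minimum-free-energy
(MFE) secondary structure, yet a large share of natural RNAs live in
suboptimal conformations, so MFE agreement alone is a poor acceptance test
for a designed sequence.  `foldna` instead treats design as a prediction
problem: given a sequence *and* a target secondary structure (pseudoknotted
or not), it estimates the *foldability* `l(structure, sequence)` — the
probability that the two co-exist.  It is aimed at people building RNA
nanostructures or evaluating inverse-folding candidates who want a
data-driven score rather than a single thermodynamic verdict.

## What it computes

Each pair is mapped to a length-free feature vector:

* **Sequence segment entropy (SSE).**  For window size *w*, the Shannon
  entropy of the distribution of the `n + 1 − w` overlapping *w*-mers,
  `V_ent,w = −Σ_i p_i log2 p_i`, normalized by its closed-form maximum
  `V*_ent,w` (uniform two-level *w*-mer profile) to give `RV_ent,w ∈ [0,1]`.
  Windows 3–8 are the shipped default; `select_window_range` recomputes the
  usable range on a corpus by growing the window set until the columns'
  condition index exceeds 30 (the standard collinearity alarm).
* **Thermodynamics.**  `RV_fe = |V_fe − V_mfe| / |V_mfe|` from the structure's
  free energy and the sequence MFE; for pseudoknots, the structure is first
  decomposed into a maximum non-crossing *base substructure* and excised
  *knot segments*, giving `RV_bfe`, `RV_kfe` and the knot base-pair fraction.
  A self-contained nearest-neighbour energy model (frozen parameter table,
  Zuker-style MFE, McCaskill partition function) ships with the package; a
  ViennaRNA adapter can stand in when full physics is wanted.
* **Ensemble statistics.**  Ensemble diversity
  `V_ed = [Σ_{(i,j)∈s}(1−p_ij) + Σ_{(i,j)∉s} p_ij]/n` and expected accuracy
  `V_ea = [Σ_{(i,j)∈s} 2 p_ij + Σ_{i∈up} q_i]/n` from base-pair
  probabilities.
* **Composition.**  GC content and base-pair percentage.

Because failed RNAs are rarely published, training uses positive–unlabeled
(PU) learning: candidate sequences are generated for each positive structure
under base-pairing, run-length and GC constraints, the *k* unlabeled rows
with the largest (max over positives) Euclidean feature distance are taken
as reliable negatives, and a logistic regression is fit.  A pair is called
foldable when its predicted probability exceeds 0.5.

## Worked example

```sh
$ printf '>seq1\nGAAAAAAAAAAAAAAAAAAC\n>seq2\nGACCGUCGUGAGACAGGUUA\n' > ex.fa
$ foldna sse --fasta ex.fa --window 3
id      v_ent     v_max     rv_ent
seq1    0.614369  4.169925  0.147333
seq2    3.947703  4.169925  0.946708
```

Both 20-mers admit 18 trigram windows, so the maximum entropy is
`log2 18 = 4.170` bits.  The near-homopolymer `seq1` has only three distinct
trigrams (one of them 16 times out of 18, probability 0.889) and lands at
`RV_ent,3 = 0.147`; the diverse `seq2` is close to the maximum at 0.947 —
higher segment diversity means the sequence can sample more alternative
pairings.

The library surface mirrors the pipeline:

```python
>>> from foldna import *
>>> m = builtin_model()
>>> pair = StructurePair(RnaSequence("GGGGAAAACCCC"), parse_dotbracket("((((....))))"))
>>> featurize(pair, m, preset="pkfree-best5").values
{'RV_ent_3': 0.819, 'Per_GC': 0.667, 'V_ed': 0.009, 'V_ea': 0.987, 'RV_fe': 0.0}
>>> mfe(RnaSequence("GGGGAAAACCCC"), m)[0]
-3.114
```

`RV_fe = 0` says the target *is* the MFE structure under the built-in model,
and the near-zero ensemble diversity says the Boltzmann ensemble is
concentrated on it — an easily foldable pair.

The full CLI pipeline is `foldna synth` → `foldna featurize` →
`foldna gen-negatives` → `foldna train` → `foldna predict`, with
`foldna decompose` and `foldna evaluate` as utilities; every artifact embeds
the seed and energy-backend fingerprint that produced it.

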