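# Methods

## Problem and model

`foldna` scores the compatibility of an RNA sequence with a target secondary
structure.  The score is the positive-class probability of a logistic
regression over a small set of length-free features; a pair is called
foldable when the probability strictly exceeds 0.5 (the threshold is
configurable, and the strict inequality means a score of exactly 0.5 is a
negative call).

Coordinates are 1-based throughout, pairs are `(i, j)` with `i < j`, and a
structure is pseudoknotted exactly when two pairs interleave
(`i < k < j < l`).  Pseudoknots are rendered with up to four bracket pages
(`()`, `[]`, `{}`, `<>`), assigned greedily first-fit; inputs needing more
than four mutually crossing pages are refused.  Permitted pairings are
Watson–Crick plus GU wobble; non-canonical pairs in input structures are
rejected by default (the energy model cannot score them) and admitted only
with an explicit override.  `T` is transliterated to `U` on read; IUPAC
ambiguity codes are rejected because segment entropy and pairing features
are undefined for them.

## Sequence segment entropy

For window `w`, the `N = n + 1 − w` overlapping segments define an empirical
distribution whose Shannon entropy (bits) is `V_ent,w`; `0·log 0 := 0`.  The
maximum for given `n, w` has a closed form: if `N ≤ 4^w` it is `log2 N`
(all segments distinct); otherwise the most uniform integer profile puts
`b = N mod 4^w` words at count `a+1` and the rest at `a = ⌊N/4^w⌋`.  The
normalized value `RV = V/V*` is defined as 0 when `V* = 0` (window equal to
the sequence length), where the ratio would be 0/0.

The model consumes normalized SSE columns for windows 3–8 by default.
`select_window_range` recomputes that range on a user corpus: columns are
scaled to unit Euclidean length *without centering* (the Belsley-style
convention for collinearity diagnostics — the computation is not pinned by
any published definition here, so the diagnostics-literature convention was
chosen) and windows are added until the largest condition index
`σ_max/σ_min` exceeds 30.  Normalized rather than raw SSE columns enter the
diagnostic, since they are what the classifier consumes.  Numerically
rank-deficient matrices report a large sentinel (1e12) with a collinearity
flag rather than dividing by a zero singular value.

## Built-in energy model

The package delegates nothing to external binaries by default: a simplified
nearest-neighbour model makes the whole pipeline self-contained.

* Stacking energies from a frozen 6×6 table (kcal/mol): −3.0 for
  strong-on-strong (GC-type on GC-type), −1.0 for weak-on-weak (AU/GU-type),
  −2.0 mixed.  The table ships as versioned config
  (`data/builtin_energy_v1.yaml`); trained models fingerprint it.
* Hairpin loops (≥ 3 unpaired bases): `4.5 + ln(size)`; internal/bulge
  loops: `1.5 + ln(size)`; multiloops: `3.0 + 0.3·branches +
  0.1·unpaired`, closing pair counted as a branch.  Exterior bases are free.
  Penalty magnitudes sit in the range of published nearest-neighbour fits;
  dangles, coaxial stacking and special loops (e.g. tetraloop bonuses) are
  deliberately excluded for tractability.
* Temperature 310.15 K, R = 1.987e−3 kcal/(mol·K).

`eval_energy` scores a structure by loop decomposition; `mfe` is a
Zuker-style interval DP over exactly the same decomposition (interior loops
capped at 30 unpaired bases, the standard truncation, which only matters
above the lengths the test corpora use); `pair_probabilities` runs McCaskill
inside/outside recursions under the same function, so
`weight(s) = exp(−eval_energy(s)/RT)` holds identically — the property the
enumeration-oracle tests assert to 1e−9 for n ≤ 12.  MFE ties are broken
toward fewer pairs and then by a fixed traceback scan order (earliest 5'
pair, nearest partner), making the traceback deterministic.  Unpairable
sequences fold to the empty structure at 0.0 kcal/mol.

Energies under this model are model-relative.  The optional ViennaRNA
adapter provides full-physics numbers behind the same three-operation
surface; because the scales differ, model files embed the backend
fingerprint and scoring refuses to mix backends unless overridden.  An
absent engine degrades gracefully to the built-in model with a logged
notice when not strict; a *failure* during a run always raises.

## Pseudoknot decomposition

The base substructure is the maximum-cardinality non-crossing subset of
pairs — cardinality, not energy-weighted, following the maximum-pair
criterion — computed by interval DP with ties broken toward the
lexicographically smallest sorted pair list.  Removed (knot) pairs are
grouped into components by span overlap: nested or crossing knot pairs
belong together (pure crossing-edge connectivity would split a nested knot
helix across segments, which contradicts how an H-type knot stem should be
scored as one unit).  Each component is excised as the minimal contiguous
window covering its pairs, re-indexed, with interior non-component bases
left unpaired; if a component is internally crossing, its dominant
non-crossing subset is scored.

Three energies result: `V_bfe` (base substructure on the full sequence),
`V_bmfe` (plain sequence MFE — pseudoknot-free by construction; refolding
through knot positions is not forbidden), and `V_kfe`, the sum over knot
segments of the segment fold energy minus the hairpin-loop penalties of the
hairpins created by closing the excised segment.  Those hairpins are
artifacts of the excision — their loop bases pair elsewhere in the original
molecule — so exactly their loop-penalty terms are subtracted, nothing else.
For a pure two-stack H-knot this leaves a single stack term, which is why
stabilizing knots give `V_kfe < 0`.

## Features and presets

Pseudoknot-free vectors: GC content, base-pair percentage, `RV_ent_3..8`,
`RV_fe = |V_fe − V_mfe|/|V_mfe|`, ensemble diversity `V_ed`, expected
accuracy `V_ea` (11 features).  Pseudoknotted vectors replace the three
ensemble/energy features with `RV_bfe = |V_bfe − V_bmfe|/|V_bmfe|`,
`RV_kfe = |V_bfe − V_kfe|/|V_bfe|` and the knot base-pair fraction.
`V_ed`'s "pairs not in s" sum ranges over the pairs a partition function can
populate (canonical, hairpin-feasible), which is exactly the support of the
probability matrix.  Reduced presets encode the published outcome of an
exhaustive feature-combination search: `pkfree-best5 = {RV_ent_3, Per_GC,
V_ed, V_ea, RV_fe}` and `pk-best3 = {RV_ent_3, RV_ent_8, RV_bfe}`.  (The
prose naming the third pseudoknot feature attaches the knotted-substructure
symbol to the base-substructure description; the base-substructure formula
is used, and the discrepancy is recorded here.)  Ratios whose denominator is
below 1e−9 in magnitude are reported as 0 and flagged degenerate rather
than returning the undefined formula value.  Feature order is frozen per
preset and stored in model files.

## PU training sets

Unlabeled candidates are generated per positive seed structure (100 per
structure by default) under three constraints: permitted pairings at paired
positions, identical-base runs no longer than the repetition limit (default
4 — the run-length reading of the constraint: runs *strictly longer* than
the limit are barred), and GC fraction within a band (default 0.2–0.8).
Generation is rejection-with-repair with a bounded budget; genuinely
infeasible constraint combinations raise.  A configurable fraction (default
20%) of candidates per seed instead comes from an adaptive-walk inverse
folder: single-position or pair-consistent mutations accepted whenever the
base-pair distance from the candidate's MFE structure to the target does not
increase.  The walk stands in for external inverse-folding tools behind the
same seam and keeps candidate quality mixed, which is the point of an
unlabeled pool.

Features of unlabeled records are computed against their *seed* structure —
the pair whose foldability is in question — not against the candidate's own
MFE fold.  After joint min-max normalization of P and U (the record is
persisted and re-applied verbatim at prediction), each unlabeled row gets
`d_u = max_k ||f_u − f_{p_k}||` over positives, and the top-k rows are the
reliable negatives (row-index tie-break).  The maximum-distance form is the
default; a nearest-positive (`min`) variant is available since "furthest
from the positives" is also naturally read that way.  All randomness
derives from one master seed through named substreams, and provenance
(seed structure, generator, substream seed) is persisted per record.

## Classifier

scikit-learn logistic regression (lbfgs) with a small L2 penalty
(λ = 1e−4 per example) for stability on collinear or separable features;
no penalty strength is prescribed by the method itself.  Models serialize
to JSON (schema-versioned) with weights, intercept, preset, normalization
record and backend fingerprint; serialization is bit-stable and scoring a
reloaded model reproduces scores exactly.  Evaluation reports confusion
counts, sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)` and their mean;
undefined ratios are reported as absent, never as 0.  Leave-one-out
cross-validation refits per held-out row; a held-out row that removes the
only member of its class is counted as misclassified rather than skipped.

## Synthetic corpora

The fixture generator draws side-by-side nested stem-loops (hairpins ≥ 3
nt) and, with configurable probability, injects one H-type pseudoknot by
pairing two hairpin-loop bases with two downstream free bases — sufficient
to exercise decomposition and every pseudoknot feature, and the only knot
topology generated.  Sequences are sampled under the same constraint
machinery as PU generation (defaults: GC 0.3–0.7, repetition limit 4,
lengths 24–40 nt; tests use 18–30 nt so partition functions stay cheap).
Corpora carry mandatory manifests with every seed.  The generator emulates
pairing geometry and composition, not the length or family distributions of
curated RNA databases — so green tests demonstrate correctness of the
machinery on realistic-sized inputs, not real-data sensitivities, which
require curated corpora and a full-physics backend.

## Numerical choices and limitations

* Energy comparisons in tests use 1e−9 absolute tolerance (float summation
  order), probabilities likewise 1e−9 against exhaustive Boltzmann sums.
* Exhaustive oracles run at n ≤ 12 (structure enumeration), ≤ 12 pairs
  (non-crossing subsets), n ≤ 40 / w ≤ 3 (entropy-maximization partitions);
  beyond that the DPs are the only tractable route, which is why they are
  cross-checked at small n.
* Partition-function arithmetic is unscaled doubles; fine below ~100 nt
  with this parameter table, overflow-prone far beyond (a known limit).
* The logistic weight-recovery check uses equal-magnitude generating
  weights (±1.5): at n = 2000 the per-coefficient information, not the
  fitter, bounds relative error, and low-magnitude coefficients cannot be
  pinned to 15% at that sample size.
* Foldability scores are clipped to [1e−12, 1 − 1e−12] so the open-interval
  contract survives sigmoid saturation in floating point.
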