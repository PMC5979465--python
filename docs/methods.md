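# Methods

This note records the scientific and numerical choices behind `protstab`:
what each stage computes, the parameters that matter, what the synthetic
generators do and do not emulate, and the known limitations.

## Curation model

A variant record is one ΔΔG measurement with its conditions (temperature,
pH, salt), provenance (sequence and optional structure reference,
measurement method) and a state flag distinguishing folded-protein
measurements from unfolded proteins and from per-stage values of
multi-stage denaturation pathways. Harmonization is mechanical and
idempotent: kJ/mol divided by 4.184; temperatures above 150 read as Kelvin
and shifted by −273.15 (no folded-protein measurement exists above
150 °C, so the heuristic cannot misfire in range). The sign convention is
positive ΔΔG = stabilizing.

Filtering rules, in order: unfolded-protein and per-stage records are
always rejected (whole-pathway totals are genuine ΔΔG values and pass);
peptides shorter than 30 residues are rejected (a "true fold" cutoff —
the underlying guidance says only "very short"); the reported wild-type
residue must match the reference sequence *after* applying background
substitutions (e.g. a cysteine-free pseudo-wild-type carrying C54T/C97A),
with ±5-offset probing to diagnose numbering shifts; exact duplicates
(same variant, ΔΔG, T, pH) collapse; measurements at pH outside 5–9 or
salt ≥ 0.2 M are rejected **only when** an in-range measurement of the
same variant exists — a lone measurement at pH 4 is kept; surviving
replicates resolve to one representative by ordered preference
(calorimetric > other thermal > chemical denaturation, then pH closest
to 7, then lowest salt, then record id). Every rejection carries a reason
code, making the curation reproducible and auditable rather than manual.

The label boundary at ±0.5 kcal/mol is closed: ΔΔG = ±0.5 exactly is
`no_effect`, reflecting measurement uncertainty near the boundary.

Reverse-variant augmentation mirrors each record (wt/mut swapped, ΔΔG
negated, reference sequence carrying the substitution) and flags the
mirrors; double mirroring restores the original (wt, mut, ΔΔG) triples.

## Conservation descriptors

Information content per column is `log2(20) + Σ p·log2 p` over the 20
amino acids, gaps excluded — 0 bits for a uniform column, 4.322 bits for
an invariant one. The plug-in estimate (no pseudocount) is the default;
the PSSM uses log2 odds with pseudocount 1.0 distributed by the background
(uniform 0.05 by default), which keeps unobserved residues finite:
`score = log2(((n_a + c·b_a)/(N + c))/b_a)`. These parameter choices
(log base, pseudocount, background) are this package's defaults, stated
here because the upstream convention is not standardized.

Co-evolution is a proxy: pairwise column association by Cramér's V on
residue identities, `max_cor` the largest association of a position with
any other column, `is_coevolving` thresholded at 0.8, and co-evolving
groups the connected components of the thresholded graph. Dedicated
co-evolution tools model phylogeny explicitly; this proxy keeps the four
feature names and value ranges while being dependency-free and
deterministic. Below 10 non-reference rows all co-evolution outputs are
zeroed and flagged low-depth rather than reporting associations that a
shallow alignment cannot support. Homolog search (typically E < 0.001)
and alignment happen upstream; the MSA is an input.

## Feature registry

The 1106 slots decompose as 2 (conditions) + 3 (conservation) + 4
(co-evolution) + 617 (amino-acid indices) + 400 (one-hot 20×20
substitution) + 36 (one-hot 6×6 physicochemical groups) + 20 + 5
(neighborhood counts over a 23-position window, variant site excluded,
truncated at termini) + 19 (precomputed whole-protein descriptors,
accepted as a sidecar table and median-imputed when absent). Per-residue
indices are encoded as value(mut) − value(wt) — one scalar per index;
matrix-type indices contribute their (wt, mut) entry, lower-triangular
matrices read symmetrically. Index records containing NA values are
filtered at load, leaving exactly 617 usable features.

Two different residue groupings coexist deliberately: the 6×6 block uses
hydrophobic {V,I,L,F,M,W,Y,C} / negative {D,E} / positive {R,K,H} /
conformational {G,P} / polar {N,Q,S} / other {A,T}, while the five
neighborhood class counts use a standard nonpolar/polar/charged scheme
with histidine counted polar-uncharged. The first follows the grouping
convention of the substitution-type encoding verbatim; the second is the
common neighborhood-composition scheme.

The packaged `aaindex_sample.txt` carries three real published indices
(Kyte–Doolittle hydropathy, Grantham polarity and volume) plus two
clearly-marked synthetic records for parser coverage. The full-census
table (544 + 94 + 47 records, 68 planted-incomplete → 617 usable) is
generated deterministically by `synthetic_fixtures.synthetic_aaindex_table()`;
its values are synthetic, its *census and format* are the point. Real
analyses should load a real index collection through
`AAIndexTable.from_file`.

## Homology-aware splitting and balancing

Pairwise identity is matches over total alignment columns of a global
BLOSUM62 alignment (gap open −11, extend −1) — the conservative
denominator. Clusters are single-linkage components above 30% identity:
single linkage is the safest closure of the pairwise "keep close homologs
together" constraint. Fold assignment is greedy largest-cluster-first onto
the smallest fold; the blind set is drawn (seeded) from singleton clusters
only, so no blind protein has a close homolog anywhere in training.

Layer-1 balancing keeps every decrease case and assembles the same total
of negatives from equal halves of increase and no_effect; layer 2
undersamples increase and no_effect to equal counts. Undersampling is
without replacement; a too-small class is resampled with replacement only
when unavoidable, and flagged. The equal-halves reading of the layer-1
negative composition is a documented choice where the underlying
description is ambiguous.

## Selection and model

Backward elimination removes, per iteration, the feature with the
smallest impurity-based forest importance, retraining each time, down to
8 features per fold (the terminal-8 subset is the default; a `keep="best"`
switch returns the lowest-validation-error intermediate subset instead).
The five subsets merge order-stably; forward selection then grows a single
subset, accepting per round the candidate with the lowest mean CV error
and stopping at the first round without strict improvement — the accepted
error path is strictly decreasing by construction. Error rate is
1 − accuracy (identically 1 − CPR for multi-class). Selection uses the
same 300-tree default as the final model for consistency; tests and the
recovery study use smaller forests (40–80 trees) as a problem-size choice.

Both cascade layers threshold the vote fraction at 0.5. Masked external
descriptors are imputed with training-set medians stored in the results
object; saved models embed a hash of the feature-name order so drift is
detected at load. Training and prediction are pure functions of
(data, seed): identical seeds give identical forests and predictions.

## Evaluation

CPR = trace/N replaces accuracy for three classes; GC² is the
chi-square-based generalization of MCC², `Σ (z−e)²/(e·N·(K−1))` with
expectations from the matrix's own margins, in [0, 1], and equal to MCC²
on 2×2 matrices with non-zero margins. When a margin is zero (a class
never predicted), GC² is undefined and reported NA, never 0.

Class-size normalization rescales each true-class row to the no-effect
row total. It preserves within-row proportions exactly (sensitivities are
unchanged) and equalizes row sums, making column-derived quantities (PPV,
NPV, specificity) comparable under imbalance; those are recomputed from
the scaled matrix. Normalized counts are displayed rounded to one decimal
but all downstream arithmetic uses unrounded values; displayed metrics
use decimal half-up rounding. (Published tables normalized per fold
before averaging in one case, which differs from single-pass row scaling
in the second decimal; single-pass is this package's default, and
`matrix_from_margins` + `normalize_to_reference` reproduce the printed
single-matrix numbers exactly.)

For evaluation from published per-class one-vs-rest counts,
`matrix_from_margins` rebuilds a full K×K matrix by non-negative least
squares on the off-diagonal cells. That completion is not unique, but
every quantity used downstream of it here — the diagonal, row sums, CPR,
row normalization — is invariant to the ambiguity.

## Synthetic data: what it does and does not show

The generators emulate the *mechanics* of the benchmark: class imbalance
≈ 1:2:4 (increase:no_effect:decrease), ΔΔG within −17.4…23.0 kcal/mol
with class-conditional truncated normals (decrease centred −2, increase
+1.5, sd 1), pH 2.7–9.6, temperatures 0–89 °C, corrupted files with
planted reason-coded issues, alignments with planted conservation and
perfectly coupled column pairs, and numeric tables with a known set of
mean-shifted informative columns. They do **not** emulate protein
energetics, realistic substitution patterns, phylogenetic structure in
alignments, or correlated features; a passing suite shows the pipeline's
mechanics (curation audit, leakage-free splitting, signal recovery,
metric arithmetic) are correct, not that any particular real-data
accuracy is attainable.

Problem sizes used by the test and acceptance runs, chosen as the
package's own desk-scale study conditions: the selection-recovery study
uses 20 seeded repeats of 200 rows × 50 features (3 informative columns,
class-mean spacing 2.0 sd, 40-tree forests, one 140/60 train/validation
split, forward selection over the two fold-swapped splits); the cascade
study uses 600 rows × 20 features (5 informative, spacing 3.0, 300 trees,
400/200 split). At these sizes the backward+forward procedure recovers at
least 2 of the 3 planted features in ≥ 90% of repeats and the cascade's
held-out CPR exceeds 0.8 comfortably.

## Limitations

* The co-evolution proxy measures column association, not
  phylogeny-corrected co-evolution; its numeric values are not comparable
  to dedicated tools, only its feature semantics.
* The 19 whole-protein descriptors are pass-through columns; the package
  neither computes nor validates them beyond masking and imputation.
* Sign-flip errors in ΔΔG records are not mechanically detectable from a
  record alone; curation documents the convention but cannot audit it.
* Identity clustering aligns all protein pairs (O(n²) global alignments);
  for thousands of proteins an external clustering tool would be the
  practical route.
* Real-data performance depends on the quality and depth of the supplied
  MSAs and index tables, which are inputs here.
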