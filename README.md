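# protstab

Three-class classification of the effect of amino-acid substitutions on
protein stability, from curated experimental ΔΔG measurements.

Experimental stability data (thermal and chemical denaturation of point
variants) is the training source for essentially every machine-learning
stability predictor, and it is messy: mixed units (kcal/mol vs kJ/mol),
Kelvin temperatures recorded as Celsius, pseudo-wild-type backgrounds
carrying extra substitutions, per-stage values of two-stage denaturation
pathways, unfolded proteins, duplicates, and measurements far from
physiological pH or ionic strength. `protstab` provides, as a library plus
a thin CLI, the full pipeline from raw records to an evaluated classifier:

* **Curation** — parsing, unit harmonization (kJ → kcal at 4.184, K → °C),
  sequence/background validation, and auditable filtering rules, every
  exclusion carrying a machine-readable reason code.
* **Labelling** — positive ΔΔG is stabilizing; |ΔΔG| ≤ 0.5 kcal/mol is
  `no_effect`, above +0.5 `increase`, below −0.5 `decrease`.
* **Features** — a 1106-slot registry: measurement conditions (T, pH),
  conservation (information content and PSSM log-odds from an MSA), a
  co-evolution proxy, 617 amino-acid indices/substitution matrices/contact
  potentials, one-hot 20×20 and 6×6 substitution-type blocks, 23-residue
  neighborhood counts, and 19 precomputed whole-protein descriptors.
* **Homology-aware validation** — proteins are clustered at >30% pairwise
  identity (single linkage, global BLOSUM62 alignment) and whole clusters
  assigned to the 5 CV folds; the blind test set contains only proteins
  without a close homolog anywhere.
* **Feature selection** — per-fold random-forest backward elimination to 8
  features, order-stable merge, then forward selection with a strict
  error-reduction stopping rule.
* **Model** — a two-layer cascade of balanced random forests (300 trees):
  layer 1 decides decrease vs no-decrease (negatives drawn half from
  increase, half from no_effect); layer 2 splits the rest into increase vs
  no_effect. A layer-1 decrease call is terminal.
* **Evaluation** — one-vs-rest accuracy/PPV/NPV/sensitivity/specificity/
  MCC, the correct prediction ratio CPR = trace(z)/N, the generalized
  squared correlation GC² = Σᵢⱼ (zᵢⱼ−eᵢⱼ)²/(eᵢⱼ·N·(K−1)) with
  eᵢⱼ = xᵢyⱼ/N, and class-size normalization: each true-class row of the
  confusion matrix rescaled to the no-effect class size, so metrics are
  comparable under the ≈ 1:2:4 increase:no_effect:decrease imbalance.

## Worked example

The model API follows the Model/Results convention: build a
`StabilityCascade` from a feature table and labels, `fit()` returns a
results object that predicts and summarizes. On a synthetic table with 5
informative and 15 noise columns:

```python
from protstab.synthetic_fixtures import generate_feature_table
from protstab import StabilityCascade, ConfusionMatrix

X, y, informative = generate_feature_table(
    n_rows=600, n_features=20, n_informative=5, effect_size=3.0, seed=1)
result = StabilityCascade(X.iloc[:400], y.iloc[:400].to_numpy(),
                          n_trees=300).fit(seed=1)
print(result.summary())

pred = result.predict(X.iloc[400:])
m = ConfusionMatrix.from_labels(y.iloc[400:], pred["label"],
                                classes=["increase", "decrease", "no_effect"])
print(f"held-out CPR  {m.cpr():.3f}")
```

prints (abridged):

```
               Two-layer stability cascade
==========================================================
Training records:      400
Trees per forest:      300
...
Layer 1 (decrease vs no-decrease)
  balanced composition: {'decrease': 218, 'increase': 109, 'no_effect': 109}
  out-of-bag accuracy:  1.000
...
held-out CPR  1.000
```

The balanced composition shows the layer-1 negative class assembled from
equal halves of increase and no_effect (109 + 109, matching the 218
decrease cases); out-of-bag accuracy and the held-out CPR of 1.000 reflect
the deliberately large effect size of the fixture, not real stability
data.

The same stages are available as subcommands (`protstab simulate`,
`curate`, `features`, `select`, `train`, `predict`, `evaluate`); every
stage writes a manifest of its resolved parameters so runs are repeatable
byte-for-byte.

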