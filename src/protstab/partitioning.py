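"""Homology-aware data splitting and class balancing.

Variants of the same protein — and of close homologs — share most of their
sequence context, so letting them straddle a train/test boundary leaks
information and inflates performance estimates.  Proteins are therefore
clustered by pairwise sequence identity (single linkage above a threshold,
30% by default) and whole clusters are assigned to cross-validation folds.
The blind test set is drawn from singleton clusters only, i.e. proteins
without a close homolog anywhere in the data.

Class balancing for the two cascade layers:

* ``layer1`` (decrease vs no-decrease): the negative class is assembled
  from equal halves of increase and no_effect cases, matched in total to
  the decrease count;
* ``layer2`` (increase vs no_effect): plain undersampling to the smaller
  class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DECREASE, INCREASE, NO_EFFECT

IDENTITY_THRESHOLD = 30.0


def _default_aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Percent identity from a global alignment.

    BLOSUM62 with gap open −11 / extend −1; identity is matches over total
    alignment columns (gaps included), the conservative denominator.
    Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = aligner or _default_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


@dataclass
class HomologyClusters:
    """Partition of the protein set into identity-linked components."""

    clusters: list[frozenset[str]]
    identity_threshold: float = IDENTITY_THRESHOLD

    def cluster_of(self, protein_id: str) -> frozenset[str]:
        for c in self.clusters:
            if protein_id in c:
                return c
        raise KeyError(protein_id)

    @property
    def singletons(self) -> list[frozenset[str]]:
        return [c for c in self.clusters if len(c) == 1]


def cluster_proteins(sequences: dict[str, str],
                     threshold: float = IDENTITY_THRESHOLD,
                     aligner=None) -> HomologyClusters:
    """Single-linkage components of the identity-above-threshold graph."""
    if not sequences:
        raise ValueError("no sequences")
    ids = sorted(sequences)
    aligner = aligner or _default_aligner()
    parent = {p: p for p in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if pairwise_identity(sequences[a], sequences[b],
                                 aligner) > threshold:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for p in ids:
        groups.setdefault(find(p), set()).add(p)
    clusters = sorted((frozenset(g) for g in groups.values()),
                      key=lambda c: sorted(c)[0])
    return HomologyClusters(clusters=clusters, identity_threshold=threshold)


@dataclass
class CVPlan:
    """Protein → fold assignment plus the blind-test protein set."""

    fold_of: dict[str, int]
    blind_test: frozenset[str]
    k: int = 5
    seed: int | None = None

    def fold_proteins(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.fold_of.items() if f == fold)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"protein_id": p, "assignment": f"fold{f}"}
                for p, f in sorted(self.fold_of.items())]
        rows += [{"protein_id": p, "assignment": "blind"}
                 for p in sorted(self.blind_test)]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CVPlan":
        df = pd.read_csv(path, sep="\t", dtype=str)
        fold_of, blind = {}, set()
        for _, row in df.iterrows():
            if row["assignment"] == "blind":
                blind.add(row["protein_id"])
            else:
                fold_of[row["protein_id"]] = int(
                    row["assignment"].removeprefix("fold"))
        k = max(fold_of.values()) if fold_of else 0
        return cls(fold_of=fold_of, blind_test=frozenset(blind), k=k)


def make_cv_plan(clusters: HomologyClusters,
                 variant_counts: dict[str, int], k: int = 5,
                 blind_fraction: float = 0.1,
                 seed: int = 0) -> CVPlan:
    """Assign homology clusters to k folds and carve out a blind test set.

    The blind set is drawn (seeded) from singleton clusters only, until it
    holds about ``blind_fraction`` of the variants; the remaining clusters
    are greedily placed, largest first, onto the currently smallest fold.
    """
    total = sum(variant_counts.get(p, 0) for c in clusters.clusters
                for p in c)
    rng = np.random.default_rng(seed)
    blind: set[str] = set()
    if blind_fraction > 0:
        singles = [sorted(c)[0] for c in clusters.singletons]
        order = rng.permutation(len(singles))
        target = blind_fraction * total
        acc = 0
        for idx in order:
            p = singles[idx]
            if acc >= target:
                break
            blind.add(p)
            acc += variant_counts.get(p, 0)
    remaining = [c for c in clusters.clusters if not (c & blind)]
    if len(remaining) < k:
        raise ValueError(
            f"only {len(remaining)} clusters left for {k} folds")

    def cluster_count(c):
        return sum(variant_counts.get(p, 0) for p in c)

    remaining.sort(key=lambda c: (-cluster_count(c), sorted(c)[0]))
    fold_sizes = [0] * k
    fold_of: dict[str, int] = {}
    for c in remaining:
        f = int(np.argmin(fold_sizes))
        fold_sizes[f] += cluster_count(c)
        for p in c:
            fold_of[p] = f + 1
    return CVPlan(fold_of=fold_of, blind_test=frozenset(blind), k=k,
                  seed=seed)


@dataclass
class BalancedSet:
    """Index selection of a balanced binary training set."""

    indices: np.ndarray
    y: np.ndarray               # binary task labels, aligned to indices
    task: str
    resampled: bool = False     # True when a class had to be oversampled
    composition: dict[str, int] = field(default_factory=dict)


def balance_binary(labels, task: str, seed: int = 0) -> BalancedSet:
    """Seeded balanced sampling for one cascade layer.

    ``labels`` are three-class stability labels; returns positional indices
    into them.  layer1 keeps every decrease case and samples its negatives
    half-and-half from increase and no_effect; layer2 undersamples increase
    and no_effect to equal counts.  Undersampling is without replacement;
    only when a side is too small is it resampled with replacement (and
    the result flagged).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    idx = {lab: np.flatnonzero(labels == lab)
           for lab in (INCREASE, NO_EFFECT, DECREASE)}
    for lab, ii in idx.items():
        if len(ii) == 0:
            raise ValueError(f"class {lab!r} is empty")

    def draw(pool: np.ndarray, n: int) -> tuple[np.ndarray, bool]:
        if n <= len(pool):
            return rng.choice(pool, size=n, replace=False), False
        return rng.choice(pool, size=n, replace=True), True

    if task == "layer1":
        pos = idx[DECREASE]
        n_half = len(pos) // 2
        inc, r1 = draw(idx[INCREASE], n_half)
        ne, r2 = draw(idx[NO_EFFECT], len(pos) - n_half)
        chosen = np.concatenate([pos, inc, ne])
        y = np.array([DECREASE] * len(pos)
                     + ["no_decrease"] * (len(inc) + len(ne)))
        resampled = r1 or r2
        composition = {DECREASE: len(pos), INCREASE: len(inc),
                       NO_EFFECT: len(ne)}
    elif task == "layer2":
        n = min(len(idx[INCREASE]), len(idx[NO_EFFECT]))
        inc, _ = draw(idx[INCREASE], n)
        ne, _ = draw(idx[NO_EFFECT], n)
        chosen = np.concatenate([inc, ne])
        y = np.array([INCREASE] * n + [NO_EFFECT] * n)
        resampled = False
        composition = {INCREASE: n, NO_EFFECT: n}
    else:
        raise ValueError(f"unknown task {task!r}")

    order = rng.permutation(len(chosen))
    return BalancedSet(indices=chosen[order], y=y[order], task=task,
                       resampled=resampled, composition=composition)


def folds_from_plan(plan: CVPlan, protein_ids) -> list[tuple[np.ndarray,
                                                             np.ndarray]]:
    """(train_idx, test_idx) row-index pairs for each CV fold.

    ``protein_ids`` is the per-record protein column; blind-test records
    are excluded from every fold.
    """
    protein_ids = np.asarray(protein_ids)
    folds = []
    for f in range(1, plan.k + 1):
        test_prot = set(plan.fold_proteins(f))
        train_prot = {p for p, g in plan.fold_of.items() if g != f}
        test_idx = np.flatnonzero(np.isin(protein_ids, sorted(test_prot)))
        train_idx = np.flatnonzero(np.isin(protein_ids, sorted(train_prot)))
        folds.append((train_idx, test_idx))
    return folds
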