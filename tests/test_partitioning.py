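"""Identity clustering, homology-aware CV plans and class balancing."""

import numpy as np
import pytest

from protstab.dataset import DECREASE, INCREASE, NO_EFFECT
from protstab.partitioning import (CVPlan, balance_binary, cluster_proteins,
                                   folds_from_plan, make_cv_plan,
                                   pairwise_identity)
from protstab.synthetic_fixtures import FixtureSpec, generate_variant_corpus


class TestIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("MKVLWDERTA", "MKVLWDERTA", 100.0),
        ("AAAA", "TTTT", 0.0),
        ("MKVL", "MKIL", 75.0),
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        a, b = "MKVLWDERTAGY", "MKVLWDERTGY"
        assert pairwise_identity(a, b) == pytest.approx(
            pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")


class TestClustering:
    def test_identical_proteins_merge(self):
        seqs = {f"P{i}": "MKVLWDERTAGY" * 3 for i in range(3)}
        clusters = cluster_proteins(seqs)
        assert len(clusters.clusters) == 1

    def test_single_linkage_transitivity(self):
        # A~B and B~C above threshold, A~C far below: one component
        base = "MKVLWDERTAGYSNQPHCIF" * 3
        mid = list(base)
        for i in range(0, len(mid), 2):   # ~50% identity to base
            mid[i] = "A" if mid[i] != "A" else "G"
        far = "W" * len(base)
        seqs = {"A": base, "B": "".join(mid), "C": far}
        # force linkage B~C by making C a variant of B instead
        c = list(mid)
        for i in range(1, len(c), 3):
            c[i] = "P" if c[i] != "P" else "S"
        seqs["C"] = "".join(c)
        clusters = cluster_proteins(seqs, threshold=30.0)
        assert len(clusters.clusters) == 1
        assert clusters.cluster_of("A") == frozenset({"A", "B", "C"})

    def test_unrelated_fixture_sequences_stay_singletons(self):
        corpus = generate_variant_corpus(FixtureSpec(
            n_proteins=8, variants_per_protein=1, seed=13))
        clusters = cluster_proteins(corpus.sequences)
        assert len(clusters.clusters) == 8

    def test_planted_homolog_pair_clusters_together(self):
        corpus = generate_variant_corpus(FixtureSpec(
            n_proteins=5, variants_per_protein=1, n_homolog_pairs=1,
            seed=21))
        clusters = cluster_proteins(corpus.sequences)
        assert clusters.cluster_of("P001") == frozenset({"P001", "P001h"})


@pytest.fixture(scope="module")
def corpus_plan():
    corpus = generate_variant_corpus(FixtureSpec(
        n_proteins=14, variants_per_protein=10, seed=7))
    clusters = cluster_proteins(corpus.sequences)
    counts = corpus.truth.groupby("protein_id").size().to_dict()
    plan = make_cv_plan(clusters, counts, k=5, blind_fraction=0.12,
                        seed=7)
    return corpus, clusters, counts, plan


class TestCVPlan:

    def test_one_cluster_per_fold_when_five_singletons(self):
        seqs = {f"P{i}": s for i, s in enumerate(
            generate_variant_corpus(FixtureSpec(
                n_proteins=5, variants_per_protein=1,
                seed=3)).sequences.values())}
        clusters = cluster_proteins(seqs)
        plan = make_cv_plan(clusters, {p: 1 for p in seqs}, k=5,
                            blind_fraction=0.0, seed=0)
        assert sorted(plan.fold_of.values()) == [1, 2, 3, 4, 5]

    def test_deterministic_under_seed(self, corpus_plan):
        corpus, clusters, counts, plan = corpus_plan
        again = make_cv_plan(clusters, counts, k=5, blind_fraction=0.12,
                             seed=7)
        assert again.fold_of == plan.fold_of
        assert again.blind_test == plan.blind_test

    def test_fold_sizes_within_greedy_bound(self, corpus_plan):
        _, _, counts, plan = corpus_plan
        sizes = [sum(counts[p] for p in plan.fold_proteins(f))
                 for f in range(1, 6)]
        assert max(sizes) - min(sizes) <= max(counts.values())

    def test_no_homology_across_fold_or_blind_boundary(self, corpus_plan):
        corpus, clusters, _, plan = corpus_plan
        thr = clusters.identity_threshold
        assignment = dict(plan.fold_of)
        assignment.update({p: "blind" for p in plan.blind_test})
        ids = sorted(assignment)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if assignment[a] != assignment[b]:
                    assert pairwise_identity(
                        corpus.sequences[a], corpus.sequences[b]) <= thr

    def test_blind_proteins_absent_from_folds(self, corpus_plan):
        *_, plan = corpus_plan
        assert not plan.blind_test & set(plan.fold_of)

    def test_tsv_roundtrip(self, corpus_plan, tmp_path):
        *_, plan = corpus_plan
        path = tmp_path / "plan.tsv"
        plan.to_tsv(path)
        loaded = CVPlan.from_tsv(path)
        assert loaded.fold_of == plan.fold_of
        assert loaded.blind_test == plan.blind_test

    def test_too_few_clusters_is_error(self):
        seqs = {"A": "MKVLWDERTAGY" * 3}
        clusters = cluster_proteins(seqs)
        with pytest.raises(ValueError):
            make_cv_plan(clusters, {"A": 5}, k=5, blind_fraction=0.0)

    def test_folds_from_plan_excludes_blind(self, corpus_plan):
        corpus, _, _, plan = corpus_plan
        folds = folds_from_plan(plan, corpus.truth["protein_id"])
        blind_idx = set(np.flatnonzero(
            corpus.truth["protein_id"].isin(plan.blind_test)))
        for train, test in folds:
            assert not (set(train) | set(test)) & blind_idx
            assert not set(train) & set(test)


class TestBalancing:
    def _labels(self, n_inc, n_ne, n_dec):
        return np.array([INCREASE] * n_inc + [NO_EFFECT] * n_ne
                        + [DECREASE] * n_dec)

    def test_layer2_undersamples_to_smaller_class(self):
        bal = balance_binary(self._labels(233, 467, 864), "layer2", seed=1)
        assert bal.composition == {INCREASE: 233, NO_EFFECT: 233}
        assert len(bal.indices) == 466 and not bal.resampled

    def test_layer1_equal_halves_exact_fit(self):
        bal = balance_binary(self._labels(10, 10, 20), "layer1", seed=1)
        assert bal.composition == {DECREASE: 20, INCREASE: 10,
                                   NO_EFFECT: 10}
        assert (bal.y == DECREASE).sum() == (bal.y == "no_decrease").sum()

    def test_layer1_resamples_small_side_and_flags(self):
        bal = balance_binary(self._labels(3, 50, 40), "layer1", seed=0)
        assert bal.resampled
        assert bal.composition[INCREASE] == 20

    def test_seeded_determinism(self):
        labels = self._labels(30, 60, 120)
        a = balance_binary(labels, "layer1", seed=5)
        b = balance_binary(labels, "layer1", seed=5)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError, match="increase"):
            balance_binary(self._labels(0, 5, 5), "layer1", seed=0)
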