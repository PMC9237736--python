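import numpy as np
import pytest

from progeval import (
    KernelSpec,
    MMDMatrix,
    OntologyDAG,
    embed,
    mmd,
    mmd_matrix,
    mrr,
    mrr_blind,
    per_label_ranks,
    subset_by_label,
)


def matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"T{i}" for i in range(values.shape[0])]
    return MMDMatrix(labels, values)


class TestMMDMatrix:
    def test_gen_equals_real_gives_zero_diagonal(self, corpus):
        ds, _ = corpus
        subs = {t: embed(subset_by_label(ds, t, 20, seed=3)) for t in ds.vocabulary}
        M = mmd_matrix(subs, subs)
        assert np.allclose(np.diag(M.values), 0.0)
        off = M.values[~np.eye(M.d, dtype=bool)]
        assert (off > 0).all()

    def test_entries_match_direct_mmd_calls(self, corpus):
        ds, _ = corpus
        labels = ds.vocabulary[:3]
        real = {t: embed(subset_by_label(ds, t, 15, seed=1)) for t in labels}
        gen = {t: embed(subset_by_label(ds, t, 15, seed=2)) for t in labels}
        M = mmd_matrix(real, gen)
        for i, li in enumerate(M.labels):
            for j, lj in enumerate(M.labels):
                assert M.values[i, j] == mmd(real[lj], gen[li]).mmd

    def test_key_mismatch_lists_difference(self):
        X = embed_from_rows([[1.0, 0.0]])
        with pytest.raises(ValueError, match="T9"):
            mmd_matrix({"T1": X, "T9": X}, {"T1": X, "T2": X})

    def test_save_round_trip(self, tmp_path):
        M = matrix([[0.0, 1.0], [1.0, 0.0]])
        p = tmp_path / "m.tsv"
        M.save(p)
        import pandas as pd

        back = pd.read_csv(p, sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), M.values)


def embed_from_rows(rows):
    from progeval import EmbeddingMatrix

    return EmbeddingMatrix([f"r{i}" for i in range(len(rows))], np.array(rows))


class TestMRR:
    def test_perfect_diagonal_gives_one(self):
        assert mrr(matrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]])) == 1.0

    def test_two_label_rank_example(self):
        # label 0 at rank 1, label 1 at rank 2 -> (1 + 1/2) / 2
        M = matrix([[0.1, 0.9], [0.2, 0.5]])
        assert mrr(M) == pytest.approx(0.75)

    def test_constant_matrix_pessimistic_ties(self):
        M = matrix(np.ones((4, 4)))
        assert mrr(M) == pytest.approx(1 / 4)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = int(rng.integers(2, 8))
            M = matrix(rng.random((d, d)))
            assert 1 / d <= mrr(M) <= 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        V = rng.random((5, 5))
        base = mrr(matrix(V))
        assert mrr(matrix(2.0 * V + 0.1)) == base
        assert mrr(matrix(V**1.7)) == base
        assert mrr(matrix(np.expm1(V))) == base

    def test_per_label_ranks_match_mrr(self):
        rng = np.random.default_rng(2)
        M = matrix(rng.random((6, 6)))
        ranks = per_label_ranks(M)
        assert mrr(M) == pytest.approx(
            np.mean([1 / r for r in ranks.values()])
        )


class TestMRRBlind:
    def test_two_related_labels_always_one(self):
        dag = OntologyDAG({"T0", "T1"}, {("T1", "T0")})
        M = matrix([[0.9, 0.1], [0.1, 0.9]], labels=["T0", "T1"])
        assert mrr_blind(M, dag) == 1.0

    def test_unrelated_competitor_unchanged(self):
        dag = OntologyDAG({"T0", "T1", "T2"}, {("T1", "T0")})
        # T2's diagonal beaten by unrelated T0: still penalized in both
        V = [[0.0, 1, 1], [1, 0.0, 1], [0.1, 1, 0.5]]
        M = matrix(V, labels=["T0", "T1", "T2"])
        assert mrr_blind(M, dag) == mrr(M)

    def test_parent_confusion_forgiven(self):
        dag = OntologyDAG({"P", "C", "U"}, {("C", "P")})
        # child's (row C) diagonal outranked by parent P but not by U
        V = np.array(
            [
                [0.1, 0.9, 0.9],  # P row
                [0.2, 0.5, 0.9],  # C row: P (0.2) beats diagonal (0.5)
                [0.9, 0.9, 0.1],  # U row
            ]
        )
        M = MMDMatrix(["P", "C", "U"], V)
        assert per_label_ranks(M)["C"] == 2
        assert per_label_ranks(M, dag=dag)["C"] == 1
        assert mrr_blind(M, dag) > mrr(M)

    def test_never_below_plain_mrr(self, corpus):
        ds, dag = corpus
        rng = np.random.default_rng(3)
        labels = ds.vocabulary
        for _ in range(10):
            M = MMDMatrix(labels, rng.random((len(labels), len(labels))))
            assert mrr_blind(M, dag) >= mrr(M)
            assert mrr_blind(M, dag, transitive=True) >= mrr_blind(M, dag) - 1e-12

    def test_missing_label_raises(self):
        dag = OntologyDAG({"T0"}, set())
        M = matrix([[0.0, 1], [1, 0.0]], labels=["T0", "TX"])
        with pytest.raises(ValueError, match="TX"):
            mrr_blind(M, dag)


class TestRandomizedNull:
    def test_label_blind_generation_matches_harmonic_expectation(self, corpus):
        """Random label assignment should give mean MRR ~ H_d / d."""
        ds, _ = corpus
        labels = ds.vocabulary
        d = len(labels)
        size = 25
        E = embed(ds.sequences)
        real_means = np.vstack(
            [E.matrix[ds.label_index[t][:size]].mean(axis=0) for t in labels]
        )
        rng = np.random.default_rng(0)
        reps = 200
        vals = np.empty(reps)
        from scipy.spatial.distance import cdist

        for r in range(reps):
            idx = rng.permutation(len(ds))[: d * size].reshape(d, size)
            gen_means = E.matrix[idx].mean(axis=1)
            D = cdist(gen_means, real_means)  # row i: gen-for-label-i
            ranks = 1 + (D < np.diag(D)[:, None]).sum(axis=1)
            vals[r] = (1 / ranks).mean()
        expected = np.sum(1 / np.arange(1, d + 1)) / d
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - expected) < 3 * se + 1e-9

    def test_high_signal_real_vs_real_recovers_labels(self, corpus):
        """Independent draws from the true per-label distributions give MRR >= 0.9."""
        ds, _ = corpus
        leaves = [t for t in ds.vocabulary if ds.label_count(t) < 200]
        real = {t: embed(subset_by_label(ds, t, 40, seed=1)) for t in leaves}
        gen = {
            t: embed(
                [s for s in subset_by_label(ds, t, ds.label_count(t), seed=2)][-40:]
            )
            for t in leaves
        }
        M = mmd_matrix(real, gen)
        assert mrr(M) >= 0.9
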