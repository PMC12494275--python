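import numpy as np
import pandas as pd
import pytest

from hgsoctx.errors import ConfigError, ValidationError
from hgsoctx.io_formats import ExpressionMatrix, GeneSetCollection
from hgsoctx.subtyping import (
    RankMetrics,
    annotate_clusters,
    consensus_nmf,
    extract_metagenes,
    kim_park_scores,
    nmf_factorize,
    quantile_normalize,
    rank_rule_cophenetic_plateau,
    select_features_mad,
    select_rank,
)


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = _matrix([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.tpm, m.tpm)

    def test_mean_quantile_hand_example(self):
        m = _matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.tpm.to_numpy(), expected)

    def test_columns_share_sorted_values(self, rng):
        m = _matrix(rng.uniform(0, 100, (30, 6)))
        out = quantile_normalize(m).tpm.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref)


class TestMADSelection:
    def test_constant_gene_excluded(self):
        m = _matrix([[5, 5, 5, 5], [0, 0, 100, 100]])
        assert "g0" not in select_features_mad(m, mad_threshold=0.0)

    def test_hand_computed_mad(self):
        m = _matrix([[0, 0, 0, 100, 100, 100], [1, 1, 1, 1, 1, 1]])
        # MAD of row 0 is 50 -> passes threshold 30
        assert select_features_mad(m, mad_threshold=30.0) == ["g0"]

    def test_zero_threshold_keeps_all_nonconstant(self, rng):
        m = _matrix(rng.uniform(0, 10, (20, 8)))
        assert len(select_features_mad(m, mad_threshold=0.0)) == 20

    def test_top_n(self, rng):
        m = _matrix(rng.uniform(0, 10, (20, 8)))
        assert len(select_features_mad(m, top_n=5)) == 5


class TestNMF:
    def test_rank_one_exact(self, rng):
        u = rng.uniform(1, 2, 40)
        v = rng.uniform(1, 2, 10)
        V = np.outer(u, v)
        W, H, trace = nmf_factorize(V, k=1, seed=0, max_iter=500)
        rel_err = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
        assert rel_err < 1e-6

    def test_seeded_determinism(self, rng):
        V = rng.uniform(0, 5, (30, 10))
        W1, H1, _ = nmf_factorize(V, 3, seed=42)
        W2, H2, _ = nmf_factorize(V, 3, seed=42)
        assert np.array_equal(W1, W2) and np.array_equal(H1, H2)

    def test_objective_monotone_nonincreasing(self, rng):
        V = rng.uniform(0, 5, (100, 30))
        _, _, trace = nmf_factorize(V, 4, seed=1, max_iter=200, tol=0)
        diffs = np.diff(trace)
        assert (diffs <= 1e-8 * max(trace)).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            nmf_factorize(np.array([[1.0, -1.0], [2.0, 3.0], [1.0, 1.0]]), 1, seed=0)

    def test_matches_sklearn_reconstruction_quality(self, rng):
        """Independent cross-check: our KL multiplicative updates reach a
        reconstruction comparable to sklearn's mu/KL solver."""
        from sklearn.decomposition import NMF as SkNMF

        V = rng.uniform(0.1, 5, (60, 20))
        W, H, trace = nmf_factorize(V, 3, seed=0, max_iter=400, tol=0)
        sk = SkNMF(
            n_components=3, solver="mu", beta_loss="kullback-leibler",
            init="random", random_state=0, max_iter=400, tol=0,
        )
        Wk = sk.fit_transform(V)
        ours = np.linalg.norm(V - W @ H)
        theirs = np.linalg.norm(V - Wk @ sk.components_)
        assert ours <= theirs * 1.05


def _block_matrix(rng, n_genes=60, n_samples=24, k=2, signal=8.0):
    labels = np.repeat(np.arange(k), n_samples // k)
    V = rng.uniform(0.5, 1.5, (n_genes, n_samples))
    per = n_genes // k
    for j in range(k):
        V[j * per : (j + 1) * per, labels == j] += signal
    return V, labels


class TestConsensus:
    def test_planted_blocks_high_cophenetic(self, rng):
        V, labels = _block_matrix(rng)
        metrics, consensus = consensus_nmf(V, k_range=[2], n_runs=5, seed=0)
        c = consensus[2]
        assert metrics[2]["cophenetic"] > 0.99
        off = c[np.triu_indices_from(c, 1)]
        assert np.all((off < 0.05) | (off > 0.95))

    def test_dispersion_higher_on_structure_than_noise(self, rng):
        structured = []
        noisy = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            V, _ = _block_matrix(r)
            m_s, _ = consensus_nmf(V, k_range=[2], n_runs=5, seed=seed)
            m_n, _ = consensus_nmf(
                r.uniform(0.5, 1.5, V.shape), k_range=[2], n_runs=5, seed=seed
            )
            structured.append(m_s[2]["dispersion"])
            noisy.append(m_n[2]["dispersion"])
        assert np.mean(structured) > np.mean(noisy)

    def test_consensus_diagonal_and_symmetry(self, rng):
        V = rng.uniform(0, 3, (40, 16))
        _, consensus = consensus_nmf(V, k_range=[2, 3], n_runs=4, seed=0)
        for c in consensus.values():
            assert np.allclose(np.diag(c), 1.0)
            assert np.allclose(c, c.T)
            assert c.min() >= 0 and c.max() <= 1

    def test_too_few_runs_rejected(self, rng):
        with pytest.raises(ConfigError):
            consensus_nmf(rng.uniform(0, 1, (10, 6)), k_range=[2], n_runs=1, seed=0)


class TestRankSelection:
    def _metrics(self, coph, sil):
        ks = list(range(2, 2 + len(coph)))
        return RankMetrics(
            pd.DataFrame(
                {"k": ks, "cophenetic": coph, "silhouette": sil,
                 "dispersion": [0.5] * len(ks), "sparseness_w": [0.5] * len(ks),
                 "sparseness_h": [0.5] * len(ks)}
            ).set_index("k")
        )

    def test_plateau_rule_trace(self):
        # flat at 1.0 for k=2..4 then a clear drop: the plateau rule picks 4
        m = self._metrics([1.0, 1.0, 1.0, 0.8, 0.7], [0.5, 0.5, 0.5, 0.4, 0.3])
        assert select_rank(m, rule=rank_rule_cophenetic_plateau) == 4

    def test_balanced_rule_prefers_joint_optimum(self):
        m = self._metrics([0.99, 1.0, 0.995, 0.99, 0.98], [0.5, 0.9, 0.6, 0.5, 0.4])
        assert select_rank(m) == 3

    def test_single_k(self):
        m = self._metrics([0.9], [0.5])
        assert select_rank(m) == 2
        assert select_rank(m, rule=rank_rule_cophenetic_plateau) == 2

    def test_empty_metrics_rejected(self):
        with pytest.raises(ConfigError):
            select_rank(RankMetrics(pd.DataFrame(columns=["cophenetic", "silhouette"])))


class TestMetagenes:
    def test_pure_row_maximal_score(self):
        W = np.array([[10.0, 0, 0, 0], [2.5, 2.5, 2.5, 2.5], [0.1, 0.2, 0.3, 0.4]])
        scores = kim_park_scores(W)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)
        assert scores[0] > scores[2] > scores[1]

    def test_selection_matches_formula_oracle(self, rng):
        W = rng.uniform(0, 1, (200, 4)) ** 3
        genes = [f"g{i}" for i in range(200)]
        result = extract_metagenes(W, genes, n_sd=1.0)
        # independent recomputation
        p = W / W.sum(axis=1, keepdims=True)
        ent = np.array(
            [sum(q * np.log(q) for q in row if q > 0) for row in p]
        )
        score = 1 + ent / np.log(4)
        thr = score.mean() + 1.0 * score.std()
        expected = {
            g: int(W[i].argmax())
            for i, g in enumerate(genes)
            if score[i] > thr
        }
        got = {g: cl for cl, gs in result.items() for g in gs}
        assert got == expected

    def test_metagene_sets_disjoint(self, rng):
        W = rng.uniform(0, 1, (100, 3)) ** 2
        result = extract_metagenes(W, [f"g{i}" for i in range(100)], n_sd=0.5)
        all_genes = [g for gs in result.values() for g in gs]
        assert len(all_genes) == len(set(all_genes))


class TestAnnotation:
    def test_exact_hypergeometric_p(self):
        universe = [f"g{i}" for i in range(20)]
        gene_sets = GeneSetCollection(sets={"SET": set(universe[:5])})
        ann = annotate_clusters({1: universe[:5]}, gene_sets, universe, alpha=0.5)
        row = ann[ann["gene_set"] == "SET"].iloc[0]
        assert row["p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        gene_sets = GeneSetCollection(sets={"SET": set(universe[10:15])})
        ann = annotate_clusters({1: universe[:5]}, gene_sets, universe, alpha=1.1)
        assert ann[ann["gene_set"] == "SET"].iloc[0]["p"] == pytest.approx(1.0)

    def test_bh_adjustment_hand_example(self):
        from hgsoctx.cistrans import bh_fdr

        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_query_outside_universe_rejected(self):
        gene_sets = GeneSetCollection(sets={"SET": {"g1"}})
        with pytest.raises(ValidationError):
            annotate_clusters({1: ["zzz"]}, gene_sets, ["g1", "g2"])
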