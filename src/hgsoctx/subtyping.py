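"""Consensus non-negative matrix factorization (NMF) molecular subtyping.

The stage mirrors TCGA-style transcriptome subtyping: quantile-normalize
the expression matrix, select high-variability genes by median absolute
deviation (MAD), factorize the non-negative matrix with Kullback-Leibler
multiplicative updates over a range of ranks k, build a consensus matrix
from repeated random restarts per k, choose k from consensus stability
metrics (cophenetic coefficient, dispersion, sparseness, silhouette),
assign each sample to the factor with the largest H loading, and extract
cluster-specific metagenes with the Kim-Park feature score. Metagene lists
are annotated against gene-set collections by hypergeometric
over-representation with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.metrics import silhouette_score

from .cistrans import bh_fdr
from .errors import ConfigError, ValidationError
from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Preprocessing


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean quantile vector (ties averaged)."""
    df = matrix.tpm
    if df.shape[1] < 2:
        raise ValidationError("quantile normalization needs >=2 samples")
    ranks = df.rank(axis=0, method="average")
    mean_quantiles = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    # value for (possibly fractional) rank r by linear interpolation
    grid = np.arange(1, df.shape[0] + 1, dtype=float)
    out = np.empty_like(df.to_numpy(), dtype=float)
    for j in range(df.shape[1]):
        out[:, j] = np.interp(ranks.iloc[:, j].to_numpy(), grid, mean_quantiles)
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def select_features_mad(
    matrix: ExpressionMatrix,
    mad_threshold: float = 30.0,
    log_scale: bool = False,
    top_n: int | None = None,
) -> list[str]:
    """Genes whose MAD across samples exceeds ``mad_threshold``
    (MAD = median |x - median(x)|, unscaled).

    ``log_scale`` computes the MAD on log2(TPM+1); ``top_n`` instead returns
    the n genes with the largest MAD (the threshold is ignored).
    """
    data = matrix.log2() if log_scale else matrix.tpm
    med = data.median(axis=1)
    mad = (data.sub(med, axis=0)).abs().median(axis=1)
    if top_n is not None:
        return mad.sort_values(ascending=False).head(top_n).index.tolist()
    return mad[mad > mad_threshold].index.tolist()


# ---------------------------------------------------------------------------
# NMF with Kullback-Leibler multiplicative updates


def nmf_factorize(
    matrix: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Factorize a non-negative matrix V ~ W H by multiplicative updates
    minimizing the generalized Kullback-Leibler divergence (Brunet variant).

    Returns (W, H, objective trace). The objective is non-increasing per
    iteration; iteration stops when the relative objective change drops
    below ``tol`` or ``max_iter`` is reached.
    """
    V = np.asarray(matrix, dtype=float)
    if (V < 0).any():
        raise ValidationError("NMF input must be non-negative")
    n_genes, n_samples = V.shape
    if not 1 <= k < min(n_genes, n_samples):
        raise ConfigError(f"rank k={k} out of range for shape {V.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.0, 1.0, (n_genes, k)) * scale + 1e-4
    H = rng.uniform(0.0, 1.0, (k, n_samples)) * scale + 1e-4
    eps = np.finfo(float).tiny

    def objective() -> float:
        WH = W @ H
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(V > 0, V * np.log(np.maximum(V, eps) / np.maximum(WH, eps)), 0.0)
        return float((ratio - V + WH).sum())

    trace = [objective()]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, eps)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = np.maximum(W @ H, eps)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        trace.append(objective())
        prev, cur = trace[-2], trace[-1]
        if prev > 0 and abs(prev - cur) / max(abs(prev), eps) < tol:
            break
    return W, H, trace


def _hoyer_sparseness(x: np.ndarray) -> float:
    """Hoyer sparseness of a vector: (sqrt(n) - l1/l2) / (sqrt(n) - 1)."""
    n = x.size
    l2 = np.linalg.norm(x)
    if l2 == 0 or n == 1:
        return 0.0
    return float((np.sqrt(n) - np.abs(x).sum() / l2) / (np.sqrt(n) - 1))


# ---------------------------------------------------------------------------
# Consensus over restarts and rank selection


@dataclass
class RankMetrics:
    """Per-rank consensus quality metrics."""

    table: pd.DataFrame  # index k; columns cophenetic, dispersion, sparseness_w, sparseness_h, silhouette

    def __getitem__(self, k: int) -> pd.Series:
        return self.table.loc[k]

    @property
    def k_values(self) -> list[int]:
        return self.table.index.tolist()


def _consensus_metrics(consensus: np.ndarray, k: int) -> dict[str, float]:
    n = consensus.shape[0]
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = hierarchy.average(condensed)
    coph = hierarchy.cophenet(tree, condensed)[0]
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    if np.unique(labels).size > 1 and condensed.max() > 0:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = 1.0 if condensed.max() == 0 else 0.0
    dispersion = float(np.mean(4.0 * (consensus - 0.5) ** 2))
    return {
        "cophenetic": float(coph) if np.isfinite(coph) else 1.0,
        "dispersion": dispersion,
        "silhouette": sil,
        "_labels": labels,
    }


def consensus_nmf(
    matrix: np.ndarray,
    k_range: Sequence[int] = range(2, 7),
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> tuple[RankMetrics, dict[int, np.ndarray]]:
    """Repeated-restart NMF per rank; consensus[i, j] is the fraction of runs
    in which samples i and j share the argmax factor."""
    if n_runs < 2:
        raise ConfigError("consensus NMF needs n_runs >= 2")
    V = np.asarray(matrix, dtype=float)
    n_samples = V.shape[1]
    run_seeds = np.random.SeedSequence(seed).generate_state(len(list(k_range)) * n_runs)
    consensus_by_k: dict[int, np.ndarray] = {}
    rows = []
    for ki, k in enumerate(k_range):
        conn = np.zeros((n_samples, n_samples))
        sp_w = []
        sp_h = []
        for r in range(n_runs):
            run_seed = int(run_seeds[ki * n_runs + r]) % (2**31 - 1)
            W, H, _ = nmf_factorize(V, k, seed=run_seed, max_iter=max_iter, tol=tol)
            labels = H.argmax(axis=0)
            conn += labels[:, None] == labels[None, :]
            sp_w.append(np.mean([_hoyer_sparseness(W[:, j]) for j in range(k)]))
            sp_h.append(np.mean([_hoyer_sparseness(H[j, :]) for j in range(k)]))
        consensus = conn / n_runs
        consensus_by_k[k] = consensus
        metrics = _consensus_metrics(consensus, k)
        rows.append(
            {
                "k": k,
                "cophenetic": metrics["cophenetic"],
                "dispersion": metrics["dispersion"],
                "sparseness_w": float(np.mean(sp_w)),
                "sparseness_h": float(np.mean(sp_h)),
                "silhouette": metrics["silhouette"],
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    return RankMetrics(table), consensus_by_k


def rank_rule_balanced(table: pd.DataFrame, tol: float = 0.01) -> int:
    """Pick the largest k whose cophenetic + silhouette is within ``tol`` of
    the optimum.

    The combined score balances consensus stability against cluster
    interpretability and stays discriminating when the cophenetic
    coefficient alone saturates near 1 for every k at or below the true
    rank. Ranks below the true one can tie with it almost exactly (a
    consistent merge of two real clusters is also perfectly stable), while
    ranks above lose silhouette sharply; taking the largest k inside the
    tolerance therefore resolves the maximum structure the consensus
    supports."""
    score = table["cophenetic"] + table["silhouette"]
    return int(score[score >= score.max() - tol].index.max())


def rank_rule_cophenetic_plateau(
    table: pd.DataFrame, slack: float = 0.01
) -> int:
    """Largest k whose cophenetic coefficient is within ``slack`` of the
    maximum and whose silhouette is positive."""
    best = table["cophenetic"].max()
    ok = table[(table["cophenetic"] >= best - slack) & (table["silhouette"] > 0)]
    if ok.empty:
        ok = table[table["cophenetic"] >= best - slack]
    return int(ok.index.max())


def select_rank(
    metrics: RankMetrics,
    rule: Callable[[pd.DataFrame], int] | None = None,
) -> int:
    """Choose the factorization rank from consensus metrics.

    The default rule is :func:`rank_rule_balanced`;
    :func:`rank_rule_cophenetic_plateau` or any callable on the metrics
    table can be plugged in instead."""
    table = metrics.table
    if table.empty:
        raise ConfigError("empty rank metrics")
    if rule is None:
        rule = rank_rule_balanced
    return rule(table)


# ---------------------------------------------------------------------------
# Metagenes (Kim-Park feature score)


def kim_park_scores(W: np.ndarray) -> np.ndarray:
    """Feature score 1 + (1/log k) * sum_q p(g,q) log p(g,q) with p the
    row-normalized basis loadings; 1 for a pure row, 0 for a uniform row.
    All-zero rows score NaN."""
    W = np.asarray(W, dtype=float)
    k = W.shape[1]
    rowsum = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = W / rowsum
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        score = 1.0 + plogp.sum(axis=1) / np.log(k)
    score[rowsum.ravel() == 0] = np.nan
    return score


def extract_metagenes(
    W: np.ndarray,
    gene_ids: Sequence[str],
    n_sd: float = 3.0,
) -> dict[int, list[str]]:
    """Assign each selected gene to its argmax factor; keep genes whose
    Kim-Park score exceeds mean + ``n_sd`` * sd of all finite scores."""
    scores = kim_park_scores(W)
    finite = np.isfinite(scores)
    if (~finite).any():
        logger.info("extract_metagenes: %d all-zero gene rows excluded", int((~finite).sum()))
    threshold = scores[finite].mean() + n_sd * scores[finite].std()
    keep = finite & (scores > threshold)
    assign = np.asarray(W).argmax(axis=1)
    out: dict[int, list[str]] = {q: [] for q in range(np.asarray(W).shape[1])}
    for g, q, flag in zip(gene_ids, assign, keep):
        if flag:
            out[int(q)].append(g)
    return out


# ---------------------------------------------------------------------------
# Cluster annotation


def annotate_clusters(
    metagenes: Mapping[int, Sequence[str]],
    gene_sets: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.01,
    min_report: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each cluster's
    metagene list, BH-adjusted within cluster. All sets with adjusted
    p < alpha are reported; when fewer than ``min_report`` pass, the
    top-ranked sets are retained with ``significant`` False."""
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty annotation universe")
    N = len(universe_set)
    frames = []
    for cluster, genes in metagenes.items():
        query = set(genes) & universe_set
        if set(genes) - universe_set:
            raise ValidationError(
                f"cluster {cluster} metagenes outside the universe: "
                f"{sorted(set(genes) - universe_set)[:5]}"
            )
        rows = []
        for name, members in gene_sets.items():
            K = len(members & universe_set)
            if K == 0:
                continue
            overlap = len(query & members)
            p = float(hypergeom.sf(overlap - 1, N, K, len(query))) if query else 1.0
            rows.append({"cluster": cluster, "gene_set": name, "overlap": overlap, "p": p})
        if not rows:
            continue
        sub = pd.DataFrame(rows)
        sub["adj_p"] = bh_fdr(sub["p"].to_numpy())
        sub["significant"] = sub["adj_p"] < alpha
        sub = sub.sort_values(["adj_p", "gene_set"]).reset_index(drop=True)
        keep = sub["significant"] | (sub.index < min_report)
        frames.append(sub[keep])
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene_set", "overlap", "p", "adj_p", "significant"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# High-level model


@dataclass
class SubtypeModel:
    """Fitted consensus-NMF subtyping result."""

    selected_genes: list[str]
    k_selected: int
    W: pd.DataFrame                  # genes x k
    H: pd.DataFrame                  # k x samples
    consensus: dict[int, np.ndarray]
    metrics: RankMetrics
    cluster_label: pd.Series         # sample -> 1..k
    metagenes: dict[int, list[str]]

    def summary(self) -> pd.DataFrame:
        return self.metrics.table


def fit_subtypes(
    matrix: ExpressionMatrix,
    k_range: Sequence[int] = range(2, 7),
    n_runs: int = 10,
    seed: int = 0,
    mad_threshold: float | None = None,
    top_n_genes: int | None = 500,
    mad_log_scale: bool = True,
    nmf_log_scale: bool = False,
    max_iter: int = 300,
    rank_rule: Callable[[pd.DataFrame], int] | None = None,
) -> SubtypeModel:
    """End-to-end subtyping: quantile normalization, MAD gene selection,
    consensus NMF over ``k_range``, rank selection, a final factorization at
    the chosen rank, argmax-H labels and Kim-Park metagenes.

    Gene selection uses ``mad_threshold`` when given, otherwise the
    ``top_n_genes`` genes with the largest MAD (on log2(TPM+1) by default).
    The NMF input is the quantile-normalized non-negative matrix itself
    (``nmf_log_scale`` switches to log2(TPM+1); no z-scoring, which would
    break non-negativity).
    """
    normalized = quantile_normalize(matrix)
    if mad_threshold is not None:
        genes = select_features_mad(normalized, mad_threshold, log_scale=mad_log_scale)
    else:
        genes = select_features_mad(normalized, top_n=top_n_genes, log_scale=mad_log_scale)
    if len(genes) < 10:
        raise ValidationError(f"only {len(genes)} genes pass the MAD filter")
    sub = normalized.subset_genes(genes)
    V = sub.log2().to_numpy() if nmf_log_scale else sub.tpm.to_numpy()

    metrics, consensus = consensus_nmf(
        V, k_range=k_range, n_runs=n_runs, seed=seed, max_iter=max_iter
    )
    k = select_rank(metrics, rule=rank_rule)
    final_seed = int(np.random.SeedSequence(seed).generate_state(1)[0]) % (2**31 - 1)
    W, H, _ = nmf_factorize(V, k, seed=final_seed, max_iter=max_iter)
    labels = pd.Series(H.argmax(axis=0) + 1, index=sub.sample_ids, name="cluster")
    metagenes = extract_metagenes(W, genes)
    return SubtypeModel(
        selected_genes=genes,
        k_selected=k,
        W=pd.DataFrame(W, index=genes, columns=[f"factor_{q + 1}" for q in range(k)]),
        H=pd.DataFrame(H, index=[f"factor_{q + 1}" for q in range(k)], columns=sub.sample_ids),
        consensus=consensus,
        metrics=metrics,
        cluster_label=labels,
        metagenes={q + 1: gs for q, gs in metagenes.items()},
    )
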