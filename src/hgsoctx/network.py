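"""Gene co-expression network construction and pathway-cluster detection.

Candidate genes are pre-filtered by variance of log2(TPM+1); edges connect
gene pairs with Pearson correlation strictly above a threshold (0.55 by
default); isolated genes are dropped. Node clusters come from complete-
linkage agglomerative clustering on the distance 1 - r (non-adjacent pairs
at distance 2), cut at a fixed cluster count (ten by default). Per-subtype
log2 fold changes provide the cluster overlays.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError, ValidationError
from .io_formats import ExpressionMatrix


@dataclass
class CorrelationNetwork:
    graph: nx.Graph                       # nodes = gene ids, edge attr "r"
    correlations: pd.DataFrame            # node x node Pearson r
    node_cluster: pd.Series | None = None
    node_fold_change: pd.DataFrame | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]

    def write_edge_list(self, path) -> None:
        rows = [{"gene_i": u, "gene_j": v, "r": r} for u, v, r in self.edges]
        pd.DataFrame(rows, columns=["gene_i", "gene_j", "r"]).to_csv(
            path, sep="\t", index=False
        )

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.node_cluster is not None:
            nx.set_node_attributes(g, self.node_cluster.to_dict(), "cluster")
        nx.write_graphml(g, path)


def build_network(
    expr: ExpressionMatrix,
    variance_quantile: float = 0.75,
    r_min: float = 0.55,
) -> CorrelationNetwork:
    """Build the co-expression graph over the top ``1 - variance_quantile``
    fraction of genes by log-scale variance, keeping edges with r > r_min."""
    if not 0 < r_min < 1:
        raise ConfigError(f"r_min must be in (0, 1), got {r_min}")
    if expr.shape[1] < 3:
        raise ValidationError("build_network needs >=3 samples")
    logx = expr.log2()
    variances = logx.var(axis=1)
    cutoff = variances.quantile(variance_quantile)
    candidates = variances[variances >= cutoff].index.tolist()
    sub = logx.loc[candidates]
    corr = pd.DataFrame(
        np.corrcoef(sub.to_numpy()), index=candidates, columns=candidates
    )
    graph = nx.Graph()
    arr = corr.to_numpy()
    n = len(candidates)
    iu, ju = np.triu_indices(n, k=1)
    keep = arr[iu, ju] > r_min
    for i, j in zip(iu[keep], ju[keep]):
        graph.add_edge(candidates[i], candidates[j], r=float(arr[i, j]))
    # isolated candidates never enter the graph; restrict corr to graph nodes
    nodes = list(graph.nodes)
    return CorrelationNetwork(graph=graph, correlations=corr.loc[nodes, nodes])


def cluster_network(network: CorrelationNetwork, n_clusters: int = 10) -> pd.Series:
    """Complete-linkage clustering on 1 - r (non-edges at distance 2)."""
    nodes = network.nodes
    if n_clusters > len(nodes):
        raise ConfigError(f"n_clusters={n_clusters} exceeds {len(nodes)} nodes")
    r = network.correlations.loc[nodes, nodes].to_numpy().copy()
    adj = nx.to_numpy_array(network.graph, nodelist=nodes) != 0
    dist = np.where(adj, 1.0 - r, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = hierarchy.complete(condensed)
    # cut_tree rather than fcluster(maxclust): the constant non-edge
    # distance ties every between-component merge, which maxclust cannot
    # split into a fixed cluster count
    labels = hierarchy.cut_tree(tree, n_clusters=n_clusters).ravel() + 1
    result = pd.Series(labels, index=nodes, name="cluster")
    network.node_cluster = result
    return result


def cluster_fold_changes(
    expr: ExpressionMatrix, subtype_labels: pd.Series
) -> pd.DataFrame:
    """Per gene and subtype s: log2(mean TPM in s + 1) - log2(mean TPM elsewhere + 1)."""
    labels = subtype_labels.reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValidationError("subtype labels missing for some samples")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValidationError("cluster_fold_changes needs >=2 subtypes")
    out = {}
    for s in groups:
        inside = labels[labels == s].index
        outside = labels[labels != s].index
        if len(inside) == 0 or len(outside) == 0:
            raise ValidationError(f"subtype {s!r} has an empty group")
        mean_in = expr.tpm[inside].mean(axis=1)
        mean_out = expr.tpm[outside].mean(axis=1)
        out[s] = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
    return pd.DataFrame(out, index=expr.gene_ids)
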