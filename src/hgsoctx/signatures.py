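"""Single-sample gene-set scoring and group-comparison statistics.

``ssgsea_score`` is a rank-based single-sample enrichment statistic
(ssGSEA-style): genes are ranked by expression within the sample and the
score accumulates the gap between the weighted in-set empirical CDF and the
out-of-set CDF while walking down the ranking. Being rank-based, the score
is invariant to any strictly monotone transform of the expression vector
and comparable only within a run.

Composite stromal/immune scores follow the ESTIMATE construction: each is
a single-sample enrichment score of the corresponding signature and the
combined score is their sum (an inverse proxy of tumor purity).

The module also houses the shared statistical engines: one-way ANOVA with
Tukey HSD and a compact letter display, a Welch-t differential expression
engine on log2(TPM+1), and the hypergeometric over-representation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cistrans import bh_fdr
from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Single-sample enrichment


def ssgsea_score(
    expression: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 0.25,
) -> float:
    """Rank-based single-sample enrichment score of ``gene_set``.

    Genes are sorted by decreasing expression (ties broken by gene id so the
    score is deterministic); walking down the list, the score sums the
    difference between the in-set ECDF weighted by |rank statistic| **
    ``weight_exponent`` and the unweighted out-of-set ECDF. The rank
    statistic of the top gene is n, of the bottom gene 1.
    """
    members = set(gene_set) & set(expression.index)
    if not members:
        raise ValidationError("gene set has no member measured in the expression vector")
    n = len(expression)
    order = sorted(
        expression.index, key=lambda g: (-float(expression[g]), g)
    )
    rank_stat = np.arange(n, 0, -1, dtype=float)  # n at the top of the list
    in_set = np.array([g in members for g in order])
    weights = np.abs(rank_stat) ** weight_exponent
    w_in = np.where(in_set, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    n_out = n - len(members)
    if n_out == 0:
        return float(np.sum(p_in))  # degenerate: everything in the set
    p_out = np.cumsum(~in_set) / n_out
    return float(np.sum(p_in - p_out))


def score_gene_sets(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection | Mapping[str, set[str]],
    weight_exponent: float = 0.25,
) -> pd.DataFrame:
    """Enrichment score matrix: gene sets x samples."""
    items = gene_sets.items()
    out = {}
    for sample in expr.sample_ids:
        col = expr.tpm[sample]
        out[sample] = {
            name: ssgsea_score(col, members, weight_exponent) for name, members in items
        }
    return pd.DataFrame(out)


@dataclass
class CompositeScores:
    stromal: pd.Series
    immune: pd.Series

    @property
    def estimate(self) -> pd.Series:
        """Combined score: stromal + immune, exactly."""
        return self.stromal + self.immune

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stromal_score": self.stromal, "immune_score": self.immune,
             "estimate_score": self.estimate}
        )


def composite_scores(
    expr: ExpressionMatrix,
    stromal_set: Iterable[str],
    immune_set: Iterable[str],
) -> CompositeScores:
    """Per-sample stromal and immune enrichment scores and their sum."""
    scores = score_gene_sets(
        expr, {"stromal": set(stromal_set), "immune": set(immune_set)}
    )
    return CompositeScores(stromal=scores.loc["stromal"], immune=scores.loc["immune"])


# ---------------------------------------------------------------------------
# Group comparison: ANOVA + Tukey HSD + compact letter display


def _compact_letters(groups: Sequence[str], different: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups not significantly
    different share at least one letter."""
    letter_sets: list[set[str]] = [set(groups)]
    for pair in different:
        a, b = tuple(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets = [s for s in letter_sets if s]
    # absorb sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < other or (s == other and i > j) for j, other in enumerate(letter_sets))
    ]
    letter_sets.sort(key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in sorted(s):
            letters[g] += ch
    return letters


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    tukey: pd.DataFrame


def compare_groups_anova(
    scores: pd.Series,
    group_labels: pd.Series,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA across groups followed by Tukey HSD at ``alpha`` and a
    compact letter display (groups sharing a letter are not significantly
    different)."""
    labels = group_labels.reindex(scores.index)
    if labels.isna().any():
        raise ValidationError("group labels missing for some samples")
    labels = labels.astype(str)
    groups = sorted(labels.unique())
    arrays = [scores[labels == g].to_numpy(dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs >=2 members")
    f_stat, p = stats.f_oneway(*arrays)
    if all(np.allclose(a, arrays[0].mean()) for a in arrays):
        # degenerate identical data: no differences
        return AnovaResult(0.0, 1.0, {g: "a" for g in groups}, pd.DataFrame())
    tk = pairwise_tukeyhsd(
        scores.to_numpy(dtype=float), labels.to_numpy(), alpha=alpha
    )
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    different = {
        frozenset((str(row["group1"]), str(row["group2"])))
        for _, row in tukey.iterrows()
        if bool(row["reject"])
    }
    letters = _compact_letters(groups, different)
    return AnovaResult(float(f_stat), float(p), letters, tukey)


# ---------------------------------------------------------------------------
# Differential expression (Welch t on log2(TPM+1))


def deg_analysis(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    deg_alpha: float = 0.01,
    deg_lfc: float = 1.5,
) -> pd.DataFrame:
    """Per-gene Welch t-test of group A vs B on log2(TPM+1).

    log2fc is mean(A) - mean(B) on the log scale; q is BH-adjusted;
    ``significant`` requires q < deg_alpha and |log2fc| > deg_lfc. Genes with
    zero variance in both groups get p = 1 (logged).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("both groups need >=2 samples")
    logx = expr.log2()
    xa = logx[list(group_a)].to_numpy()
    xb = logx[list(group_b)].to_numpy()
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    flat = np.isnan(p)
    if flat.any():
        logger.info("deg_analysis: %d zero-variance genes set to p=1", int(flat.sum()))
        p = np.where(flat, 1.0, p)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": (q < deg_alpha) & (np.abs(log2fc) > deg_lfc),
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# Over-representation


def ora_test(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Hypergeometric upper-tail probability of observing at least the
    actual overlap between ``query`` and ``gene_set`` within ``universe``."""
    universe = set(universe)
    query = set(query)
    if query - universe:
        raise ValidationError(
            f"query genes outside the universe: {sorted(query - universe)[:5]}"
        )
    members = set(gene_set) & universe
    overlap = len(query & members)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
    return overlap, p
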