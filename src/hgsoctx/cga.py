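"""Cancer-germline antigen (CGA) calling.

CGAs are genes silent in somatic tissues but expressed in germline tissue
(testis, ovary) and in some tumors, making them candidate immunotherapy
targets. The caller takes a candidate list, restricts it to genes whose
expression in a germline-tissue reference matrix is confined to the
germline tissues, and flags (sample, gene) pairs whose cohort expression
exceeds the per-gene mean by more than three standard deviations on the
log2(TPM+1) scale. A sample is CGA-positive when any candidate gene is
flagged; per-subtype positive proportions and a CGA+/CGA- differential
expression contrast summarize the calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .signatures import deg_analysis

logger = logging.getLogger(__name__)


@dataclass
class GermlineRestriction:
    restricted: dict[str, bool]
    somatic_tpm_max: float
    germline_tissues: tuple[str, ...]

    @property
    def restricted_genes(self) -> list[str]:
        return [g for g, ok in self.restricted.items() if ok]


def filter_germline_restricted(
    tissue_ref: pd.DataFrame,
    candidate_genes: Sequence[str],
    germline_tissues: Iterable[str] = ("testis", "ovary"),
    somatic_tpm_max: float = 1.0,
) -> GermlineRestriction:
    """A gene is germline-restricted iff its TPM is below ``somatic_tpm_max``
    in every non-germline tissue (no constraint on germline tissues).
    Candidates absent from the reference are excluded and logged."""
    germline = tuple(germline_tissues)
    somatic = [t for t in tissue_ref.index if t not in germline]
    if not somatic:
        raise ValidationError("tissue reference has no somatic tissues")
    restricted: dict[str, bool] = {}
    missing = []
    for g in candidate_genes:
        if g not in tissue_ref.columns:
            missing.append(g)
            continue
        restricted[g] = bool((tissue_ref.loc[somatic, g] < somatic_tpm_max).all())
    if missing:
        logger.info(
            "filter_germline_restricted: %d candidates absent from reference", len(missing)
        )
    return GermlineRestriction(
        restricted=restricted,
        somatic_tpm_max=somatic_tpm_max,
        germline_tissues=germline,
    )


def detect_outliers(
    expr: ExpressionMatrix,
    candidate_genes: Sequence[str],
    z_threshold: float = 3.0,
    log_scale: bool = True,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Boolean flags (genes x samples): sample s is an outlier for gene g iff
    x_gs > mean_g + z_threshold * sd_g across the cohort.

    Statistics are computed on log2(TPM+1) by default; with
    ``leave_one_out`` the mean/sd exclude the candidate sample itself.
    Zero-variance genes are skipped (all False) and logged.
    """
    missing = [g for g in candidate_genes if g not in expr.tpm.index]
    if missing:
        raise ValidationError(f"candidate genes absent from expression: {missing[:5]}")
    data = expr.log2() if log_scale else expr.tpm
    x = data.loc[list(candidate_genes)].to_numpy(dtype=float)
    n = x.shape[1]
    if leave_one_out:
        total = x.sum(axis=1, keepdims=True)
        mean_loo = (total - x) / (n - 1)
        sq = (x**2).sum(axis=1, keepdims=True)
        var_loo = (sq - x**2) / (n - 1) - mean_loo**2
        var_loo = np.clip(var_loo * (n - 1) / (n - 2), 0, None)
        sd = np.sqrt(var_loo)
        flags = x > mean_loo + z_threshold * sd
        skipped = (sd == 0).all(axis=1)
        flags[skipped, :] = False
    else:
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        skipped = (sd == 0).ravel()
        with np.errstate(invalid="ignore"):
            flags = x > mean + z_threshold * sd
        flags[skipped, :] = False
    if skipped.any():
        logger.info("detect_outliers: %d zero-variance genes skipped", int(skipped.sum()))
    return pd.DataFrame(flags, index=list(candidate_genes), columns=expr.sample_ids)


@dataclass
class CGACallSet:
    candidate_genes: list[str]
    outlier_flags: pd.DataFrame  # genes x samples, boolean

    @property
    def sample_positive(self) -> pd.Series:
        """A sample is positive when any candidate gene is flagged."""
        return self.outlier_flags.any(axis=0)

    @property
    def positive_fraction(self) -> float:
        return float(self.sample_positive.mean())


def call_cga(
    expr: ExpressionMatrix,
    candidate_genes: Sequence[str],
    tissue_ref: pd.DataFrame | None = None,
    germline_tissues: Iterable[str] = ("testis", "ovary"),
    somatic_tpm_max: float = 1.0,
    z_threshold: float = 3.0,
) -> CGACallSet:
    """Full CGA calling: germline restriction (when a tissue reference is
    supplied) followed by 3-SD outlier detection."""
    genes = list(candidate_genes)
    if tissue_ref is not None:
        restriction = filter_germline_restricted(
            tissue_ref, genes, germline_tissues, somatic_tpm_max
        )
        genes = restriction.restricted_genes
    if not genes:
        raise ValidationError("no germline-restricted candidate genes to test")
    flags = detect_outliers(expr, genes, z_threshold=z_threshold)
    return CGACallSet(candidate_genes=genes, outlier_flags=flags)


def summarize_by_subtype(
    callset: CGACallSet, subtype_labels: pd.Series
) -> pd.Series:
    """Fraction of CGA-positive samples per subtype."""
    positive = callset.sample_positive
    labels = subtype_labels.reindex(positive.index)
    if labels.isna().any():
        missing = positive.index[labels.isna()].tolist()
        raise ValidationError(f"unlabeled samples: {missing[:5]}")
    return positive.groupby(labels).mean()


def contrast_cga_groups(
    expr: ExpressionMatrix,
    callset: CGACallSet,
    deg_alpha: float = 0.01,
    deg_lfc: float = 1.5,
) -> pd.DataFrame:
    """Differential expression of CGA-positive vs CGA-negative samples."""
    positive = callset.sample_positive
    group_a = positive[positive].index.tolist()
    group_b = positive[~positive].index.tolist()
    return deg_analysis(expr, group_a, group_b, deg_alpha=deg_alpha, deg_lfc=deg_lfc)
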