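"""Copy-number dosage effects on the transcriptome (cis and trans).

A *cis* effect is the correlation between a gene's copy number and its own
mRNA abundance; a *trans* effect is the correlation between a source gene's
copy number and the expression of genes on other chromosomes. Expression is
analysed on the log2(TPM+1) scale, copy number on the linear scale. P-values
come from the exact t distribution of the Pearson correlation (n-2 df) and
are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .genomic_scores import AlleleSegment
from .io_formats import ExpressionMatrix, GeneCoordinates

logger = logging.getLogger(__name__)

MAX_TRANS_PAIRS = 10_000_000


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1; the output preserves
    the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p for paired rows of x and y."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.clip(r, -1.0, 1.0)
    p = _pearson_pvalue(r, n)
    p[denom == 0] = np.nan
    r[denom == 0] = np.nan
    return r, p

def _pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def gene_level_cn(
    segments: Sequence[AlleleSegment],
    coords: GeneCoordinates,
    min_covered_fraction: float = 0.5,
) -> pd.DataFrame:
    """Gene-level copy number: length-weighted mean cn_total of overlapping
    segments, per sample. Genes with no overlapping segment are NaN (logged);
    if more than half the genes are uncovered a configuration error is raised
    (likely coordinate mismatch).
    """
    samples = sorted({s.sample_id for s in segments})
    genes = coords.gene_ids
    by_sample_chrom: dict[tuple[str, str], list[AlleleSegment]] = {}
    for seg in segments:
        by_sample_chrom.setdefault((seg.sample_id, seg.chrom), []).append(seg)

    by_chrom_genes: dict[str, list[str]] = {}
    for g in genes:
        by_chrom_genes.setdefault(coords.chrom_of(g), []).append(g)

    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_pos = {s: j for j, s in enumerate(samples)}
    values = np.full((len(genes), len(samples)), np.nan)
    for (sample, chrom), segs in by_sample_chrom.items():
        chrom_genes = by_chrom_genes.get(chrom)
        if not chrom_genes:
            continue
        segs = sorted(segs, key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        totals = np.array([s.cn_total for s in segs], dtype=float)
        g_rows = np.array([gene_pos[g] for g in chrom_genes])
        g_starts = np.array([coords[g].start for g in chrom_genes])
        g_ends = np.array([coords[g].end for g in chrom_genes])
        lo = np.searchsorted(ends, g_starts, side="right")
        hi = np.searchsorted(starts, g_ends, side="left")
        col = sample_pos[sample]
        single = hi - lo == 1
        values[g_rows[single], col] = totals[np.clip(lo[single], 0, len(segs) - 1)]
        for idx in np.flatnonzero(hi - lo > 1):
            sl = slice(lo[idx], hi[idx])
            ov = np.minimum(ends[sl], g_ends[idx]) - np.maximum(starts[sl], g_starts[idx])
            ov = np.clip(ov, 0, None)
            if ov.sum() > 0:
                values[g_rows[idx], col] = float((totals[sl] * ov).sum() / ov.sum())
    cn = pd.DataFrame(values, index=genes, columns=samples)
    uncovered = cn.isna().all(axis=1)
    if uncovered.any():
        logger.info("gene_level_cn: %d genes without segment overlap", uncovered.sum())
    if uncovered.mean() > min_covered_fraction:
        raise ConfigError(
            f"{uncovered.sum()}/{len(genes)} genes have no segment overlap; "
            "check that gene coordinates and segments share a genome"
        )
    return cn


@dataclass(frozen=True)
class CisRecord:
    gene_id: str
    r: float
    p: float
    q: float

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


def cis_effects(
    cn: pd.DataFrame,
    expr: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between copy number and log2(TPM+1).

    Returns a DataFrame indexed by gene with columns r, p, q, sign,
    significant (q < alpha). Genes with zero variance in either row are
    skipped and logged.
    """
    genes = [g for g in cn.index if g in expr.tpm.index]
    samples = [s for s in cn.columns if s in expr.tpm.columns]
    if len(samples) < 3:
        raise ValidationError("cis_effects needs >=3 shared samples")
    if not genes:
        raise ValidationError("no shared genes between CN and expression")
    x = cn.loc[genes, samples].to_numpy(dtype=float)
    y = expr.log2().loc[genes, samples].to_numpy(dtype=float)
    keep = ~np.isnan(x).any(axis=1)
    r, p = _pearson_rows(x[keep], y[keep])
    valid = ~np.isnan(p)
    if (~valid).any():
        logger.info("cis_effects: skipped %d zero-variance genes", int((~valid).sum()))
    tested = np.array(genes)[keep][valid]
    r, p = r[valid], p[valid]
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "r": r,
            "p": p,
            "q": q,
            "sign": np.where(r >= 0, "positive", "negative"),
            "significant": q < alpha,
        },
        index=pd.Index(tested, name="gene_id"),
    )
    return out


@dataclass(frozen=True)
class TransTally:
    source_gene_id: str
    n_positive: int
    n_negative: int


def trans_effects(
    cn: pd.DataFrame,
    expr: ExpressionMatrix,
    coords: GeneCoordinates,
    source_genes: Sequence[str],
    alpha: float = 0.05,
    force: bool = False,
) -> tuple[pd.DataFrame, list[TransTally]]:
    """Correlate each source gene's copy number with the expression of every
    gene on a *different* chromosome.

    Returns the per-pair table (source, target, r, p, q, significant) and the
    per-source tallies of significant pairs by sign. BH adjustment spans all
    pairs tested in the run.
    """
    samples = [s for s in cn.columns if s in expr.tpm.columns]
    if len(samples) < 3:
        raise ValidationError("trans_effects needs >=3 shared samples")
    for g in source_genes:
        if g not in cn.index:
            raise ValidationError(f"source gene {g!r} absent from CN matrix")
        if g not in coords:
            raise ValidationError(f"source gene {g!r} has no coordinates")
    expr_genes = [g for g in expr.tpm.index if g in coords]
    logx = expr.log2().loc[expr_genes, samples].to_numpy(dtype=float)
    expr_chroms = np.array([coords.chrom_of(g) for g in expr_genes])
    expr_index = np.array(expr_genes)

    n_pairs = sum(int((expr_chroms != coords.chrom_of(s)).sum()) for s in source_genes)
    if n_pairs > MAX_TRANS_PAIRS and not force:
        raise ConfigError(
            f"{n_pairs} trans pairs requested (> {MAX_TRANS_PAIRS}); "
            "pass force=True to override"
        )

    frames = []
    for src in source_genes:
        mask = expr_chroms != coords.chrom_of(src)
        targets = expr_index[mask]
        if targets.size == 0:
            continue
        x = np.broadcast_to(
            cn.loc[src, samples].to_numpy(dtype=float), (targets.size, len(samples))
        )
        r, p = _pearson_rows(np.ascontiguousarray(x), logx[mask])
        frames.append(
            pd.DataFrame({"source": src, "target": targets, "r": r, "p": p})
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs = pairs.dropna(subset=["p"]).reset_index(drop=True)
    pairs["q"] = bh_fdr(pairs["p"].to_numpy())
    pairs["significant"] = pairs["q"] < alpha

    tallies = []
    for src in source_genes:
        sub = pairs[(pairs["source"] == src) & pairs["significant"]]
        tallies.append(
            TransTally(
                source_gene_id=src,
                n_positive=int((sub["r"] > 0).sum()),
                n_negative=int((sub["r"] < 0).sum()),
            )
        )
    return pairs, tallies
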