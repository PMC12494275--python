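"""End-to-end orchestration of the analysis stages with config and provenance.

Stages run in a fixed order — HRD scoring, subtyping, cis/trans effects,
network, signature scoring, CGA calling, survival modelling — each writing
its outputs into its own subdirectory of the run directory. The resolved
configuration, master seed and a config hash are captured in
``provenance.json``; reruns with an identical config and seed produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cga import call_cga, contrast_cga_groups, summarize_by_subtype
from .cistrans import cis_effects, gene_level_cn, trans_effects
from .errors import ConfigError
from .genome import GenomeModel, reduced_genome
from .genomic_scores import compute_hrd_cohort
from .io_formats import (
    read_allele_segments,
    read_clinical_table,
    read_expression_matrix,
    read_gene_coordinates,
    read_gene_list,
    read_gene_sets,
    read_tissue_reference,
)
from .network import build_network, cluster_fold_changes, cluster_network
from .signatures import compare_groups_anova, score_gene_sets
from .subtyping import fit_subtypes
from .survival import cox_univariate_filter, fit_logistic_backward, roc_auc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths to the inputs plus every stage threshold (documented defaults)."""

    expression: str = ""
    segments: str = ""
    clinical: str = ""
    gene_bed: str = ""
    gene_sets: str = ""
    tissue_reference: str = ""
    cga_candidates: str = ""
    genome_table: str = ""

    hrd_threshold: int = 25
    mad_threshold: float | None = None
    mad_top_n: int = 500
    k_min: int = 2
    k_max: int = 6
    nmf_runs: int = 10
    fdr_alpha: float = 0.05
    network_rmin: float = 0.55
    network_clusters: int = 10
    annotation_alpha: float = 0.01
    cga_z: float = 3.0
    deg_alpha: float = 0.01
    deg_lfc: float = 1.5
    cox_alpha: float = 0.05
    n_trans_sources: int = 5
    master_seed: int = 0
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ConfigError("fdr_alpha must be in (0, 1)")
        if not 0 < self.network_rmin < 1:
            raise ConfigError("network_rmin must be in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.nmf_runs < 2:
            raise ConfigError("nmf_runs must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "skip_stages" in payload:
            payload["skip_stages"] = tuple(payload["skip_stages"])
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_genome_table(path: str | Path) -> GenomeModel:
    """Genome TSV with columns chrom, length, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t")
    return GenomeModel(
        chrom_lengths=dict(zip(df["chrom"].astype(str), df["length"].astype(int))),
        centromeres={
            str(r.chrom): (int(r.cen_start), int(r.cen_end)) for r in df.itertuples()
        },
    )


def _fit_nomogram(cdf, subtype_model, risk_scores, outcome):
    """Multivariable logistic model of vital status over grade, neoadjuvant
    status, NMF cluster and the transcriptomic risk score, turned into a
    point-based nomogram."""
    import statsmodels.api as sm

    from .survival import build_nomogram

    samples = outcome.index
    grade_num = cdf.loc[samples, "grade"].map({"G1": 1, "G2": 2, "G3": 3}).astype(float)
    neo = cdf.loc[samples, "neoadjuvant"].astype(float)
    clusters = (
        subtype_model.cluster_label.reindex(samples)
        if subtype_model is not None
        else pd.Series(1, index=samples)
    )
    cluster_levels = sorted(clusters.dropna().unique())
    X = pd.DataFrame({"grade": grade_num, "neoadjuvant": neo,
                      "risk": risk_scores.reindex(samples)})
    for c in cluster_levels[1:]:
        X[f"cluster_{c}"] = (clusters == c).astype(float)
    X = sm.add_constant(X, has_constant="add")
    res = sm.Logit(outcome.to_numpy(dtype=float), X.to_numpy()).fit(disp=0, maxiter=200)
    beta = dict(zip(X.columns, res.params))
    coefficients = {
        "grade": {g: beta["grade"] * v for g, v in (("G1", 1.0), ("G2", 2.0), ("G3", 3.0))},
        "neoadjuvant": {"no": 0.0, "yes": beta["neoadjuvant"]},
        "risk_score": {f"{v:.1f}": beta["risk"] * v for v in np.linspace(0, 1, 11)},
        "cluster": {
            str(c): beta.get(f"cluster_{c}", 0.0) for c in cluster_levels
        },
    }
    return build_nomogram(coefficients, intercept=float(beta["const"]))


STAGES = ("hrd", "subtype", "cistrans", "network", "signatures", "cga", "survival")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every configured stage; outputs land in ``out_dir/<stage>/``.

    A stage failure raises a stage-named error; outputs of completed stages
    are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    active = [s for s in STAGES if s not in config.skip_stages]

    # -- validate inputs up front -------------------------------------------
    required = {"expression": config.expression}
    if "hrd" in active or "cistrans" in active:
        required["segments"] = config.segments
    if "survival" in active:
        required["clinical"] = config.clinical
    if "cistrans" in active:
        required["gene_bed"] = config.gene_bed
    for name, path in required.items():
        if not path or not Path(path).exists():
            raise ConfigError(f"required input {name!r} missing or unreadable: {path!r}")

    (out / "provenance.json").write_text(
        json.dumps(
            {
                "tool": "hgsoctx",
                "version": __version__,
                "config": dataclasses.asdict(config),
                "config_hash": config.config_hash(),
                "master_seed": config.master_seed,
            },
            indent=1,
            sort_keys=True,
            default=str,
        )
    )

    expr = read_expression_matrix(config.expression)
    genome = (
        read_genome_table(config.genome_table) if config.genome_table else reduced_genome()
    )
    segments = read_allele_segments(config.segments) if config.segments else None
    coords = read_gene_coordinates(config.gene_bed) if config.gene_bed else None
    clinical = read_clinical_table(config.clinical) if config.clinical else None
    gene_sets = read_gene_sets(config.gene_sets) if config.gene_sets else None
    tissue_ref = (
        read_tissue_reference(config.tissue_reference) if config.tissue_reference else None
    )
    cga_candidates = (
        read_gene_list(config.cga_candidates) if config.cga_candidates else None
    )

    model = None
    cn = None

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    for stage in active:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "hrd":
                hrd = compute_hrd_cohort(segments, genome, config.hrd_threshold)
                hrd.to_csv(stage_dir("hrd") / "hrd.tsv", sep="\t")

            elif stage == "subtype":
                model = fit_subtypes(
                    expr,
                    k_range=range(config.k_min, config.k_max + 1),
                    n_runs=config.nmf_runs,
                    seed=config.master_seed,
                    mad_threshold=config.mad_threshold,
                    top_n_genes=config.mad_top_n,
                )
                d = stage_dir("subtype")
                model.cluster_label.to_csv(d / "labels.tsv", sep="\t")
                model.W.to_csv(d / "W.tsv", sep="\t")
                model.H.to_csv(d / "H.tsv", sep="\t")
                model.metrics.table.to_csv(d / "rank_metrics.tsv", sep="\t")
                (d / "metagenes.json").write_text(
                    json.dumps(model.metagenes, indent=1, sort_keys=True)
                )
                if gene_sets is not None:
                    from .subtyping import annotate_clusters

                    ann = annotate_clusters(
                        model.metagenes, gene_sets, expr.gene_ids,
                        alpha=config.annotation_alpha,
                    )
                    ann.to_csv(d / "cluster_annotation.tsv", sep="\t", index=False)

            elif stage == "cistrans":
                cn = gene_level_cn(segments, coords)
                cis = cis_effects(cn, expr, alpha=config.fdr_alpha)
                d = stage_dir("cistrans")
                cis.to_csv(d / "cis.tsv", sep="\t")
                sources = (
                    cn.var(axis=1).sort_values(ascending=False)
                    .head(config.n_trans_sources).index.tolist()
                )
                pairs, tallies = trans_effects(
                    cn, expr, coords, sources, alpha=config.fdr_alpha
                )
                pairs.to_csv(d / "trans_pairs.tsv", sep="\t", index=False)
                pd.DataFrame(
                    [
                        {"source": t.source_gene_id, "n_positive": t.n_positive,
                         "n_negative": t.n_negative}
                        for t in tallies
                    ]
                ).to_csv(d / "trans_tally.tsv", sep="\t", index=False)

            elif stage == "network":
                net = build_network(expr, r_min=config.network_rmin)
                d = stage_dir("network")
                net.write_edge_list(d / "edges.tsv")
                if len(net.nodes) >= config.network_clusters:
                    clusters = cluster_network(net, config.network_clusters)
                    clusters.to_csv(d / "node_clusters.tsv", sep="\t")
                if model is not None:
                    fc = cluster_fold_changes(expr, model.cluster_label)
                    fc.to_csv(d / "fold_changes.tsv", sep="\t")
                net.write_graphml(d / "network.graphml")

            elif stage == "signatures":
                if gene_sets is None:
                    logger.info("signatures stage skipped: no gene sets configured")
                    continue
                scores = score_gene_sets(expr, gene_sets)
                d = stage_dir("signatures")
                scores.to_csv(d / "scores.tsv", sep="\t")
                if model is not None:
                    rows = []
                    for name in scores.index:
                        res = compare_groups_anova(
                            scores.loc[name], model.cluster_label.astype(str)
                        )
                        rows.append(
                            {"gene_set": name, "F": res.f_statistic, "p": res.p_value,
                             "letters": json.dumps(res.letters, sort_keys=True)}
                        )
                    pd.DataFrame(rows).to_csv(d / "anova.tsv", sep="\t", index=False)

            elif stage == "cga":
                if cga_candidates is None:
                    logger.info("cga stage skipped: no candidate list configured")
                    continue
                callset = call_cga(
                    expr, cga_candidates, tissue_ref=tissue_ref, z_threshold=config.cga_z
                )
                d = stage_dir("cga")
                callset.outlier_flags.to_csv(d / "flags.tsv", sep="\t")
                if model is not None:
                    props = summarize_by_subtype(callset, model.cluster_label)
                    props.to_csv(d / "subtype_proportions.tsv", sep="\t")
                positive = callset.sample_positive
                if 2 <= positive.sum() <= len(positive) - 2:
                    deg = contrast_cga_groups(
                        expr, callset, deg_alpha=config.deg_alpha, deg_lfc=config.deg_lfc
                    )
                    deg.to_csv(d / "cga_deg.tsv", sep="\t")

            elif stage == "survival":
                cdf = clinical.data.set_index("sample_id")
                event = cdf["vital_status"] == "death"
                followup = cdf["followup_years"].astype(float)
                candidates = (
                    model.selected_genes[:200] if model is not None else expr.gene_ids[:200]
                )
                cox = cox_univariate_filter(
                    expr, followup, event, alpha=config.cox_alpha, genes=candidates
                )
                d = stage_dir("survival")
                cox.to_csv(d / "cox_univariate.tsv", sep="\t")
                selected = cox[cox["selected"]].index.tolist()
                if not selected:
                    logger.info("survival: no gene passed the Cox filter")
                    continue
                keep = cdf["vital_status"].isin(["alive", "death"])
                outcome = (cdf.loc[keep, "vital_status"] == "death").astype(int)
                risk_model = fit_logistic_backward(expr, outcome, selected)
                scores = risk_model.risk_score(expr)
                scores.rename("risk_score").to_csv(d / "risk_scores.tsv", sep="\t")
                (d / "risk_model.json").write_text(
                    json.dumps(
                        {
                            "genes": risk_model.selected_genes,
                            "intercept": risk_model.intercept,
                            "coefficients": risk_model.coefficients,
                            "regularized": risk_model.regularized,
                        },
                        indent=1,
                        sort_keys=True,
                    )
                )
                roc = roc_auc(scores.loc[outcome.index], outcome.astype(bool))
                pd.DataFrame(
                    {"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                     "specificity": roc.specificity}
                ).to_csv(d / "roc.tsv", sep="\t", index=False)
                (d / "auc.json").write_text(json.dumps({"auc": roc.auc}))
                try:
                    nomogram = _fit_nomogram(cdf, model, scores, outcome)
                    (d / "nomogram.json").write_text(
                        json.dumps(
                            {
                                "points": nomogram.points,
                                "eta_at_reference": nomogram.eta_at_reference,
                                "eta_per_point": nomogram.eta_per_point,
                            },
                            indent=1,
                            sort_keys=True,
                        )
                    )
                except Exception as nomo_exc:  # degenerate covariates
                    logger.info("survival: nomogram skipped (%s)", nomo_exc)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
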