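"""Synthetic HGSOC-like cohort generator with planted ground truth.

The generator emits every input the analysis pipeline consumes — TPM
expression, allele-specific copy-number segments, gene-level CN, clinical
covariates, gene coordinates, a germline-tissue reference matrix and a
cancer-germline antigen (CGA) candidate list — together with the planted
truth (subtype labels, infiltration levels, HRD status, cis/trans
architecture, CGA outliers, survival coefficients) so that every downstream
stage has a recovery test.

Model
-----
Expression is built on the log2 scale: for gene g and sample s

    y[g, s] = base_g + factor_strength * marker(g, z_s) + immune + cis/trans + eps

with ``eps ~ N(0, 1)``, ``z_s`` the planted subtype, immune genes elevated
in proportion to the sample's infiltration level, cis genes coupled to
their own gene-level copy number (noise calibrated so the Pearson r on the
analysis scale matches ``cis_slope``), and trans-hub copy number perturbing
target genes on other chromosomes. TPM is the exact inverse of the analysis
transform, ``2**max(y, 0) - 1``, and each sample column is rescaled to sum
to 1e6. The inverse-log link (rather than a softplus) is used so planted
correlations are controlled analytically on the very scale the analysis
measures them; the zero clip keeps TPM non-negative.

Copy-number segments tile a reduced genome (five 100 Mb chromosomes by
default). HRD-positive samples are tiled with many >= 8 Mb state switches,
long LOH runs and telomeric imbalance; HRD-negative samples are mostly
(2,1) heterozygous with a few small interstitial events, so the planted
scar-count separation is large.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cistrans import gene_level_cn
from .errors import ConfigError
from .genome import MB, GenomeModel, reduced_genome
from .genomic_scores import AlleleSegment
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneCoordinates,
    GeneRecord,
    write_allele_segments,
    write_clinical_table,
    write_expression_matrix,
    write_gene_coordinates,
    write_gene_list,
    write_tissue_reference,
)

TPM_TOTAL = 1_000_000.0

#: Table-1-style cohort marginals (counts out of 111) used for clinical draws
COHORT_MARGINALS = {
    "n": 111,
    "age_mean": 54.1,
    "age_sd": 8.6,
    "grade": {"G1": 5, "G2": 44, "G3": 62},
    "figo_stage": {"I": 1, "II": 6, "III": 58, "IV": 46},
    "neoadjuvant": {"yes": 40, "no": 71},
    "residual": {"microscopic": 88, "lt1cm": 21, "ge1cm": 2},
    "vital_status": {"alive": 55, "death": 12, "lfu": 44},
    "followup_mean": 3.90,
    "followup_sd": 1.69,
}

GERMLINE_TISSUES = ("testis", "ovary")
SOMATIC_TISSUES = ("liver", "lung", "brain", "heart", "kidney", "muscle", "skin", "colon")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    ``factor_strength`` is the log2-scale marker elevation divided by the
    unit residual SD (a signal-to-noise ratio). ``cis_slope`` is the target
    Pearson correlation between a cis gene's CN and its log2 expression.
    """

    n_samples: int = 120
    n_genes: int = 2000
    k_subtypes: int = 4
    subtype_proportions: tuple[float, ...] | None = None
    factor_strength: float = 2.0
    infiltration_subtype_index: int = 0
    n_immune_genes: int = 100
    markers_per_subtype: int = 75
    n_cis_genes: int = 100
    cis_slope: float = 0.9
    n_trans_hubs: int = 3
    trans_targets_per_hub: int = 12
    trans_positive_fraction: float = 0.7
    hrd_fraction: float = 0.5
    n_cga_genes: int = 226
    cga_outlier_fraction: float = 0.21
    cga_outlier_z: float = 6.0
    n_survival_genes: int = 5
    survival_coefficients: Mapping[str, float] | None = None
    censoring_rate: float = 0.5
    n_coexpression_modules: int = 40
    module_size: int = 10
    module_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.subtype_proportions
        if props is not None:
            if len(props) != self.k_subtypes:
                raise ConfigError("subtype_proportions length must equal k_subtypes")
            if abs(sum(props) - 1.0) > 1e-8:
                raise ConfigError("subtype_proportions must sum to 1")
        needed = (
            self.k_subtypes * self.markers_per_subtype
            + self.n_immune_genes
            + self.n_cis_genes
            + self.n_trans_hubs * (1 + self.trans_targets_per_hub)
            + self.n_cga_genes
            + self.n_survival_genes
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"gene roles need {needed} genes but n_genes={self.n_genes}"
            )
        if not 0 <= self.infiltration_subtype_index < self.k_subtypes:
            raise ConfigError("infiltration_subtype_index out of range")
        for name in ("hrd_fraction", "cga_outlier_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.cis_slope < 1:
            raise ConfigError("cis_slope must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth; the oracle against which recovery is judged."""

    subtype_label: pd.Series            # sample -> 0..k-1
    infiltration_level: pd.Series       # sample -> [0, 1]
    hrd_status: pd.Series               # sample -> "HRD" / "HRR"
    cga_outliers: set[tuple[str, str]]  # (sample, gene)
    cis_genes: dict[str, float]         # gene -> planted slope (log2 per copy)
    trans_hubs: dict[str, dict[str, float]]  # hub -> target -> signed slope
    immune_genes: list[str]
    marker_genes: dict[int, list[str]]  # subtype -> marker gene ids
    survival_coefficients: dict[str, float]
    linear_predictor: pd.Series         # sample -> true survival linear predictor
    coexpression_modules: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_label": self.subtype_label.astype(int).to_dict(),
            "infiltration_level": self.infiltration_level.round(6).to_dict(),
            "hrd_status": self.hrd_status.to_dict(),
            "cga_outliers": sorted(list(t) for t in self.cga_outliers),
            "cis_genes": self.cis_genes,
            "trans_hubs": self.trans_hubs,
            "immune_genes": self.immune_genes,
            "marker_genes": {str(k): v for k, v in self.marker_genes.items()},
            "survival_coefficients": self.survival_coefficients,
            "linear_predictor": self.linear_predictor.round(6).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    cn: pd.DataFrame
    segments: list[AlleleSegment]
    clinical: ClinicalTable
    coords: GeneCoordinates
    tissue_ref: pd.DataFrame
    cga_candidates: list[str]
    truth: SyntheticTruth
    genome: GenomeModel

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(self.expression, out / "expression.tsv")
        self.cn.to_csv(out / "cn_matrix.tsv", sep="\t", index_label="gene_id")
        write_allele_segments(self.segments, out / "segments.tsv")
        write_clinical_table(self.clinical, out / "clinical.tsv")
        write_gene_coordinates(self.coords, out / "genes.bed")
        write_tissue_reference(self.tissue_ref, out / "tissue_reference.tsv")
        write_gene_list(self.cga_candidates, out / "cga_candidates.txt")
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# Segment simulation

_HRD_STATES = [(2, 1), (2, 0), (1, 0), (3, 1), (3, 0), (4, 1), (4, 2)]


def generate_segments(
    sample_id: str,
    hrd_positive: bool,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> list[AlleleSegment]:
    """Tile every chromosome of ``genome`` with allele-specific segments.

    HRD-positive samples get dense >= 8 Mb state switches (many large-scale
    transitions), long LOH runs and telomeric imbalance; HRD-negative
    samples are near-diploid heterozygous with rare small events.
    """
    segments: list[AlleleSegment] = []
    for chrom, length in genome.chrom_lengths.items():
        if hrd_positive:
            bounds = [0]
            while bounds[-1] < length:
                bounds.append(min(length, bounds[-1] + int(rng.uniform(8, 18) * MB)))
            states = []
            for _ in range(len(bounds) - 1):
                choices = [s for s in _HRD_STATES if not states or s != states[-1]]
                states.append(choices[rng.integers(len(choices))])
            for (lo, hi), (total, minor) in zip(zip(bounds, bounds[1:]), states):
                segments.append(AlleleSegment(sample_id, chrom, lo, hi, total, minor))
        else:
            u = rng.uniform()
            if u < 0.70:
                segments.append(AlleleSegment(sample_id, chrom, 0, length, 2, 1))
            elif u < 0.85:
                # small interstitial event, too short for any scar index
                a = int(rng.uniform(20, 45) * MB)
                b = a + int(rng.uniform(3, 8) * MB)
                total, minor = (3, 1) if rng.uniform() < 0.5 else (2, 0)
                segments.append(AlleleSegment(sample_id, chrom, 0, a, 2, 1))
                segments.append(AlleleSegment(sample_id, chrom, a, b, total, minor))
                segments.append(AlleleSegment(sample_id, chrom, b, length, 2, 1))
            else:
                # short telomeric gain: a single TAI event
                c = int(rng.uniform(5, 15) * MB)
                segments.append(AlleleSegment(sample_id, chrom, 0, c, 3, 1))
                segments.append(AlleleSegment(sample_id, chrom, c, length, 2, 1))
    return segments


def _place_genes(gene_ids: Sequence[str], genome: GenomeModel) -> GeneCoordinates:
    """Spread genes evenly across chromosomes (round-robin, 50 kb loci)."""
    chroms = list(genome.chrom_lengths)
    per_chrom = int(np.ceil(len(gene_ids) / len(chroms)))
    records: dict[str, GeneRecord] = {}
    for i, g in enumerate(gene_ids):
        chrom = chroms[i % len(chroms)]
        slot = i // len(chroms)
        length = genome.length(chrom)
        start = int((slot + 0.5) * length / per_chrom)
        start = min(start, length - 50_001)
        records[g] = GeneRecord(gene_id=g, chrom=chrom, start=start, end=start + 50_000)
    return GeneCoordinates(records=records)


# ---------------------------------------------------------------------------
# Clinical table


def _moment_matched(
    rng: np.random.Generator, n: int, mean: float, sd: float, clip: float = 2.2
) -> np.ndarray:
    """Draw n values whose sample mean and SD exactly equal (mean, sd)."""
    z = np.clip(rng.standard_normal(n), -clip, clip)
    z = (z - z.mean()) / z.std()
    return mean + sd * z


def _categorical_column(
    rng: np.random.Generator, n: int, counts: Mapping[str, int] | Mapping[str, float]
) -> np.ndarray:
    total = sum(counts.values())
    out = np.empty(n, dtype=object)
    pos = 0
    items = list(counts.items())
    for i, (label, c) in enumerate(items):
        k = round(n * c / total) if total != n else int(c)
        if i == len(items) - 1:
            k = n - pos
        out[pos : pos + k] = label
        pos += k
    rng.shuffle(out)
    return out


def clinical_from_marginals(
    seed: int = 0, marginals: Mapping | None = None
) -> ClinicalTable:
    """Synthetic clinical table whose marginal counts and age/follow-up
    moments exactly match the published cohort summary (n=111, mean age
    54.1, 40 neoadjuvant-treated, 62 grade-3, ...). Individual rows are
    synthetic: categories are assigned independently at random."""
    m = dict(COHORT_MARGINALS)
    if marginals:
        m.update(marginals)
    n = m["n"]
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "age": np.round(_moment_matched(rng, n, m["age_mean"], m["age_sd"]), 1),
            "grade": _categorical_column(rng, n, m["grade"]),
            "figo_stage": _categorical_column(rng, n, m["figo_stage"]),
            "neoadjuvant": _categorical_column(rng, n, m["neoadjuvant"]) == "yes",
            "residual": _categorical_column(rng, n, m["residual"]),
            "vital_status": _categorical_column(rng, n, m["vital_status"]),
            "followup_years": np.round(
                np.clip(
                    _moment_matched(rng, n, m["followup_mean"], m["followup_sd"]), 0.05, None
                ),
                2,
            ),
        }
    )
    return ClinicalTable(df)


def _calibrate_censoring(
    times: np.ndarray, window: np.ndarray, target: float
) -> float:
    """Scale the follow-up window so the censored fraction ~= target."""
    if target <= 0:
        return 1e6
    if target >= 1:
        return 1e-6
    lo, hi = 1e-3, 1e3
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        frac_censored = float(np.mean(times > mid * window))
        if frac_censored > target:
            lo = mid  # longer windows -> fewer censored
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# Cohort generation


def _gene_roles(config: SyntheticConfig) -> dict[str, list[str]]:
    ids = [f"G{i:05d}" for i in range(config.n_genes)]
    roles: dict[str, list[str]] = {}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = ids[cursor : cursor + n]
        cursor += n
        return out

    for j in range(config.k_subtypes):
        roles[f"marker_{j}"] = take(config.markers_per_subtype)
    roles["immune"] = take(config.n_immune_genes)
    roles["cis"] = take(config.n_cis_genes)
    roles["hubs"] = take(config.n_trans_hubs)
    roles["trans_targets"] = take(config.n_trans_hubs * config.trans_targets_per_hub)
    roles["cga"] = take(config.n_cga_genes)
    roles["survival"] = take(config.n_survival_genes)
    roles["background"] = ids[cursor:]
    roles["all"] = ids
    return roles


def generate_cohort(
    config: SyntheticConfig, genome: GenomeModel | None = None
) -> SyntheticCohort:
    """Generate the full synthetic cohort (inputs plus planted truth)."""
    genome = genome or reduced_genome()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.k_subtypes
    samples = [f"S{i + 1:03d}" for i in range(n)]
    roles = _gene_roles(config)
    genes = roles["all"]
    coords = _place_genes(genes, genome)

    # --- subtypes -----------------------------------------------------------
    props = config.subtype_proportions or tuple([1.0 / k] * k)
    labels = rng.choice(k, size=n, p=np.asarray(props))
    subtype = pd.Series(labels, index=samples, name="subtype")

    # --- HRD status and segments -------------------------------------------
    hrd_flags = rng.uniform(size=n) < config.hrd_fraction
    hrd_status = pd.Series(
        np.where(hrd_flags, "HRD", "HRR"), index=samples, name="hrd_status"
    )
    segments: list[AlleleSegment] = []
    for s, flag in zip(samples, hrd_flags):
        segments.extend(generate_segments(s, bool(flag), genome, rng))
    cn = gene_level_cn(segments, coords)

    # --- infiltration gradient ---------------------------------------------
    immune_subtype = config.infiltration_subtype_index
    infiltration = np.where(
        labels == immune_subtype, rng.uniform(0.7, 1.0, n), rng.uniform(0.1, 0.4, n)
    )
    infiltration = pd.Series(infiltration, index=samples, name="infiltration")

    # --- base log2 expression -----------------------------------------------
    base = rng.normal(5.0, 1.0, size=config.n_genes)
    y = base[:, None] + rng.standard_normal((config.n_genes, n))
    gene_pos = {g: i for i, g in enumerate(genes)}

    marker_genes: dict[int, list[str]] = {}
    for j in range(k):
        marker_genes[j] = roles[f"marker_{j}"]
        rows = [gene_pos[g] for g in marker_genes[j]]
        y[np.ix_(rows, np.flatnonzero(labels == j))] += config.factor_strength

    immune_rows = [gene_pos[g] for g in roles["immune"]]
    y[immune_rows, :] += 3.0 * infiltration.to_numpy()[None, :]

    # weak background co-expression modules: subtype-independent correlated
    # gene groups, as in real transcriptomes (these also supply the
    # co-expression network's edge structure)
    background = roles["background"]
    n_mod = min(
        config.n_coexpression_modules, len(background) // max(config.module_size, 1)
    )
    for mi in range(n_mod):
        module = background[mi * config.module_size : (mi + 1) * config.module_size]
        activity = rng.normal(0.0, config.module_sd, size=n)
        for g in module:
            y[gene_pos[g], :] += activity
    module_map = {
        f"module_{mi}": background[mi * config.module_size : (mi + 1) * config.module_size]
        for mi in range(n_mod)
    }

    # --- cis coupling (noise calibrated for the target Pearson r) ----------
    cis_truth: dict[str, float] = {}
    cis_b = 0.5  # log2 units per copy
    for g in roles["cis"]:
        row = gene_pos[g]
        cn_row = cn.loc[g].to_numpy(dtype=float)
        var_cn = cn_row.var()
        if config.cis_slope <= 0 or var_cn < 1e-6:
            cis_truth[g] = 0.0
            continue
        resid_sd = float(
            np.sqrt(cis_b**2 * var_cn * (1.0 / config.cis_slope**2 - 1.0))
        )
        y[row, :] = (
            base[row]
            + cis_b * (cn_row - cn_row.mean())
            + resid_sd * rng.standard_normal(n)
        )
        cis_truth[g] = cis_b

    # --- trans hubs ---------------------------------------------------------
    trans_truth: dict[str, dict[str, float]] = {}
    target_pool = roles["trans_targets"]
    for h_idx, hub in enumerate(roles["hubs"]):
        hub_row = gene_pos[hub]
        hub_cn = cn.loc[hub].to_numpy(dtype=float)
        var_cn = hub_cn.var()
        # hubs are themselves dosage-sensitive (cis-coupled)
        if var_cn > 1e-6:
            resid_sd = float(np.sqrt(cis_b**2 * var_cn * (1.0 / 0.81 - 1.0)))
            y[hub_row, :] = (
                base[hub_row]
                + cis_b * (hub_cn - hub_cn.mean())
                + resid_sd * rng.standard_normal(n)
            )
        targets = target_pool[
            h_idx * config.trans_targets_per_hub : (h_idx + 1) * config.trans_targets_per_hub
        ]
        trans_truth[hub] = {}
        for t_idx, tgt in enumerate(targets):
            sign = 1.0 if t_idx < config.trans_positive_fraction * len(targets) else -1.0
            slope = sign * 0.35
            y[gene_pos[tgt], :] += slope * (hub_cn - hub_cn.mean())
            trans_truth[hub][tgt] = slope

    # --- cancer-germline antigens ------------------------------------------
    # silent genes: bounded technical noise (no heavy tail), so a 3-SD rule
    # flags only the planted outliers
    cga_genes = roles["cga"]
    cga_rows = [gene_pos[g] for g in cga_genes]
    cga_base_sd = 0.3
    y[cga_rows, :] = rng.uniform(0.0, 0.8, size=(len(cga_genes), n))
    non_immune = np.flatnonzero(labels != immune_subtype)
    n_pos = int(round(config.cga_outlier_fraction * n))
    outlier_samples = rng.choice(non_immune, size=min(n_pos, non_immune.size), replace=False)
    cga_outliers: set[tuple[str, str]] = set()
    for s_idx in outlier_samples:
        n_hit = int(rng.integers(1, 4))
        hit_genes = rng.choice(len(cga_genes), size=n_hit, replace=False)
        for g_idx in hit_genes:
            y[cga_rows[g_idx], s_idx] += config.cga_outlier_z * cga_base_sd + 3.0
            cga_outliers.add((samples[s_idx], cga_genes[g_idx]))

    # --- survival -----------------------------------------------------------
    surv_genes = roles["survival"]
    if config.survival_coefficients is not None:
        surv_coef = dict(config.survival_coefficients)
        for g in surv_coef:
            if g not in gene_pos:
                raise ConfigError(f"survival coefficient for unknown gene {g!r}")
    else:
        default_betas = [1.5, -1.5, 1.2, -1.2, 1.0, -1.0, 0.8, -0.8]
        surv_coef = {
            g: default_betas[i % len(default_betas)] for i, g in enumerate(surv_genes)
        }
    eta = np.zeros(n)
    for g, beta in surv_coef.items():
        row = y[gene_pos[g], :]
        eta += beta * (row - row.mean()) / max(row.std(), 1e-9)
    linear_predictor = pd.Series(eta, index=samples, name="linear_predictor")

    # exponential event times under the planted hazard; administrative
    # censoring window scaled so the censored fraction matches the config
    base_rate = 0.2  # events per year at eta = 0
    times = rng.exponential(1.0 / (base_rate * np.exp(eta)))
    window = rng.uniform(0.5, 6.5, size=n)
    scale = _calibrate_censoring(times, window, config.censoring_rate)
    event = times <= scale * window
    censored = ~event
    observed = np.clip(np.minimum(times, scale * window), 0.05, 20.0)

    # --- TPM matrix ---------------------------------------------------------
    tpm = np.power(2.0, np.clip(y, 0.0, None)) - 1.0
    tpm *= TPM_TOTAL / tpm.sum(axis=0, keepdims=True)
    expression = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples))

    # --- clinical table -----------------------------------------------------
    m = COHORT_MARGINALS
    vital = np.where(
        ~censored, "death", np.where(rng.uniform(size=n) < 0.55, "alive", "lfu")
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "age": np.round(
                    np.clip(rng.normal(m["age_mean"], m["age_sd"], n), 25, 85), 1
                ),
                "grade": _categorical_column(rng, n, m["grade"]),
                "figo_stage": _categorical_column(rng, n, m["figo_stage"]),
                "neoadjuvant": _categorical_column(rng, n, m["neoadjuvant"]) == "yes",
                "residual": _categorical_column(rng, n, m["residual"]),
                "vital_status": vital,
                "followup_years": np.round(observed, 3),
            }
        )
    )

    # --- germline-tissue reference ------------------------------------------
    tissues = list(GERMLINE_TISSUES) + list(SOMATIC_TISSUES)
    ref = pd.DataFrame(
        rng.uniform(2.0, 50.0, size=(len(tissues), config.n_genes)),
        index=tissues,
        columns=genes,
    )
    ref.loc[list(SOMATIC_TISSUES), cga_genes] = rng.uniform(
        0.0, 0.5, size=(len(SOMATIC_TISSUES), len(cga_genes))
    )
    ref.loc["testis", cga_genes] = rng.uniform(20.0, 80.0, size=len(cga_genes))
    ref.loc["ovary", cga_genes] = rng.uniform(5.0, 30.0, size=len(cga_genes))

    truth = SyntheticTruth(
        subtype_label=subtype,
        infiltration_level=infiltration,
        hrd_status=hrd_status,
        cga_outliers=cga_outliers,
        cis_genes=cis_truth,
        trans_hubs=trans_truth,
        immune_genes=list(roles["immune"]),
        marker_genes=marker_genes,
        survival_coefficients={g: float(b) for g, b in surv_coef.items()},
        linear_predictor=linear_predictor,
        coexpression_modules=module_map,
    )
    return SyntheticCohort(
        expression=expression,
        cn=cn,
        segments=segments,
        clinical=clinical,
        coords=coords,
        tissue_ref=ref,
        cga_candidates=list(cga_genes),
        truth=truth,
        genome=genome,
    )


def immune_signature(truth: SyntheticTruth) -> dict[str, set[str]]:
    """Convenience gene sets derived from the planted truth (for scoring tests)."""
    return {"IMMUNE_INFILTRATE": set(truth.immune_genes)}
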