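# Methods

`hgsoctx` re-implements, as a tested and reusable pipeline, the integrative
bulk-transcriptome analysis workflow used for high-grade serous ovarian
cancer (HGSOC) cohorts: homologous-recombination-deficiency (HRD) scar
scoring from allele-specific copy-number segments, consensus-NMF molecular
subtyping, copy-number cis/trans expression effects, co-expression network
clustering, single-sample immune-signature scoring, cancer-germline antigen
(CGA) outlier calling, and a logistic survival risk score with a nomogram.
Because no patient-level sequencing data are redistributable, every stage is
validated against a synthetic-cohort generator that plants the statistical
structure each stage is supposed to recover. This note records the models,
the parameter choices and their rationale, and what the tests do and do not
demonstrate.

## HRD scar scores

A sample's allele-specific copy-number profile is a tiling of each
chromosome by segments with total (`cn_total`) and minor-allele (`cn_minor`)
copy counts. Each segment falls into one of six states: HET (1+1), NLOH
(copy-neutral LOH, 2+0), DLOH (LOH with deletion, total ≤ 1 — homozygous
loss is folded in to keep the classifier total), BCNA (balanced gain, k+k),
ALOH (amplified LOH) and ASCNA (unbalanced gain retaining both alleles).

The three scar indices use the canonical published definitions — the de
facto standard parameterization in HRD scar scoring; all sizes are exposed
as arguments:

* **LOH**: maximal runs of minor-allele-0 segments (total ≥ 1) longer than
  15 Mb that do not span a whole chromosome;
* **TAI**: allele-imbalanced segments reaching a chromosome end without
  spanning the centromere interval;
* **LST**: breakpoints between adjacent segments each ≥ 10 Mb after 3 Mb
  smoothing.

Identical-state neighbours are merged before every index, so counts are
invariant to how a segmentation splits an unchanged region (property-tested
by splitting random segments). For LST the order is merge → drop < 3 Mb →
re-merge; dropping before merging would make the count depend on arbitrary
segment boundaries. The HRD call is `HRD` iff LOH+TAI+LST strictly exceeds
25 (a conventional cutoff, originally chosen as a cohort median); a sum
of exactly 25 is `HRR`. Uncorrected counts are used; ploidy-normalized
variants of the indices exist but are not implemented.

Gene-level copy number is the length-weighted mean `cn_total` of
overlapping segments; `Amp`/`Del` labels use the strict cutoffs > 4 and
< 1. Tumor mutational burden is non-synonymous mutations per callable
megabase.

## Consensus-NMF subtyping

Expression columns are quantile-normalized (each sample mapped onto the
mean quantile vector, ties averaged). Genes are then filtered by median
absolute deviation (MAD); the cutoff is exposed both as an absolute
threshold (cohort studies have used values like 30 on their own normalized scales) and as
a top-N selection, which is the default (N = 500) because an absolute MAD
is not transferable across cohorts with different dynamic ranges. MAD is
computed on log2(TPM+1) by default — the robust statistic is otherwise
dominated by expression level — while the NMF input is the
quantile-normalized non-negative matrix itself (no z-scoring, which would
break non-negativity; no log, which buries block structure under the shared
baseline).

The factorization V ≈ WH uses multiplicative updates minimizing the
generalized Kullback–Leibler divergence (the Brunet variant used by the R
NMF package); the objective trace is returned and its monotone
non-increase is asserted in every test run. The updates are hand-authored
so the trace is available; scikit-learn's `mu`/KL solver serves as an
independent cross-check in the tests, never as the implementation.
Convergence: relative objective change < 1e-5 or 300 iterations; random
uniform initialization scaled to the data mean; all run seeds derive from
one master seed via `SeedSequence`.

For each rank k in 2..6 (10 runs each), the consensus matrix holds the
fraction of runs in which two samples share the argmax factor. Rank
metrics: cophenetic correlation of the average-linkage tree on 1 −
consensus, dispersion (mean of 4(c − ½)²), Hoyer sparseness of W and H,
and the mean silhouette of the consensus partition.

**Rank selection.** A plateau rule — largest k with cophenetic within 0.01
of the maximum and positive silhouette — is implemented and available
(`rank_rule_cophenetic_plateau`), but it over-selects on strongly
structured data: when k ≤ k_true every consensus is essentially crisp
(cophenetic 0.997–1.000), so every rank in range sits inside the slack and
the rule returns the top of the range. The default
(`rank_rule_balanced`) therefore takes the largest k whose cophenetic +
silhouette lies within 0.01 of the optimum. Below the true rank the
combined score can tie with the optimum almost exactly (a consistent merge
of two real clusters is also perfectly stable), while above it the
silhouette drops sharply (observed gaps ≥ 0.19 vs ≤ 0.005); the tolerance
separates the two regimes and the largest qualifying k resolves the most
structure the consensus supports. Any callable on the metrics table can be
plugged in instead.

Sample labels are the argmax of the H column of a final factorization at
the selected rank. Metagenes use the Kim–Park feature score
s(g) = 1 + (1/log k) Σ_q p log p on the row-normalized W, keeping genes
with s > mean + 3·sd and assigning each to its argmax factor; metagene
sets are disjoint by construction. Cluster annotation is hypergeometric
over-representation against user-supplied gene sets (GMT),
Benjamini–Hochberg-adjusted within cluster at α = 0.01, always reporting
at least the top three sets per cluster.

## Copy-number cis/trans effects

Cis: per gene, Pearson correlation between its copy number (linear scale)
and its own expression (log2(TPM+1) — variance-stabilized, while CN stays
linear for dosage interpretability), two-sided p from the exact t
distribution (n−2 df), BH adjustment across all tested genes, significance
at q < 0.05. Trans: each source gene's CN against expression of every gene
on a *different* chromosome; BH spans all pairs of the run; per-source
tallies count significant pairs by sign. The BH family choice (cis among
cis, trans among all pairs of the run) is recorded in the outputs. An
all-pairs genome-wide scan is quadratic, so sources default to the
top-variance CN genes and a guard refuses > 10⁷ pairs unless forced. The
BH step-up itself is implemented in `bh_fdr` (order-preserving, capped at
1) and cross-checked against `statsmodels.multipletests` in tests.

## Co-expression network

Candidate genes are the top quartile by log-scale variance (a joint
"variance and correlation" filter is decomposed here into a variance
pre-filter followed by the correlation threshold, both exposed). Edges connect pairs with Pearson
r strictly above 0.55; isolated genes are dropped. Clustering is
complete-linkage on 1 − r with non-adjacent pairs at distance 2, cut at a
fixed count (default 10). Because every between-component merge happens at
exactly distance 2, threshold-based cutting (`fcluster maxclust`) cannot
produce a fixed count — `cut_tree`, which splits tied merges by merge
order, is used instead. Per-subtype overlays are
log2(mean TPM in s + 1) − log2(mean TPM elsewhere + 1). The graph is
emitted as an edge list and GraphML for external layout; no layout is
computed.

## Signature scoring and group statistics

`ssgsea_score` is a rank-based single-sample enrichment statistic: genes
sorted by decreasing expression (ties broken by gene id for determinism);
the score accumulates the difference between the in-set ECDF weighted by
|rank statistic|^0.25 and the unweighted out-of-set ECDF. It is invariant
to strictly monotone transforms of the expression vector and comparable
only within a run. The immune and stromal composites are scores of
user-supplied signatures and their sum is the combined (purity-inverse)
score; no third-party signature compendium is shipped — the tests use the
synthetic immune signature.

Group comparisons: one-way ANOVA, Tukey HSD (statsmodels) at α = 0.05, and
an insert-and-absorb compact letter display (groups sharing a letter are
not significantly different). Differential expression: Welch t on
log2(TPM+1) (Welch t is the conservative default; a Wilcoxon alternative is flagged), log2FC as the difference of log-scale means, BH
adjustment, significance at q < 0.01 and |log2FC| > 1.5. The
over-representation test is the hypergeometric upper tail.

## Cancer-germline antigens

Candidates (a user-supplied list; published compilations contain 226 genes) are first restricted to genes whose median TPM is below
1.0 in every non-germline tissue of a tissues × genes reference matrix
(no constraint on testis/ovary); 1.0 TPM is the conventional
"not expressed" cutoff, as no numeric value is published. Outliers are
(sample, gene) pairs exceeding the per-gene cohort mean by more than 3 SD
on log2(TPM+1) (log scale tames TPM skew; raw-scale and leave-one-out
variants are flags). A sample is CGA-positive when ≥ 1 gene is flagged;
per-subtype positive proportions and a CGA+/CGA− Welch-t contrast complete
the stage.

## Survival risk model

Genes pass a univariate Cox proportional-hazards filter (lifelines;
Breslow ties) on log2(TPM+1) at Wald p < 0.05, with deaths as events and
both alive and lost-to-follow-up as censored. The logistic stage models
death vs alive (lost-to-follow-up excluded — the binary outcome is
undefined for them) with backward elimination: refit and drop the
highest-p gene until all p < 0.05 or one gene remains. Perfect separation
falls back to an L2-regularized fit, flagged in the result, and stops
elimination. The risk score is exactly 1/(1 + exp(−(β₀ + Σ β_g x_g))).

The nomogram assigns each covariate level points
100·β·(value − ref)/max|β·range|, with the reference level chosen as the
level minimizing β·value so points are non-negative and the covariate with
the largest coefficient × range spans 0–100; total points are then an
exact affine image of the linear predictor, so the points → probability
map reproduces the model prediction to machine precision (property-tested).
ROC/AUC uses the Mann–Whitney U form with ties counting ½, cross-checked
against brute-force pairwise comparison.

## Synthetic cohorts

The generator emits every pipeline input plus the planted truth. Defaults
are the study conditions: n = 120 samples, 2,000 genes, four equiprobable
subtypes, 75 marker genes per subtype elevated by `factor_strength` = 2
(log2 units per unit residual SD), a 100-gene immune program scaled by an
infiltration level drawn U(0.7, 1) in the designated immune subtype and
U(0.1, 0.4) elsewhere, 100 cis genes at a target CN–expression correlation
of 0.9, three trans hubs with 12 targets each (70% positive, slope ±0.35
log2/copy), 50% HRD samples, 226 CGA candidates with 21% of non-immune
samples carrying 1–3 outliers planted ≈ 6 baseline-SDs high, five
survival genes with standardized log-hazard coefficients ±(1.5, 1.2, 1.0),
and 40 weak background co-expression modules (10 genes, N(0, 0.8) shared
activity) supplying the non-subtype correlation structure real
transcriptomes have.

Expression is built on the log2 scale and mapped to TPM through the exact
inverse of the analysis transform, TPM = 2^max(y,0) − 1, then each column
is rescaled to sum to 10⁶ (conservation is asserted to ±0.1%). The
inverse-log link is used instead of a softplus because it lets the cis
residual SD be solved analytically for the target Pearson r on the very
scale the analysis measures (b²·var(CN)·(1/r² − 1)); the clip at zero
preserves non-negativity, and column rescaling attenuates planted
correlations by < 0.01 at these sizes (observed mean planted r ≈ 0.87
for a target of 0.9). CGA baselines are uniform (bounded) noise so a 3-SD
rule has a zero tail on nulls; the planted outliers are the only expected
flags.

Segments tile a reduced genome (five 100 Mb chromosomes, centromere =
central 5%) — full genome tables can be supplied instead. HRD-positive
samples are tiled with 8–18 Mb segments and random no-repeat states
(yielding scar sums ≈ 30–45); HRD-negative samples are mostly 2+1 with
occasional events too small or too interior to score (sums ≈ 0–6), so
planted status separates cleanly at the 25 threshold. Survival times are
exponential with rate 0.2·exp(η)/year under the planted linear predictor
η; an administrative follow-up window U(0.5, 6.5) years is rescaled by
bisection so the censored fraction matches the configured rate (0.5 by
default), which keeps death/alive status informative about η. The
clinical covariates (age, grade, FIGO stage, neoadjuvant, residual
disease) are drawn with the marginals of the published 111-patient cohort
summary; `clinical_from_marginals` additionally reproduces those marginal
counts and the age/follow-up moments exactly, for tests against the
printed summary. Everything derives from one `numpy` Generator seeded by
the config, so identical configs are bit-identical.

**What passing tests do not show.** The generator's noise is Gaussian on
the log-latent scale with independent genes outside the planted
structures; real cohorts have heavier tails, batch effects, correlated
technical noise, ambiguous cluster boundaries and genuinely unknown k.
Recovery at ARI ≈ 1 on these cohorts demonstrates correctness of the
machinery, not expected performance on clinical data; the published
cohort-level figures (four clusters of 111 patients, 2,790 cis genes, a
0.98 AUC) depend on that cohort's raw data and are not reproduction
targets here.

## Problem sizes and numerical choices

Consensus NMF runs 5 ranks × 10 restarts on a 500 × 120 matrix in ≈ 8 s;
the survival stage fits ≈ 2,000 univariate Cox models in ≈ 1 min; the
full acceptance sweep (10 subtyping seeds, 20 CGA cohorts, null
calibrations, n = 300 survival cohort) completes in a few minutes on one
core. Degenerate inputs are handled explicitly: zero-variance genes are
skipped and logged (cis, DEG p = 1, Cox, outlier calling), empty effective
gene sets raise a named error, ties in ranking are broken
deterministically by gene id, and consensus matrices are exactly
symmetric with unit diagonal by construction.
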