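"""Survival risk modelling: Cox gene filtering, logistic risk score,
nomogram construction and ROC evaluation.

The pipeline filters genes by univariate Cox proportional-hazards
association with overall survival (Wald p < 0.05), refines the set by
backward elimination in a logistic regression of vital status, and defines
the per-sample risk score as 1 / (1 + exp(-(b0 + sum_g b_g x_g))) on
log2(TPM+1) expression. A nomogram assigns each covariate level a point
value proportional to its coefficient-weighted displacement from the
reference level (the covariate with the largest coefficient x range spans
0-100 points) so that summed points map back to the model's predicted
probability exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .errors import ValidationError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Univariate Cox filter


def cox_univariate_filter(
    expr: ExpressionMatrix,
    followup_years: pd.Series,
    event: pd.Series,
    alpha: float = 0.05,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene univariate Cox proportional-hazards fit on log2(TPM+1).

    ``event`` is True for deaths; censored samples (alive or lost to
    follow-up) are False. Returns a table indexed by gene with columns
    coef, hr, p, selected (Wald p < alpha). Constant genes are skipped.
    """
    samples = [s for s in expr.sample_ids if s in followup_years.index]
    if len(samples) < 10:
        raise ValidationError("cox filter needs >=10 samples with follow-up")
    ev = event.reindex(samples).astype(bool)
    if not ev.any():
        raise ValidationError("no events (deaths) in the input")
    times = followup_years.reindex(samples).astype(float)
    logx = expr.log2()[samples]
    gene_list = list(genes) if genes is not None else expr.gene_ids
    rows = []
    for g in gene_list:
        x = logx.loc[g]
        if x.std() == 0:
            logger.info("cox_univariate_filter: constant gene %s skipped", g)
            continue
        df = pd.DataFrame({"T": times, "E": ev.astype(int), "x": x})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")
        except ConvergenceError:
            logger.info("cox_univariate_filter: gene %s did not converge", g)
            continue
        coef = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])
        rows.append({"gene_id": g, "coef": coef, "hr": float(np.exp(coef)), "p": p})
    if not rows:
        raise ValidationError("no genes could be fitted")
    out = pd.DataFrame(rows).set_index("gene_id")
    out["selected"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# Logistic risk model


@dataclass
class RiskModel:
    """Fitted logistic risk score over a gene panel (log2(TPM+1) inputs)."""

    selected_genes: list[str]
    intercept: float
    coefficients: dict[str, float]
    regularized: bool = False  # True when a separation fallback was used
    pvalues: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, expr: ExpressionMatrix) -> pd.Series:
        missing = [g for g in self.selected_genes if g not in expr.tpm.index]
        if missing:
            raise ValidationError(f"model genes missing from expression: {missing}")
        logx = expr.log2()
        eta = pd.Series(self.intercept, index=expr.sample_ids, dtype=float)
        for g in self.selected_genes:
            eta += self.coefficients[g] * logx.loc[g]
        return eta

    def risk_score(self, expr: ExpressionMatrix) -> pd.Series:
        """1 / (1 + exp(-(b0 + sum_g b_g x_g))), strictly inside (0, 1)."""
        eta = self.linear_predictor(expr)
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit a logistic regression; fall back to an L2-ridge fit on (quasi-)
    separation. Returns (params, pvalues, regularized_flag)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 50:
            return np.asarray(res.params), np.asarray(res.pvalues), False
    except Exception:  # PerfectSeparation or singular matrix
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1.0, L1_wt=0.0
        )
    params = np.asarray(res.params)
    return params, np.full(params.shape, np.nan), True


def fit_logistic_backward(
    expr: ExpressionMatrix,
    outcome: pd.Series,
    genes: Sequence[str],
    p_remove: float = 0.05,
) -> RiskModel:
    """Backward elimination: refit and drop the highest-p gene until every
    remaining coefficient has p < ``p_remove`` or a single gene remains.

    On perfect separation the fit falls back to an L2-regularized logistic
    regression (flagged via ``regularized``) and elimination stops.
    """
    outcome = outcome.reindex([s for s in expr.sample_ids if s in outcome.index])
    outcome = outcome.dropna().astype(int)
    if outcome.nunique() != 2:
        raise ValidationError("outcome must contain both classes")
    samples = outcome.index.tolist()
    logx = expr.log2()[samples]
    current = list(genes)
    if not current:
        raise ValidationError("no genes supplied to the logistic stage")
    y = outcome.to_numpy(dtype=float)
    while True:
        X = sm.add_constant(logx.loc[current].T.to_numpy(), has_constant="add")
        params, pvals, regularized = _fit_logit(y, X)
        if regularized or len(current) == 1:
            break
        gene_p = pvals[1:]
        worst = int(np.nanargmax(gene_p))
        if gene_p[worst] < p_remove:
            break
        current.pop(worst)
    return RiskModel(
        selected_genes=current,
        intercept=float(params[0]),
        coefficients={g: float(b) for g, b in zip(current, params[1:])},
        regularized=regularized,
        pvalues={g: float(p) for g, p in zip(current, pvals[1:])},
    )


# ---------------------------------------------------------------------------
# Nomogram


@dataclass
class NomogramSpec:
    """Point assignments per covariate level plus the total-points ->
    predicted-probability map. The reference level of each covariate is the
    level minimizing beta * value, so points are non-negative and the sum of
    points is an exact affine image of the model's linear predictor."""

    points: dict[str, dict[str, float]]   # covariate -> level -> points
    eta_at_reference: float
    eta_per_point: float

    def total_points(self, levels: Mapping[str, str]) -> float:
        return sum(self.points[c][str(l)] for c, l in levels.items())

    def predicted_probability(self, total_points: float) -> float:
        eta = self.eta_at_reference + self.eta_per_point * total_points
        return 1.0 / (1.0 + np.exp(-eta))


def build_nomogram(
    coefficients: Mapping[str, Mapping[str, float]],
    intercept: float,
) -> NomogramSpec:
    """Build a nomogram from a fitted logistic model.

    ``coefficients`` maps each covariate to {level: beta * value} — i.e. the
    linear-predictor contribution of every level (for numeric covariates,
    discretized values). The covariate with the largest contribution range
    spans 0-100 points; zero-range covariates are excluded (logged).
    """
    ranges = {}
    for cov, contribs in coefficients.items():
        vals = list(contribs.values())
        ranges[cov] = max(vals) - min(vals)
    kept = {c: r for c, r in ranges.items() if r > 0}
    for c in set(ranges) - set(kept):
        logger.info("build_nomogram: zero-range covariate %s excluded", c)
    if not kept:
        raise ValidationError("no covariate with a non-zero contribution range")
    max_range = max(kept.values())
    points: dict[str, dict[str, float]] = {}
    eta_ref = float(intercept)
    for cov in kept:
        contribs = coefficients[cov]
        ref = min(contribs.values())
        eta_ref += ref
        points[cov] = {
            str(level): 100.0 * (v - ref) / max_range for level, v in contribs.items()
        }
    return NomogramSpec(
        points=points, eta_at_reference=eta_ref, eta_per_point=max_range / 100.0
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> ROCResult:
    """ROC curve and AUC via the Mann-Whitney U statistic (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    thresholds = np.r_[np.inf, np.unique(s)[::-1]]
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)
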