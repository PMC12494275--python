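import numpy as np
import pandas as pd
import pytest

from hgsoctx.errors import ValidationError
from hgsoctx.io_formats import ExpressionMatrix
from hgsoctx.survival import (
    RiskModel,
    build_nomogram,
    cox_univariate_filter,
    fit_logistic_backward,
    roc_auc,
)


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _simulate_survival(rng, n=200, beta=1.0):
    """Expression-driven exponential survival with ~50% administrative censoring."""
    x = rng.normal(0, 1, n)
    tpm = 2.0 ** np.clip(5 + x, 0, None) - 1
    times = rng.exponential(1.0 / (0.2 * np.exp(beta * x)))
    window = rng.uniform(0.5, 12, n)
    event = times <= window
    observed = np.minimum(times, window)
    genes = np.vstack([tpm, 2.0 ** rng.normal(5, 1, n) - 1])
    expr = _expr(genes, ["hit", "noise"])
    idx = expr.sample_ids
    return expr, pd.Series(observed, index=idx), pd.Series(event, index=idx)


class TestCoxFilter:
    def test_null_gene_retained_near_alpha(self):
        retained = 0
        sims = 40
        for seed in range(sims):
            rng = np.random.default_rng(seed)
            expr, t, e = _simulate_survival(rng, n=100, beta=0.0)
            res = cox_univariate_filter(expr, t, e, genes=["hit"])
            retained += bool(res["selected"].iloc[0])
        assert retained / sims <= 0.15

    def test_planted_hazard_gene_retained(self):
        retained = 0
        sims = 20
        for seed in range(sims):
            rng = np.random.default_rng(1000 + seed)
            expr, t, e = _simulate_survival(rng, n=200, beta=1.0)
            res = cox_univariate_filter(expr, t, e, genes=["hit"])
            retained += bool(res["selected"].iloc[0])
        assert retained >= 0.95 * sims

    def test_constant_gene_skipped(self, rng):
        expr, t, e = _simulate_survival(rng)
        flat = ExpressionMatrix(
            pd.concat(
                [expr.tpm, pd.DataFrame([[7.0] * len(t)], index=["flat"],
                                        columns=expr.sample_ids)]
            )
        )
        res = cox_univariate_filter(flat, t, e)
        assert "flat" not in res.index

    def test_all_censored_rejected(self, rng):
        expr, t, e = _simulate_survival(rng)
        with pytest.raises(ValidationError):
            cox_univariate_filter(expr, t, e & False)


class TestLogisticBackward:
    def test_perfectly_predictive_gene_flagged_regularized(self):
        rng = np.random.default_rng(0)
        y = pd.Series(np.r_[np.zeros(20), np.ones(20)].astype(int))
        tpm = np.vstack([
            np.r_[np.full(20, 1.0), np.full(20, 100.0)],
            rng.uniform(1, 50, 40),
        ])
        expr = _expr(tpm, ["sep", "noise"])
        y.index = expr.sample_ids
        model = fit_logistic_backward(expr, y, ["sep", "noise"])
        assert model.regularized
        assert "sep" in model.selected_genes
        # the separation direction must survive the ridge fit
        assert model.coefficients["sep"] > 0

    def test_noise_genes_mostly_eliminated(self):
        kept = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = _expr(rng.uniform(1, 50, (10, 200)))
            y = pd.Series(rng.integers(0, 2, 200), index=expr.sample_ids)
            model = fit_logistic_backward(expr, y, expr.gene_ids)
            kept.append(len(model.selected_genes))
        assert np.median(kept) <= 2

    def test_single_class_rejected(self, rng):
        expr = _expr(rng.uniform(1, 50, (3, 20)))
        y = pd.Series(np.ones(20, dtype=int), index=expr.sample_ids)
        with pytest.raises(ValidationError):
            fit_logistic_backward(expr, y, expr.gene_ids)


class TestRiskScore:
    def test_zero_predictor_gives_half(self, rng):
        expr = _expr(rng.uniform(1, 50, (2, 5)))
        model = RiskModel(selected_genes=[], intercept=0.0, coefficients={})
        assert np.allclose(model.risk_score(expr), 0.5)

    def test_monotone_in_positive_beta_gene(self):
        tpm = np.vstack([np.linspace(1, 100, 10), np.full(10, 5.0)])
        expr = _expr(tpm, ["up", "flat"])
        model = RiskModel(
            selected_genes=["up"], intercept=-2.0, coefficients={"up": 1.5}
        )
        scores = model.risk_score(expr)
        assert (np.diff(scores.to_numpy()) > 0).all()
        assert ((scores > 0) & (scores < 1)).all()

    def test_hand_arithmetic_three_gene_toy(self):
        tpm = np.array(
            [[1.0, 3.0, 7.0, 0.0, 15.0],
             [2.0, 2.0, 2.0, 2.0, 2.0],
             [0.0, 1.0, 0.0, 4.0, 9.0]]
        )
        expr = _expr(tpm, ["a", "b", "c"])
        betas = {"a": 0.8, "b": -1.1, "c": 0.3}
        model = RiskModel(selected_genes=["a", "b", "c"], intercept=0.4, coefficients=betas)
        logx = np.log2(tpm + 1)
        for j, s in enumerate(expr.sample_ids):
            eta = 0.4 + 0.8 * logx[0, j] - 1.1 * logx[1, j] + 0.3 * logx[2, j]
            assert model.risk_score(expr)[s] == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_missing_gene_rejected(self, rng):
        expr = _expr(rng.uniform(1, 50, (2, 5)))
        model = RiskModel(selected_genes=["zz"], intercept=0.0, coefficients={"zz": 1.0})
        with pytest.raises(ValidationError):
            model.risk_score(expr)


class TestNomogram:
    def test_largest_covariate_spans_100_and_reference_zero(self):
        spec = build_nomogram(
            {
                "grade": {"G1": 0.0, "G2": 0.5, "G3": 1.0},
                "neoadjuvant": {"no": 0.0, "yes": 2.0},
            },
            intercept=-1.0,
        )
        assert max(spec.points["neoadjuvant"].values()) == pytest.approx(100.0)
        assert min(spec.points["grade"].values()) == 0.0
        assert max(spec.points["grade"].values()) == pytest.approx(50.0)

    def test_total_points_reproduce_model_probability(self, rng):
        for _ in range(20):
            covs = {}
            for c in range(3):
                levels = {f"L{i}": float(rng.normal(0, 2)) for i in range(3)}
                covs[f"cov{c}"] = levels
            intercept = float(rng.normal())
            spec = build_nomogram(covs, intercept)
            choice = {c: list(covs[c])[int(rng.integers(3))] for c in covs}
            eta = intercept + sum(covs[c][l] for c, l in choice.items())
            direct = 1 / (1 + np.exp(-eta))
            via_points = spec.predicted_probability(spec.total_points(choice))
            assert via_points == pytest.approx(direct, abs=1e-9)

    def test_zero_range_covariate_excluded(self):
        spec = build_nomogram(
            {"flat": {"a": 1.0, "b": 1.0}, "ok": {"x": 0.0, "y": 1.0}}, intercept=0.0
        )
        assert "flat" not in spec.points


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc(np.r_[np.zeros(5), np.ones(5)], np.r_[np.zeros(5), np.ones(5)] > 0)
        assert res.auc == 1.0

    def test_chance_level(self, rng):
        aucs = [
            roc_auc(rng.uniform(size=200), rng.integers(0, 2, 200) > 0).auc
            for _ in range(10)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 10), size=30)  # with ties
            labels = rng.integers(0, 2, 30) > 0
            if labels.all() or not labels.any():
                continue
            res = roc_auc(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_complement_identity(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50) > 0
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            roc_auc(rng.uniform(size=10), np.ones(10, dtype=bool))


class TestPlantedSignalPipeline:
    def test_risk_model_recovers_planted_signature(self, small_cohort):
        """Cox filter + logistic backward elimination on the synthetic cohort
        yields a discriminative risk score for vital status."""
        cdf = small_cohort.clinical.data.set_index("sample_id")
        event = cdf["vital_status"] == "death"
        t = cdf["followup_years"].astype(float)
        candidates = list(small_cohort.truth.survival_coefficients) + list(
            small_cohort.expression.gene_ids[-20:]
        )
        cox = cox_univariate_filter(small_cohort.expression, t, event, genes=candidates)
        selected = cox[cox["selected"]].index.tolist()
        assert set(selected) & set(small_cohort.truth.survival_coefficients)
        keep = cdf["vital_status"].isin(["alive", "death"])
        outcome = (cdf.loc[keep, "vital_status"] == "death").astype(int)
        model = fit_logistic_backward(small_cohort.expression, outcome, selected)
        scores = model.risk_score(small_cohort.expression)
        res = roc_auc(scores.loc[outcome.index], outcome.astype(bool))
        assert res.auc >= 0.8
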