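"""Kaplan-Meier, log-rank, Cox regression, LASSO path, risk scores, AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernaforge.errors import InvalidArgumentError
from cernaforge.prognosis import (breslow_loglik, cox_univariate, fit_cox,
                                  km_curve, lasso_cox, logrank,
                                  median_split_survival, risk_scores,
                                  td_auc, RiskModel)
from cernaforge.synth import gen_survival

from _oracles import oracle_km_no_censoring, oracle_logrank


def _surv(times, events, **cov):
    df = pd.DataFrame({"sample": [f"P{i}" for i in range(len(times))],
                       "time": times, "event": events})
    for k, v in cov.items():
        df[k] = v
    return df


def _cohort(n, betas, censor, seed, n_genes=None):
    genes = sorted(betas) if n_genes is None else [f"g{i}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(rng.standard_normal((n, len(genes))), columns=genes)
    return gen_survival(n, betas, expr, censor, seed=seed + 1)


class TestKaplanMeier:
    def test_four_distinct_events_step_down_quarters(self):
        t, s = km_curve(_surv([1, 2, 3, 4], [1, 1, 1, 1]))
        steps = dict(zip(t, s))
        assert steps[1] == pytest.approx(0.75) and steps[2] == pytest.approx(0.5)
        assert steps[3] == pytest.approx(0.25) and steps[4] == pytest.approx(0.0)
        assert steps[0] == 1.0

    def test_all_censored_flat_one(self):
        _, s = km_curve(_surv([1, 2, 3], [0, 0, 0]))
        assert (s == 1.0).all()

    def test_single_subject_drops_to_zero(self):
        t, s = km_curve(_surv([5.0], [1]))
        assert s[-1] == 0.0 and t[-1] == 5.0

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(2.0, size=200)
        t, s = km_curve(_surv(times, np.ones(200, dtype=int)))
        ot, os_ = oracle_km_no_censoring(times)
        np.testing.assert_allclose(s[1:], os_, atol=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(InvalidArgumentError):
            km_curve(_surv([0.0, 1.0], [1, 1]))


class TestLogrank:
    def test_identical_groups_null(self):
        g = _surv([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank(g, g.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_six_subjects(self):
        """O-E/V arithmetic: A events at 1 and 3 (censored 5), B events at
        2 and 6 (censored 4) gives chi2 = 0.36/0.74."""
        a = _surv([1, 3, 5], [1, 1, 0])
        b = _surv([2, 4, 6], [1, 0, 1])
        chi2, p = logrank(a, b)
        assert chi2 == pytest.approx(0.36 / 0.74, rel=1e-9)
        assert chi2 == pytest.approx(
            oracle_logrank([1, 3, 5], [1, 1, 0], [2, 4, 6], [1, 0, 1]), rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(0.36 / 0.74, 1), rel=1e-9)

    def test_no_events_warns_p_one(self):
        a = _surv([1, 2], [0, 0])
        b = _surv([3, 4], [0, 0])
        with pytest.warns(UserWarning):
            chi2, p = logrank(a, b)
        assert p == 1.0

    def test_power_under_planted_hazard_ratio(self):
        """HR=3 with 200 per arm is detected at alpha=0.05 nearly always."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(1.0 / 3.0, 200)
            _, p = logrank(_surv(ta, np.ones(200, int)),
                           _surv(tb, np.ones(200, int)))
            hits += p < 0.05
        assert hits / n_rep >= 0.95


class TestCox:
    def test_duplicated_dataset_same_beta(self):
        df = _cohort(120, {"g": 0.7}, 0.2, seed=5)
        b1, *_ = cox_univariate(df, "g")
        b2, *_ = cox_univariate(pd.concat([df, df], ignore_index=True), "g")
        assert b1 == pytest.approx(b2, abs=1e-6)

    def test_recovers_planted_beta_at_n2000(self):
        df = _cohort(2000, {"g": 1.0}, 0.2, seed=7)
        beta, hr, ci, p = cox_univariate(df, "g")
        assert abs(beta - 1.0) <= 0.15
        assert ci[0] < hr < ci[1]

    def test_partial_likelihood_maximized(self):
        df = _cohort(300, {"g": 0.8}, 0.3, seed=9)
        X = df[["g"]].to_numpy()
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        beta, _, ll = fit_cox(X, t, e)
        assert ll >= breslow_loglik(np.zeros(1), X, t, e)

    def test_null_wald_p_uniform(self):
        """Covariate independent of survival: p-values ~ U(0,1)."""
        ps = []
        for seed in range(120):
            df = _cohort(100, {"g": 0.0}, 0.2, seed=seed * 3 + 1)
            ps.append(cox_univariate(df, "g")[3])
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_matches_lifelines_on_continuous_times(self):
        """With no ties Breslow and Efron coincide; cross-check the
        Newton fitter against lifelines."""
        from lifelines import CoxPHFitter
        df = _cohort(250, {"g": 0.6}, 0.25, seed=13)
        beta, se, _ = fit_cox(df[["g"]].to_numpy(), df["time"].to_numpy(),
                              df["event"].to_numpy())
        cph = CoxPHFitter().fit(df[["time", "event", "g"]], "time", "event")
        # agreement limited by lifelines' own stopping tolerance
        assert beta[0] == pytest.approx(cph.params_["g"], abs=1e-4)
        assert se[0] == pytest.approx(cph.standard_errors_["g"], abs=1e-4)

    def test_too_few_events_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cox_univariate(_surv([1, 2, 3], [0, 0, 1], g=[1.0, 2.0, 3.0]), "g")


class TestLassoCox:
    def test_huge_lambda_empties_model(self):
        df = _cohort(150, {"g0": 1.0}, 0.1, seed=21, n_genes=4)
        with pytest.warns(UserWarning):
            m = lasso_cox(df, [f"g{i}" for i in range(4)],
                          lambda_grid=np.array([50.0]), seed=0)
            assert m.genes == [] and m.betas == []
            risk_scores(m, df[[f"g{i}" for i in range(4)]])

    def test_zero_lambda_matches_newton_fit(self):
        df = _cohort(500, {"g0": 0.8, "g1": -0.5}, 0.2, seed=23, n_genes=2)
        beta, *_ = fit_cox(df[["g0", "g1"]].to_numpy(), df["time"].to_numpy(),
                           df["event"].to_numpy())
        m = lasso_cox(df, ["g0", "g1"], lambda_grid=np.array([1e-9]), seed=0)
        assert m.genes == ["g0", "g1"]
        np.testing.assert_allclose(m.betas, beta, atol=1e-3)

    def test_support_recovery_with_one_se_rule(self):
        """3 planted genes (beta=1) among 7 nulls, n=400: the 1-SE rule
        returns exactly the planted support in >= 80% of 50 seeds."""
        planted = {"g0", "g1", "g2"}
        exact = 0
        for seed in range(50):
            df = _cohort(400, {"g0": 1.0, "g1": 1.0, "g2": 1.0}, 0.2,
                         seed=1000 + seed * 7, n_genes=10)
            m = lasso_cox(df, [f"g{i}" for i in range(10)], seed=seed, rule="1se")
            exact += set(m.genes) == planted
        assert exact / 50 >= 0.80

    def test_min_rule_never_misses_planted(self):
        planted = {"g0", "g1", "g2"}
        for seed in range(10):
            df = _cohort(400, {"g0": 1.0, "g1": 1.0, "g2": 1.0}, 0.2,
                         seed=4000 + seed * 11, n_genes=10)
            m = lasso_cox(df, [f"g{i}" for i in range(10)], seed=seed, rule="min")
            assert planted <= set(m.genes)

    def test_path_sparsity_monotone_in_lambda(self):
        df = _cohort(300, {"g0": 1.0, "g1": 0.7}, 0.2, seed=31, n_genes=6)
        grid = np.array([1e-4, 0.01, 0.05, 0.1, 0.3, 1.0])
        sizes = []
        for lam in grid:
            m = lasso_cox(df, [f"g{i}" for i in range(6)],
                          lambda_grid=np.array([lam]), seed=0)
            sizes.append(len(m.genes))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_empty_grid_rejected(self):
        df = _cohort(100, {"g0": 1.0}, 0.1, seed=37, n_genes=2)
        with pytest.raises(InvalidArgumentError):
            lasso_cox(df, ["g0", "g1"], lambda_grid=np.array([]))


class TestRiskScores:
    def test_linear_score_arithmetic(self):
        m = RiskModel(["a", "b", "c"], [0.5, -0.3, 0.2], cutoff=0.0, lambda_=0.1)
        expr = pd.DataFrame([[1.0, 1.0, 1.0]], columns=["a", "b", "c"], index=["s1"])
        scores, labels = risk_scores(m, expr)
        assert scores["s1"] == pytest.approx(0.4)
        assert labels["s1"] == "high"

    def test_empty_model_warns_degenerate(self):
        m = RiskModel([], [], cutoff=0.0, lambda_=1.0)
        expr = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.warns(UserWarning):
            scores, _ = risk_scores(m, expr)
        assert (scores == 0).all()

    def test_missing_gene_rejected(self):
        m = RiskModel(["zz"], [1.0], cutoff=0.0, lambda_=0.1)
        with pytest.raises(InvalidArgumentError):
            risk_scores(m, pd.DataFrame([[1.0]], columns=["a"]))

    def test_monotone_transform_preserves_labels(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        m1 = RiskModel(["g"], [1.0], cutoff=float(np.median(x)), lambda_=0.1)
        m2 = RiskModel(["g"], [2.0], cutoff=float(np.median(2 * x)), lambda_=0.1)
        e = pd.DataFrame({"g": x})
        _, l1 = risk_scores(m1, e)
        _, l2 = risk_scores(m2, e)
        assert (l1 == l2).all()


class TestTimeDependentAUC:
    def test_perfect_predictor_auc_one(self):
        n = 120
        times = np.linspace(0.5, 10.0, n)
        df = _surv(times, np.ones(n, int))
        scores = -times  # earlier event = higher risk
        aucs = td_auc(df, scores, [2.0, 5.0, 8.0])
        assert all(v == pytest.approx(1.0) for v in aucs.values())

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(8)
        df = _cohort(1000, {"g": 0.0}, 0.2, seed=41)
        aucs = td_auc(df, rng.standard_normal(1000), [3.0])
        assert abs(aucs[3.0] - 0.5) <= 0.05

    def test_constant_scores_half_by_convention(self):
        df = _surv([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        with pytest.warns(UserWarning):
            aucs = td_auc(df, np.ones(5), [2.5])
        assert aucs[2.5] == 0.5

    def test_horizon_beyond_followup_missing(self):
        df = _surv([1, 2, 3], [1, 1, 1], )
        with pytest.warns(UserWarning):
            aucs = td_auc(df, np.array([3.0, 2.0, 1.0]), [10.0])
        assert np.isnan(aucs[10.0])


class TestMedianSplit:
    def test_planted_gene_separates_groups(self):
        """beta=1 at n=500: the median split should find the difference."""
        hits = 0
        for seed in range(20):
            df = _cohort(500, {"g": 1.0}, 0.2, seed=600 + seed * 13)
            _, p = median_split_survival(df, "g")
            hits += p < 0.05
        assert hits / 20 >= 0.90

    def test_null_gene_p_uniform(self):
        ps = []
        for seed in range(100):
            df = _cohort(80, {"g": 0.0}, 0.2, seed=900 + seed * 17)
            ps.append(median_split_survival(df, "g")[1])
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_balanced_four_samples(self):
        df = _surv([1, 2, 3, 4], [1, 1, 1, 1], g=[1.0, 2.0, 3.0, 4.0])
        curves, _ = median_split_survival(df, "g")
        # 2 above median, 2 at-or-below
        assert len(curves["high"][0]) == 3 and len(curves["low"][0]) == 3

    def test_constant_expression_rejected(self):
        df = _surv([1, 2, 3, 4], [1, 1, 1, 1], g=[2.0] * 4)
        with pytest.raises(InvalidArgumentError):
            median_split_survival(df, "g")
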