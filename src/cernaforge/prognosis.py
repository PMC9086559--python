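"""Survival screening and the penalized-Cox risk-score signature.

The stage mirrors the standard prognostic-signature workflow: per-gene
median-split Kaplan-Meier curves with log-rank tests, univariate Cox
proportional-hazards screening, L1-penalized (LASSO) Cox regression with
cross-validated penalty selection to pick the gene combination, a linear
risk score with a median cutoff splitting patients into high- and
low-risk groups, and cumulative/dynamic time-dependent ROC AUC with
inverse-probability-of-censoring weighting at fixed horizons.

The univariate/unpenalized Cox fitter here is a Newton-Raphson maximizer
of the Breslow partial likelihood (ties handled by Breslow's
approximation); the penalized path is delegated to the glmnet-style
coordinate-descent solver in scikit-survival, with the unpenalized fitter
serving as its zero-penalty cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .errors import InvalidArgumentError, NumericError


@dataclass
class RiskModel:
    """A fitted risk-score signature: score(x) = sum_i beta_i * x_i."""

    genes: list[str]
    betas: list[float]
    cutoff: float                 # median training risk score
    lambda_: float                # penalty at which the model was taken
    rule: str = "min"             # CV selection rule used
    auc: dict[float, float] = field(default_factory=dict)


def _check_surv(df: pd.DataFrame) -> None:
    if len(df) == 0:
        raise InvalidArgumentError("empty survival table")
    if (df["time"] <= 0).any():
        raise InvalidArgumentError("survival times must be > 0")
    if not set(df["event"].unique()) <= {0, 1}:
        raise InvalidArgumentError("event indicator must be 0/1")


# ----------------------------------------------------------- Kaplan-Meier

def km_curve(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (times, S(t)) with S(0)=1."""
    _check_surv(df)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance); returns (chi2, p)."""
    _check_surv(group_a)
    _check_surv(group_b)
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, p = 1")
        return 0.0, 1.0
    res = logrank_test(group_a["time"], group_b["time"],
                       group_a["event"], group_b["event"])
    return float(res.test_statistic), float(res.p_value)


# ------------------------------------------------------------ Breslow Cox

def breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """Breslow partial log-likelihood at ``beta``."""
    order = np.argsort(-time, kind="stable")
    Xo, to, eo = X[order], time[order], event[order]
    eta = Xo @ beta
    m = eta.max()
    cum = np.cumsum(np.exp(eta - m))  # risk-set sums walking from latest time
    ll = 0.0
    i = 0
    n = len(to)
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        risk = cum[j - 1]  # everyone with time >= t_i
        for k in range(i, j):
            if eo[k]:
                ll += eta[k] - (np.log(risk) + m)
        i = j
    return float(ll)


def fit_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
            max_iter: int = 60, tol: float = 1e-9
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton-Raphson Cox fit with Breslow ties.

    Returns (beta, standard errors, partial log-likelihood).  Raises a
    numeric error on non-convergence; a diverging (monotone-likelihood)
    fit is flagged with a warning.
    """
    if event.sum() < 2:
        raise InvalidArgumentError("Cox fit requires at least two events")
    n, p = X.shape
    beta = np.zeros(p)

    order = np.argsort(-time, kind="stable")
    Xo, to, eo = X[order], time[order], event[order].astype(bool)

    # event blocks share risk sets; precompute tie-block boundaries
    blocks = []
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        blocks.append((i, j))
        i = j

    def grad_hess(b):
        eta = Xo @ b
        w = np.exp(eta - eta.max())
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * Xo, axis=0)
        cwxx = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
        g = np.zeros(p)
        h = np.zeros((p, p))
        for (i0, j0) in blocks:
            d = eo[i0:j0].sum()
            if d == 0:
                continue
            s0 = cw[j0 - 1]
            s1 = cwx[j0 - 1]
            s2 = cwxx[j0 - 1]
            xbar = s1 / s0
            g += Xo[i0:j0][eo[i0:j0]].sum(axis=0) - d * xbar
            h -= d * (s2 / s0 - np.outer(xbar, xbar))
        return g, h

    ll_prev = breslow_loglik(beta, X, time, event)
    for _ in range(max_iter):
        g, h = grad_hess(beta)
        try:
            step = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError as exc:
            raise NumericError(f"singular Hessian in Cox fit: {exc}") from exc
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll = breslow_loglik(cand, X, time, event)
            if ll >= ll_prev - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.abs(g).max() < tol or abs(ll - ll_prev) < tol * (abs(ll_prev) + 1):
            ll_prev = ll
            break
        ll_prev = ll
    else:
        if np.abs(grad_hess(beta)[0]).max() > 1e-4:
            raise NumericError(
                f"Cox Newton-Raphson did not converge in {max_iter} iterations "
                f"(max |gradient| = {np.abs(grad_hess(beta)[0]).max():.3g})")
    if np.abs(beta).max() > 15:
        warnings.warn("Cox estimate diverging; likely monotone likelihood "
                      "(perfect separation) - estimate flagged")
    _, h = grad_hess(beta)
    cov = np.linalg.inv(-h)
    se = np.sqrt(np.diag(cov))
    return beta, se, ll_prev


def cox_univariate(df: pd.DataFrame, gene: str
                   ) -> tuple[float, float, tuple[float, float], float]:
    """Univariate Cox regression of survival on one gene's expression.

    Returns (beta, hazard ratio, Wald 95% CI on the HR, Wald p).
    """
    _check_surv(df)
    if gene not in df.columns:
        raise InvalidArgumentError(f"gene {gene!r} not in survival table")
    X = df[[gene]].to_numpy(dtype=float)
    beta, se, _ = fit_cox(X, df["time"].to_numpy(dtype=float),
                          df["event"].to_numpy(dtype=int))
    b, s = float(beta[0]), float(se[0])
    z = b / s
    p = 2 * stats.norm.sf(abs(z))
    ci = (float(np.exp(b - 1.959963984540054 * s)), float(np.exp(b + 1.959963984540054 * s)))
    return b, float(np.exp(b)), ci, float(p)


# ------------------------------------------------------------- LASSO Cox

def lasso_cox(df: pd.DataFrame, genes: list[str],
              lambda_grid: np.ndarray | None = None, n_folds: int = 5,
              seed: int = 0, rule: str = "min") -> RiskModel:
    """L1-penalized Cox regression with cross-validated penalty choice.

    The coordinate-descent coefficient path is computed by the
    glmnet-style solver; the penalty is chosen by K-fold cross-validated
    partial-likelihood deviance (``rule="min"``: minimizing penalty;
    ``rule="1se"``: largest penalty within one standard error of the
    minimum).  Genes with zero coefficient at the chosen penalty are
    dropped.  The returned cutoff is the median training risk score.
    """
    _check_surv(df)
    if lambda_grid is not None and len(lambda_grid) == 0:
        raise InvalidArgumentError("empty lambda grid")
    if rule not in ("min", "1se"):
        raise InvalidArgumentError("rule must be 'min' or '1se'")
    if int(df["event"].sum()) < n_folds:
        raise InvalidArgumentError("need at least n_folds events")
    X = df[genes].to_numpy(dtype=float)
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if lambda_grid is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.001, n_alphas=60)
        path.fit(X, y)
        alphas = np.asarray(path.alphas_)
    else:
        alphas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    folds = np.array_split(order, n_folds)

    dev = np.full((n_folds, len(alphas)), np.nan)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        if event[test_idx].sum() < 1 or event[train_idx].sum() < 2:
            continue
        fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False)
        fit.fit(X[train_idx], y[train_idx])
        fitted = {a: i for i, a in enumerate(fit.alphas_)}
        for i, a in enumerate(alphas):
            j = fitted.get(a)
            if j is None:
                continue
            beta = fit.coef_[:, j]
            dev[k, i] = -2.0 * breslow_loglik(beta, X[test_idx], time[test_idx],
                                              event[test_idx])
    mean_dev = np.nanmean(dev, axis=0)
    if np.all(np.isnan(mean_dev)):
        raise NumericError("cross-validation produced no usable folds")
    i_min = int(np.nanargmin(mean_dev))
    if rule == "1se":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(dev), axis=0))
        bound = mean_dev[i_min] + se_dev[i_min]
        candidates = [i for i in range(i_min + 1) if mean_dev[i] <= bound]
        i_sel = min(candidates) if candidates else i_min  # alphas descend: min index = largest
    else:
        i_sel = i_min
    alpha_sel = float(alphas[i_sel])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False)
    final.fit(X, y)
    j = {a: i for i, a in enumerate(final.alphas_)}.get(alpha_sel)
    if j is None:
        raise NumericError(f"selected penalty {alpha_sel} missing from the final path")
    coef = final.coef_[:, j]
    nz = np.nonzero(coef)[0]
    model = RiskModel(genes=[genes[i] for i in nz], betas=[float(coef[i]) for i in nz],
                      cutoff=0.0, lambda_=alpha_sel, rule=rule)
    scores = X[:, nz] @ coef[nz] if len(nz) else np.zeros(len(df))
    model.cutoff = float(np.median(scores))
    return model


# ------------------------------------------------------------ risk scores

def risk_scores(model: RiskModel, expr: pd.DataFrame
                ) -> tuple[pd.Series, pd.Series]:
    """Per-sample risk score sum(beta * x) and high/low labels.

    ``expr`` is samples x genes.  A sample is ``high`` iff its score
    exceeds the model's training-median cutoff.
    """
    missing = [g for g in model.genes if g not in expr.columns]
    if missing:
        raise InvalidArgumentError(f"genes missing from expression: {missing}")
    if not model.genes:
        warnings.warn("empty model: all risk scores are 0; split is degenerate")
        scores = pd.Series(0.0, index=expr.index, name="risk_score")
    else:
        scores = pd.Series(expr[model.genes].to_numpy(dtype=float) @ np.asarray(model.betas),
                           index=expr.index, name="risk_score")
        if scores.nunique() == 1:
            warnings.warn("constant risk scores; split is degenerate")
    labels = pd.Series(np.where(scores > model.cutoff, "high", "low"),
                       index=expr.index, name="risk_group")
    return scores, labels


# --------------------------------------------------------------- time AUC

def td_auc(df: pd.DataFrame, scores: np.ndarray | pd.Series,
           horizons: list[float]) -> dict[float, float]:
    """Cumulative-case/dynamic-control AUC with IPCW at each horizon.

    Horizons with no case or no control, or beyond follow-up, are
    reported as NaN with a warning.  Constant scores give 0.5 by the tie
    convention.
    """
    _check_surv(df)
    scores = np.asarray(scores, dtype=float)
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    out: dict[float, float] = {}
    if np.all(scores == scores[0]):
        warnings.warn("constant scores: AUC = 0.5 at every horizon by convention")
        return {float(h): 0.5 for h in horizons}
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    for h in horizons:
        h = float(h)
        cases = (time <= h) & (event == 1)
        controls = time > h
        if cases.sum() == 0 or controls.sum() == 0 or h >= time.max():
            warnings.warn(f"horizon {h}: no cases or no controls; AUC undefined")
            out[h] = float("nan")
            continue
        auc, _ = cumulative_dynamic_auc(y, y, scores, [h])
        out[h] = float(auc[0])
    return out


# ------------------------------------------------------------ median split

def median_split_survival(df: pd.DataFrame, gene: str
                          ) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], float]:
    """KM curves and log-rank p after a median split on one gene.

    Samples strictly above the median go to the ``high`` group; ties go
    low.  Constant expression cannot be split.
    """
    _check_surv(df)
    if len(df) < 4:
        raise InvalidArgumentError("median split needs at least 4 samples")
    if gene not in df.columns:
        raise InvalidArgumentError(f"gene {gene!r} not in survival table")
    x = df[gene].to_numpy(dtype=float)
    med = float(np.median(x))
    high = x > med
    if high.sum() == 0 or (~high).sum() == 0:
        raise InvalidArgumentError(f"cannot split: {gene!r} expression is (near-)constant")
    df_hi, df_lo = df[high], df[~high]
    curves = {"high": km_curve(df_hi), "low": km_curve(df_lo)}
    _, p = logrank(df_hi, df_lo)
    return curves, p
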