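"""Logistic risk model for occult lymph-node metastases.

Fits a binary logistic regression of nodal status on clinicopathological
covariates (including the digital tumor bud count), optionally with
forward stepwise selection by likelihood-ratio test, and evaluates it by:

* apparent and stratified k-fold cross-validated AUC with DeLong
  confidence intervals (selection re-run inside each fold so the CV
  estimate is honest);
* Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk;
* a quantile-binned calibration table with exact binomial intervals.

Covariates must be numeric columns of the cohort table (dummy-code
categoricals first).  Maximum-likelihood estimation is by iteratively
reweighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RiskModel",
    "ROCResult",
    "SeparationError",
    "fit_logistic",
    "forward_select",
    "roc_auc",
    "cross_validated_auc",
    "hosmer_lemeshow",
    "calibration_curve",
]


class SeparationError(RuntimeError):
    """Logistic fit did not converge (complete or quasi-complete separation)."""


@dataclass(frozen=True)
class RiskModel:
    variables: tuple[str, ...]
    coefficients: np.ndarray  # log-odds per variable, same order
    intercept: float
    covariance: np.ndarray  # (p+1) x (p+1), intercept first
    n: int
    log_likelihood: float
    n_iterations: int

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(cohort), self.intercept)
        for name, coef in zip(self.variables, self.coefficients):
            lp = lp + coef * cohort[name].to_numpy(dtype=float)
        return lp

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(cohort)))


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("confidence interval must contain the AUC")


def _design(cohort: pd.DataFrame, variables: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for v in variables:
        x = cohort[v].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"variable {v!r} is constant")
        cols.append(x)
    return np.column_stack(cols)


def fit_logistic(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str = "node_binary",
) -> RiskModel:
    """Maximum-likelihood logistic regression (IRLS).

    Requires at least 10 patients, both outcome classes present, and no
    constant covariate.  The covariance of the estimates is the inverse
    observed information.  Complete separation raises
    :class:`SeparationError` naming the most implicated variable.
    """
    if len(cohort) < 10:
        raise ValueError("need at least 10 patients")
    y = cohort[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = _design(cohort, variables)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    params = np.asarray(res.params)
    fitted = np.asarray(res.fittedvalues)
    # separation: fitted probabilities collapse onto the labels
    if np.abs(params).max() > 25 and np.all((fitted > 0.5) == (y > 0.5)):
        worst = ["(intercept)", *variables][int(np.argmax(np.abs(params)))]
        raise SeparationError(
            f"logistic fit did not converge; separation driven by {worst}"
        )
    return RiskModel(
        variables=tuple(variables),
        coefficients=params[1:],
        intercept=float(params[0]),
        covariance=np.asarray(res.cov_params()),
        n=len(cohort),
        log_likelihood=float(res.llf),
        n_iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
    )


def forward_select(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "node_binary",
    entry_p: float = 0.05,
) -> RiskModel:
    """Forward stepwise selection by likelihood-ratio test.

    At each step the candidate with the smallest LR p-value is added if
    that p-value is below ``entry_p``; otherwise selection stops.  Ties
    break deterministically in candidate-list order.  May return an
    intercept-only model.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    selected: list[str] = []
    remaining = list(candidates)
    current = fit_logistic(cohort, selected, outcome)
    while remaining:
        best_p, best_var, best_model = np.inf, None, None
        for var in remaining:
            try:
                trial = fit_logistic(cohort, selected + [var], outcome)
            except (np.linalg.LinAlgError, ValueError, SeparationError):
                continue
            lr = 2.0 * (trial.log_likelihood - current.log_likelihood)
            p = stats.chi2.sf(max(lr, 0.0), df=1)
            if p < best_p:
                best_p, best_var, best_model = p, var, trial
        if best_var is None or best_p >= entry_p:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        current = best_model
    return current


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> ROCResult:
    """AUC with a DeLong confidence interval.

    The AUC is the Mann-Whitney U statistic over positive/negative pairs
    with ties counted one half; the variance is DeLong's structural-
    component estimate and the 95% CI uses a normal approximation
    truncated to [0, 1].
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v01 = (tz[:m] - tx) / n  # per-positive structural components
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = stats.norm.ppf(0.975) * np.sqrt(var)
    lo = min(max(auc - half, 0.0), auc)
    hi = max(min(auc + half, 1.0), auc)
    return ROCResult(
        auc=float(auc), ci_low=float(lo), ci_high=float(hi),
        method="DeLong", n_pos=m, n_neg=n,
    )


def cross_validated_auc(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str = "node_binary",
    k: int = 10,
    seed: int = 0,
    select: str | None = None,
    entry_p: float = 0.05,
) -> ROCResult:
    """Stratified k-fold cross-validated AUC on pooled out-of-fold predictions.

    With ``select="forward"`` the forward selection is re-run on every
    training fold (using ``variables`` as the candidate list), so the
    selection optimism is included in the estimate.  Pooled out-of-fold
    probabilities give a single AUC with a DeLong CI.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = cohort[outcome].to_numpy(dtype=int)
    n_min = min(np.count_nonzero(y == 0), np.count_nonzero(y == 1))
    if n_min < k:
        raise ValueError(
            f"rarest class has {n_min} members; cannot stratify into {k} folds — use smaller k"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(cohort), np.nan)
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        train = cohort.iloc[train_idx]
        if select == "forward":
            model = forward_select(train, list(variables), outcome, entry_p)
        else:
            model = fit_logistic(train, list(variables), outcome)
        oof[test_idx] = model.predict_proba(cohort.iloc[test_idx])
    return roc_auc(y, oof)


def hosmer_lemeshow(
    labels: np.ndarray, probs: np.ndarray, g: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over g quantile bins of predicted risk.

    Returns (chi2, df, p) with df = (number of effective bins) - 2.  Ties
    in the predicted probabilities stay in one bin; if tie-merging reduces
    the number of bins, the degrees of freedom shrink accordingly (with a
    warning).
    """
    if g < 3:
        raise ValueError("g must be >= 3")
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if len(y) < 5 * g:
        raise ValueError(f"need at least {5 * g} observations for g={g}")
    bins = pd.qcut(p, q=g, duplicates="drop")
    n_bins = bins.categories.size
    if n_bins < g:
        warnings.warn(
            f"tie-merging reduced {g} bins to {n_bins}; df lowered accordingly",
            stacklevel=2,
        )
    df_tab = pd.DataFrame({"y": y, "p": p, "bin": bins})
    grouped = df_tab.groupby("bin", observed=True)
    obs = grouped["y"].sum().to_numpy()
    exp = grouped["p"].sum().to_numpy()
    n_b = grouped.size().to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / (exp * (1.0 - exp / n_b))
    chi2 = float(np.nansum(terms))
    # df floors at 1 when ties collapse nearly all bins (degenerate but legal)
    dof = max(int(n_bins - 2), 1)
    return chi2, dof, float(stats.chi2.sf(chi2, dof))


def calibration_curve(
    labels: np.ndarray, probs: np.ndarray, bins: int = 10
) -> pd.DataFrame:
    """Observed vs predicted risk per quantile bin, with exact binomial CIs.

    Columns: mean_predicted, observed_fraction, ci_low, ci_high
    (Clopper-Pearson 95%), n.  Constant probabilities collapse to a single
    bin; an empty input yields an empty table.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if len(y) == 0:
        return pd.DataFrame(
            columns=["mean_predicted", "observed_fraction", "ci_low", "ci_high", "n"]
        )
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.ptp(p) == 0:
        groups = pd.Series(np.zeros(len(p), dtype=int))
    else:
        groups = pd.qcut(p, q=min(bins, len(np.unique(p))), labels=False, duplicates="drop")
    rows = []
    for _, idx in pd.Series(np.arange(len(p))).groupby(groups):
        yy, pp = y[idx], p[idx]
        k, nb = int(yy.sum()), len(yy)
        lo = stats.beta.ppf(0.025, k, nb - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(0.975, k + 1, nb - k) if k < nb else 1.0
        rows.append((pp.mean(), k / nb, lo, hi, nb))
    return pd.DataFrame(
        rows, columns=["mean_predicted", "observed_fraction", "ci_low", "ci_high", "n"]
    )
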