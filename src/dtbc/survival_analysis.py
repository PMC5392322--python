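"""Survival analysis of the digital tumor bud count.

Tertile assignment of the bud count, Kaplan-Meier curves with at-risk
tables at 0/1/3/5 years, log-rank tests, univariate and multivariate Cox
proportional-hazards models (the multivariate model with forward entry
and conditional likelihood-ratio removal), and the bud-size-vs-prognosis
sweep that refits a tertile Cox model for bud ceilings of 1..20 cells.

Partial-likelihood maximization and tie handling (Efron) are delegated to
lifelines; endpoints are overall survival (``os_time``/``os_event``) and
progression-free survival (``pfs_time``/``pfs_event``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CoxResult",
    "SweepPrognosis",
    "assign_tertiles",
    "kaplan_meier",
    "logrank",
    "cox_fit",
    "cox_forward",
    "budsize_prognosis_sweep",
]

AT_RISK_YEARS = (0.0, 1.0, 3.0, 5.0)

_ENDPOINTS = {"os": ("os_time", "os_event"), "pfs": ("pfs_time", "pfs_event")}


def assign_tertiles(values: np.ndarray) -> np.ndarray:
    """Split a numeric vector into tertiles (labels 1, 2, 3).

    Cut points are the 33 1/3 and 66 2/3 empirical percentiles
    (linear-interpolation quantiles); values at or below the first cut get
    tertile 1, values above it up to the second cut get 2, the rest 3.
    Tied values always share a tertile, so group sizes can deviate from
    n/3 by the number of ties at a cut.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct values to form tertiles")
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.ones(len(x), dtype=int)
    labels[x > q1] = 2
    labels[x > q2] = 3
    return labels


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray  # event-time grid (includes 0)
    survival: np.ndarray  # same length, starts at 1, non-increasing
    at_risk: dict[float, int]  # patients still at risk at 0/1/3/5 years
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def kaplan_meier(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier curves per group with at-risk counts at 0/1/3/5 years."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    g = np.asarray(groups) if groups is not None else np.array(["all"] * len(t))
    out: dict[str, SurvivalCurve] = {}
    for label in pd.unique(g):
        sel = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        grid = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = {yr: int(np.count_nonzero(t[sel] >= yr)) for yr in AT_RISK_YEARS}
        out[str(label)] = SurvivalCurve(
            group=str(label),
            times=grid,
            survival=surv,
            at_risk=at_risk,
            censor_times=np.sort(t[sel][e[sel] == 0]),
        )
    return out


def logrank(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, int, float]:
    """Log-rank test across groups; returns (chi2, df, p), df = groups - 1."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    n_groups = pd.unique(g).size
    if n_groups < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if e.sum() < 1:
        raise ValueError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), int(n_groups - 1), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Proportional-hazards fit: per-variable HRs and model summaries."""

    variables: tuple[str, ...]
    table: pd.DataFrame  # index variable; columns hr, ci_low, ci_high, p, log_hr, se
    log_likelihood: float  # log partial likelihood at the optimum
    n: int
    n_events: int

    def hazard_ratio(self, variable: str) -> float:
        return float(self.table.loc[variable, "hr"])


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    try:
        return _ENDPOINTS[endpoint.lower()]
    except KeyError:
        raise ValueError(f"endpoint must be one of {sorted(_ENDPOINTS)}") from None


def cox_fit(
    cohort: pd.DataFrame,
    variables: list[str],
    endpoint: str = "os",
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards model for the chosen endpoint.

    Newton-Raphson partial-likelihood maximization with Efron handling of
    tied event times; Wald confidence intervals and p-values per variable.
    Covariates must be numeric and non-constant.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    if not variables:
        raise ValueError("need at least one covariate")
    time_col, event_col = _endpoint_cols(endpoint)
    df = cohort[[time_col, event_col, *variables]].astype(float)
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event")
    for v in variables:
        if np.ptp(df[v].to_numpy()) == 0:
            raise ValueError(f"covariate {v!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=time_col, event_col=event_col)
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
            "log_hr": summ["coef"],
            "se": summ["se(coef)"],
        }
    )
    return CoxResult(
        variables=tuple(variables),
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


def _null_log_likelihood(cohort: pd.DataFrame, variables: list[str], endpoint: str) -> float:
    """Log partial likelihood of the covariate-free model."""
    fit = cox_fit(cohort, [variables[0]], endpoint)
    cph = CoxPHFitter()
    time_col, event_col = _endpoint_cols(endpoint)
    df = cohort[[time_col, event_col, variables[0]]].astype(float)
    cph.fit(df, duration_col=time_col, event_col=event_col)
    lr = cph.log_likelihood_ratio_test()
    return float(fit.log_likelihood - lr.test_statistic / 2.0)


def cox_forward(
    cohort: pd.DataFrame,
    candidates: list[str],
    endpoint: str = "os",
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> CoxResult | None:
    """Multivariate Cox model built by forward entry with conditional removal.

    At each step the candidate with the smallest likelihood-ratio p-value
    enters if p < ``entry_p``; after every entry each included variable is
    re-tested by LR against the model without it and dropped if its p-value
    exceeds ``removal_p``.  Iterates to a fixed point; ties break in
    candidate order.  Returns ``None`` when no variable qualifies.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    time_col, event_col = _endpoint_cols(endpoint)
    n_events = int(cohort[event_col].sum())
    if n_events < 10:
        warnings.warn(
            f"only {n_events} events; stepwise Cox selection is unstable", stacklevel=2
        )
    ll_null = _null_log_likelihood(cohort, candidates, endpoint)

    def ll_of(varset: list[str]) -> float:
        if not varset:
            return ll_null
        return cox_fit(cohort, varset, endpoint).log_likelihood

    selected: list[str] = []
    remaining = list(candidates)
    while True:
        changed = False
        ll_cur = ll_of(selected)
        best_p, best_var = np.inf, None
        for var in remaining:
            try:
                ll_new = ll_of(selected + [var])
            except Exception:
                continue
            p = stats.chi2.sf(max(2.0 * (ll_new - ll_cur), 0.0), df=1)
            if p < best_p:
                best_p, best_var = p, var
        if best_var is not None and best_p < entry_p:
            selected.append(best_var)
            remaining.remove(best_var)
            changed = True
            # conditional removal: re-test every included variable
            dropped = True
            while dropped and len(selected) > 1:
                dropped = False
                ll_full = ll_of(selected)
                for var in list(selected):
                    reduced = [v for v in selected if v != var]
                    p_rm = stats.chi2.sf(
                        max(2.0 * (ll_full - ll_of(reduced)), 0.0), df=1
                    )
                    if p_rm > removal_p:
                        selected.remove(var)
                        remaining.append(var)
                        dropped = True
                        break
        if not changed:
            break
    if not selected:
        return None
    return cox_fit(cohort, selected, endpoint)


@dataclass(frozen=True)
class SweepPrognosis:
    """Per-bud-ceiling prognostic strength plus its linear trend in size."""

    table: pd.DataFrame  # n_cells, threshold_um2, hr, ci_low, ci_high, p, skipped
    trend_slope: float | None  # least-squares slope of log HR on n_cells
    trend_p: float | None
    trend_stderr: float | None


def budsize_prognosis_sweep(
    sweep_counts: pd.DataFrame,
    cohort: pd.DataFrame,
    endpoint: str = "os",
) -> SweepPrognosis:
    """Prognostic value of the bud count as the bud-size ceiling grows.

    ``sweep_counts`` is the tidy (patient, n_cells, threshold_um2, count)
    table from the bud-definition sweep; ``cohort`` supplies the survival
    columns, matched on ``patient`` against the cohort ``id``.  For every
    ceiling the per-patient count is tertiled and a Cox model with the
    tertile as an ordinal covariate is fitted, giving a hazard ratio per
    tertile increment.  A least-squares regression of log HR on n_cells
    summarizes the trend; a negative slope means small islands carry the
    prognostic signal.  Ceilings whose counts cannot form tertiles are
    flagged and skipped.
    """
    time_col, event_col = _endpoint_cols(endpoint)
    merged = sweep_counts.merge(
        cohort[["id", time_col, event_col]], left_on="patient", right_on="id"
    )
    rows = []
    for n_cells, grp in merged.groupby("n_cells"):
        thr = float(grp["threshold_um2"].iloc[0])
        counts = grp["count"].to_numpy(dtype=float)
        try:
            tert = assign_tertiles(counts)
            if pd.unique(tert).size < 2:
                raise ValueError("degenerate tertiles")
            sub = pd.DataFrame(
                {
                    time_col: grp[time_col].to_numpy(dtype=float),
                    event_col: grp[event_col].to_numpy(dtype=float),
                    "tertile": tert.astype(float),
                }
            )
            fit = cox_fit(sub, ["tertile"], endpoint)
            r = fit.table.loc["tertile"]
            rows.append((int(n_cells), thr, r["hr"], r["ci_low"], r["ci_high"], r["p"], False))
        except Exception as exc:  # degenerate counts for this ceiling
            warnings.warn(f"n_cells={n_cells} skipped: {exc}", stacklevel=2)
            rows.append((int(n_cells), thr, np.nan, np.nan, np.nan, np.nan, True))
    table = pd.DataFrame(
        rows,
        columns=["n_cells", "threshold_um2", "hr", "ci_low", "ci_high", "p", "skipped"],
    ).sort_values("n_cells", ignore_index=True)
    ok = table[~table["skipped"]]
    if len(ok) >= 2:
        reg = stats.linregress(ok["n_cells"], np.log(ok["hr"]))
        return SweepPrognosis(table, float(reg.slope), float(reg.pvalue), float(reg.stderr))
    return SweepPrognosis(table, None, None, None)
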