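"""Overall-survival analysis: Kaplan-Meier, log-rank, Cox regression.

Estimation is delegated to lifelines (product-limit estimator, two-group
log-rank with hypergeometric variance, Cox partial likelihood with Efron
tie handling); this module adds the domain contracts — validated inputs,
explicit not-computable markers where a screen must continue, the strict
median-split rule ("above the median" means strictly greater), and result
objects with the fields downstream stages consume.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["KMCurve", "CoxFit", "km_estimate", "logrank_test", "median_split", "cox_fit"]


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve on the observed event-time grid."""

    times: np.ndarray  # distinct observed times (days), ascending
    survival: np.ndarray  # S(t) at each time
    at_risk: np.ndarray  # subjects at risk just before each time
    events: np.ndarray  # deaths at each time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.isnan(times).any() or (times < 0).any():
        raise ValueError("times must be >= 0 and non-missing")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0 (censored) or 1 (death)")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    Censored-only times reduce the risk set without producing steps.
    """
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # event_table carries a synthetic t=0 row; keep only observed times
    grid = np.unique(times)
    table = kmf.event_table.loc[grid]
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
    )


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns ``(chi-square statistic, p)`` with 1 df.  Empty groups are an
    error; zero events overall yield the not-computable marker
    ``(nan, nan)`` (there is nothing to compare).
    """
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must have exactly two non-empty levels")
    if events.sum() == 0:
        return np.nan, np.nan
    a = group == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def median_split(values) -> np.ndarray:
    """Binary split at the median: 1 = strictly above, 0 = at or below.

    Ties at the median are "not above" and go to the low group.  An
    all-identical input cannot be split and raises.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs at least 2 values")
    if np.isnan(values).any():
        raise ValueError("median split requires complete values")
    if np.all(values == values[0]):
        raise ValueError("degenerate split: all values identical")
    return (values > np.median(values)).astype(int)


@dataclasses.dataclass
class CoxFit:
    """Cox proportional-hazards results.

    ``table`` has one row per covariate with columns ``coef`` (beta),
    ``hazard_ratio`` (exp beta), ``se``, ``p`` (Wald).
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int

    @property
    def coefs(self) -> pd.Series:
        return self.table["coef"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.table["hazard_ratio"]

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards (Efron ties)  n={self.n}, events={self.n_events}",
            f"  log partial likelihood: {self.log_likelihood:.3f}",
            f"  {'covariate':<20s} {'coef':>8s} {'HR':>8s} {'se':>8s} {'p':>10s}",
        ]
        for cov, row in self.table.iterrows():
            lines.append(
                f"  {cov:<20s} {row['coef']:>8.3f} {row['hazard_ratio']:>8.3f} "
                f"{row['se']:>8.3f} {row['p']:>10.3g}"
            )
        return "\n".join(lines)


def _collinearity_check(X: pd.DataFrame) -> None:
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates (no variation): {const}")
    mat = X.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(centered).max()))
    if rank < X.shape[1]:
        # name the columns loading on the null space
        _, _, vt = np.linalg.svd(centered)
        null_loadings = np.abs(vt[rank:]).max(axis=0)
        involved = [c for c, w in zip(X.columns, null_loadings) if w > 1e-6]
        raise ValueError(f"collinear covariates: {involved}")


def cox_fit(covariates: pd.DataFrame, times, events) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    ``covariates`` must be a complete numeric table (one column per
    covariate); protein levels should be entered on log2 scale by the
    caller.  Missing covariates, fewer than 2 events, constant columns
    and collinear columns are hard errors naming the offender.
    """
    times, events = _check_surv(times, events)
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"covariates with missing values: {bad}")
    if events.sum() < 2:
        raise ValueError("Cox regression needs at least 2 events")
    _collinearity_check(covariates)
    df = covariates.reset_index(drop=True).astype(float)
    df["__time"] = times
    df["__event"] = events
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="__time", event_col="__event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    summ = fitter.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hazard_ratio": summ["exp(coef)"],
            "se": summ["se(coef)"],
            "p": summ["p"].clip(lower=np.nextafter(0, 1), upper=1.0),
        }
    )
    table.index.name = "covariate"
    return CoxFit(
        table=table,
        log_likelihood=float(fitter.log_likelihood_),
        n=int(len(df)),
        n_events=int(events.sum()),
    )
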