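"""Survival association of gene expression.

Samples are dichotomized at the top quartile of a gene's expression
(high = strictly above the 75th percentile, computed with linear
interpolation, so ties at the boundary fall in the low group), then
compared by Kaplan-Meier curves, a two-sided log-rank test, and a
single-covariate Cox proportional-hazards model whose hazard ratio is
exp(beta) for the high-expression group.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
the Cox model is fit here by Newton-Raphson on the partial likelihood with
Breslow tie handling by default (Efron available), which keeps the
single-binary-covariate case exact, transparent and robust to the
complete-separation degeneracies that arise at small n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as _sps

from .errors import SurvivalError, ValidationError
from .io import ClinicalCohort

logger = logging.getLogger("driverseek")

HIGH, LOW = "high", "low"


def dichotomize_top_quartile(expression: pd.Series) -> pd.Series:
    """Label samples high/low at the top quartile of expression.

    High means strictly above the 75th percentile (linear-interpolation
    quantile); ties at the boundary are low, so the high group never
    exceeds a quarter of the cohort plus boundary ties. Requires at least
    8 samples and non-constant expression.
    """
    expression = pd.Series(expression)
    if len(expression) < 8:
        raise SurvivalError("top-quartile dichotomization requires >= 8 samples")
    values = expression.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise SurvivalError("constant expression: no quartile split exists")
    q3 = float(np.quantile(values, 0.75))
    return pd.Series(np.where(values > q3, HIGH, LOW), index=expression.index)


def km_estimator(times, events) -> pd.Series:
    """Product-limit survival estimate.

    Returns the step function as a Series of survival probability indexed
    by time (starting at 0 with S = 1). Censored-only times shrink the
    risk set without changing the estimate.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise SurvivalError("km_estimator requires at least one sample")
    if (times < 0).any():
        raise SurvivalError("negative survival time")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    sf.index.name = "time"
    sf.name = "survival"
    return sf


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sided log-rank test between two groups.

    Standard observed-minus-expected statistic with hypergeometric
    variance over the pooled event times, referred to chi-square with 1
    degree of freedom. Requires at least one event overall.
    """
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if events_a.sum() + events_b.sum() == 0:
        raise SurvivalError("log-rank test requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    beta: float
    se: float
    converged: bool


def _breslow_efron_step(beta, t, d, x, ties):
    """Score and information of the partial likelihood at beta."""
    order = np.argsort(-t, kind="stable")  # descending time for cumulative risk sums
    t_s, d_s, x_s = t[order], d[order], x[order]
    e = np.exp(beta * x_s)
    # cumulative risk-set sums at each position (risk set = times >= current)
    s0 = np.cumsum(e)
    s1 = np.cumsum(e * x_s)
    score = 0.0
    info = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        # positions i..j share this time; risk set sums at index j
        ev = d_s[i : j + 1].astype(bool)
        dd = int(ev.sum())
        if dd:
            S0, S1 = s0[j], s1[j]
            sx = float(x_s[i : j + 1][ev].sum())
            if ties == "breslow":
                score += sx - dd * S1 / S0
                info += dd * (S1 / S0 - (S1 / S0) ** 2)
            else:  # efron
                e_tied = e[i : j + 1][ev]
                x_tied = x_s[i : j + 1][ev]
                T0 = float(e_tied.sum())
                T1 = float((e_tied * x_tied).sum())
                for k in range(dd):
                    f = k / dd
                    a0 = S0 - f * T0
                    a1 = S1 - f * T1
                    score += -a1 / a0
                    info += a1 / a0 - (a1 / a0) ** 2
                score += sx
        i = j + 1
    return score, info


def cox_hr(
    times,
    events,
    group,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit for a single binary covariate.

    ``group`` is boolean/0-1 (1 = high). Newton-Raphson on the partial
    likelihood until |delta beta| < ``tol``; hazard ratio is exp(beta)
    with a Wald 95% CI and two-sided Wald p. Complete separation (all
    events in one group before any in the other) makes the likelihood
    monotone; divergence is reported as an infinite (or zero) hazard-ratio
    sentinel with ``converged=False`` and a warning.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    x = np.asarray(group, dtype=float)
    if ties not in ("breslow", "efron"):
        raise ValidationError(f"unknown tie method {ties!r}")
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValidationError("cox_hr requires a binary 0/1 group covariate")
    if d[x == 1].sum() == 0 or d[x == 0].sum() == 0:
        raise SurvivalError("cox_hr requires at least one event in each group")

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        score, info = _breslow_efron_step(beta, t, d, x, ties)
        if info <= 0:
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))  # damp early oscillation
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 20:
            break

    if not converged:
        logger.warning("cox_hr did not converge (beta=%.2f); likely complete separation", beta)
        hr = float(np.inf) if beta > 0 else 0.0
        return CoxResult(hr=hr, ci95=(np.nan, np.nan), wald_p=np.nan, beta=beta,
                         se=np.nan, converged=False)

    _, info = _breslow_efron_step(beta, t, d, x, ties)
    se = float(1.0 / np.sqrt(info))
    z = _sps.norm.ppf(0.975)
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    wald_p = float(2 * _sps.norm.sf(abs(beta) / se))
    return CoxResult(hr=float(np.exp(beta)), ci95=ci, wald_p=wald_p, beta=float(beta),
                     se=se, converged=True)


@dataclass
class SurvivalResult:
    """Full survival read-out for one gene in one cohort."""

    gene: str
    km_high: pd.Series
    km_low: pd.Series
    logrank_chisq: float
    logrank_p: float
    cox: CoxResult
    n_at_risk: pd.DataFrame
    groups: pd.Series


def number_at_risk(times, groups, at: np.ndarray) -> pd.DataFrame:
    """Samples still at risk (time >= t) per group at each requested time."""
    times = np.asarray(times, dtype=float)
    rows = {
        g: [int((times[groups == g] >= t).sum()) for t in at] for g in (HIGH, LOW)
    }
    return pd.DataFrame(rows, index=pd.Index(at, name="time"))


def survival_report(
    cohort: ClinicalCohort,
    gene: str,
    cohort_type: str = "metastatic",
    risk_interval: float = 12.0,
) -> SurvivalResult:
    """Top-quartile dichotomization -> KM curves -> log-rank -> Cox HR.

    Runs on the samples of ``cohort_type`` that have overall-survival
    follow-up. The number-at-risk table is tabulated at multiples of
    ``risk_interval`` months (the round time points shown under KM plots).
    """
    sub = cohort.subset(cohort_type).with_survival()
    if gene not in sub.expression.columns:
        raise SurvivalError(f"gene {gene!r} absent from cohort expression data")
    groups = dichotomize_top_quartile(sub.expression[gene])
    t = sub.clinical["os_months"].to_numpy(dtype=float)
    e = sub.clinical["os_event"].astype(bool).to_numpy()
    hi = (groups == HIGH).to_numpy()

    km_high = km_estimator(t[hi], e[hi])
    km_low = km_estimator(t[~hi], e[~hi])
    chisq, p = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
    cox = cox_hr(t, e, hi.astype(int))
    at = np.arange(0.0, t.max() + risk_interval, risk_interval)
    nar = number_at_risk(t, groups.to_numpy(), at)
    return SurvivalResult(
        gene=gene,
        km_high=km_high,
        km_low=km_low,
        logrank_chisq=chisq,
        logrank_p=p,
        cox=cox,
        n_at_risk=nar,
        groups=groups,
    )
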