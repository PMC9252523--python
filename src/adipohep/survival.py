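"""Survival statistics implemented from their defining formulas.

Univariate Cox proportional hazards (Efron tie correction, Newton-Raphson
with step-halving), the Kaplan-Meier product-limit estimator, and the
two-sample weighted log-rank family: log-rank (w=1), Gehan-Breslow
generalized Wilcoxon (w = number at risk) and Tarone-Ware (w = sqrt(n)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionCohort, SurvivalTable, ValidationError

FIVE_YEARS_DAYS = 1826.0

_METHOD_WEIGHTS = {
    "logrank": lambda n: np.ones_like(n, dtype=float),
    "gehan_wilcoxon": lambda n: n.astype(float),
    "tarone_ware": lambda n: np.sqrt(n.astype(float)),
}


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    name: str
    beta: float
    se_beta: float
    hr: float
    wald_z: float
    p_value: float
    n: int
    n_events: int
    converged: bool
    monotone_likelihood_flag: bool
    n_iter: int = 0


def _cox_scan(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Log partial likelihood, score, information at ``beta`` (sorted input)."""
    theta = np.exp(beta * x)
    xtheta = x * theta
    x2theta = x * xtheta
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum(xtheta[::-1])[::-1]
    s2 = np.cumsum(x2theta[::-1])[::-1]

    loglik = float(beta * (x * event).sum())
    score = float((x * event).sum())
    info = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dmask = event[i:j] == 1
        d = int(dmask.sum())
        if d:
            r0, r1, r2 = s0[i], s1[i], s2[i]
            t0 = float(theta[i:j][dmask].sum())
            t1 = float(xtheta[i:j][dmask].sum())
            t2 = float(x2theta[i:j][dmask].sum())
            for ell in range(d):
                f = ell / d
                d0 = r0 - f * t0
                d1 = r1 - f * t1
                d2 = r2 - f * t2
                loglik -= np.log(d0)
                score -= d1 / d0
                info += d2 / d0 - (d1 / d0) ** 2
        i = j
    return loglik, score, info


def cox_univariate(
    time: Sequence[float],
    event: Sequence[int],
    x: Sequence[float],
    name: str = "covariate",
    tol: float = 1e-9,
    max_iter: int = 50,
    beta_cap: float = 15.0,
) -> CoxFit:
    """Fit a single-covariate Cox model by Newton-Raphson.

    Starts at beta = 0, converges when |delta| < ``tol``, halves the step
    when the partial likelihood decreases, and flags monotone likelihood
    (no interior maximum) when |beta| runs away past ``beta_cap``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if event.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    if np.ptp(x) == 0:
        raise ValidationError(f"covariate {name!r} is constant; model non-identifiable")
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]

    beta = 0.0
    loglik, score, info = _cox_scan(beta, time, event, x)
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            monotone = True
            break
        delta = score / info
        step = delta
        new_beta = beta + step
        new_ll, new_sc, new_in = _cox_scan(new_beta, time, event, x)
        n_halve = 0
        while new_ll < loglik and n_halve < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_sc, new_in = _cox_scan(new_beta, time, event, x)
            n_halve += 1
        beta, loglik, score, info = new_beta, new_ll, new_sc, new_in
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > beta_cap:
            monotone = True
            break

    se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    p = max(p, np.finfo(float).tiny)
    return CoxFit(
        name=name,
        beta=float(beta),
        se_beta=float(se),
        hr=float(np.exp(beta)),
        wald_z=float(z),
        p_value=p,
        n=len(time),
        n_events=int(event.sum()),
        converged=converged and not monotone,
        monotone_likelihood_flag=monotone,
        n_iter=it,
    )


def cox_score_test(time: Sequence[float], event: Sequence[int], x: Sequence[float]) -> float:
    """Cox score-test chi-square at beta = 0 (equals log-rank for binary x, no ties)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    order = np.argsort(time, kind="stable")
    _, score, info = _cox_scan(0.0, time[order], event[order], x[order])
    if info <= 0:
        raise ValidationError("score-test information is non-positive")
    return float(score**2 / info)


def screen_protective(
    expr: ExpressionCohort,
    survival: SurvivalTable,
    genes: Sequence[str] | None = None,
    log_transform: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Per-gene univariate Cox on z-scored expression; keep genes with HR < 1.

    Expression is log2(x + 1)-transformed before z-scoring by default
    (HRs are then per SD of log expression). No p-value filter is applied
    (the printed criterion is HR < 1 alone). Per-gene failures (constant
    expression, monotone likelihood) are flagged in the returned table
    and excluded from the retained list.
    """
    overlap = [s for s in expr.sample_ids if s in set(survival.sample_ids)]
    if len(overlap) < 10:
        raise ValidationError(
            f"only {len(overlap)} samples shared between expression and survival tables (need >= 10)"
        )
    surv = survival.df.set_index("sample_id").loc[overlap]
    time = surv["time_days"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    col_idx = [expr.sample_ids.index(s) for s in overlap]

    rows = []
    retained: list[str] = []
    for gene in genes if genes is not None else expr.gene_ids:
        vals = expr.gene_values(gene)[col_idx]
        if log_transform:
            vals = np.log2(vals + 1.0)
        sd = vals.std()
        if sd == 0:
            rows.append(
                {"gene_id": gene, "beta": np.nan, "se_beta": np.nan, "hr": np.nan,
                 "wald_z": np.nan, "p_value": np.nan, "converged": False,
                 "flag": "constant_expression"}
            )
            continue
        z = (vals - vals.mean()) / sd
        try:
            fit = cox_univariate(time, event, z, name=gene)
        except ValidationError as exc:
            rows.append(
                {"gene_id": gene, "beta": np.nan, "se_beta": np.nan, "hr": np.nan,
                 "wald_z": np.nan, "p_value": np.nan, "converged": False,
                 "flag": str(exc)}
            )
            continue
        flag = "monotone_likelihood" if fit.monotone_likelihood_flag else ""
        rows.append(
            {"gene_id": gene, "beta": fit.beta, "se_beta": fit.se_beta, "hr": fit.hr,
             "wald_z": fit.wald_z, "p_value": fit.p_value, "converged": fit.converged,
             "flag": flag}
        )
        if fit.converged and fit.hr < 1.0:
            retained.append(gene)
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier and two-sample tests
# ---------------------------------------------------------------------------


@dataclass
class KmCurve:
    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray  # product-limit S(t) at each event time


def km_curve(time: Sequence[float], event: Sequence[int]) -> KmCurve:
    """Product-limit estimator over the distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValidationError("empty survival data")
    event_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in event_times])
    deaths = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KmCurve(event_times, at_risk, deaths, surv)


@dataclass
class TwoSampleTestResult:
    method: str
    statistic: float  # sum_i w_i (O_Ai - E_Ai), A = first group label
    chi_square: float
    p_value: float
    group_a: str = ""
    group_b: str = ""
    exact: bool = False


def _weighted_oe(
    time: np.ndarray, event: np.ndarray, in_a: np.ndarray, method: str
) -> tuple[float, float]:
    """Return (statistic, variance) of the weighted observed-minus-expected sum."""
    event_times = np.unique(time[event == 1])
    stat = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_i = int(at_risk.sum())
        n_ai = int((at_risk & in_a).sum())
        dying = (time == t) & (event == 1)
        d_i = int(dying.sum())
        d_ai = int((dying & in_a).sum())
        w = _METHOD_WEIGHTS[method](np.array(n_i))
        e_ai = d_i * n_ai / n_i
        stat += float(w) * (d_ai - e_ai)
        if n_i > 1:
            var += float(w) ** 2 * (
                d_i * (n_ai / n_i) * (1 - n_ai / n_i) * (n_i - d_i) / (n_i - 1)
            )
    return stat, var


def two_sample_test(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[str],
    method: str = "gehan_wilcoxon",
    exact: bool = False,
    max_exact_n: int = 20,
) -> TwoSampleTestResult:
    """Two-sample weighted log-rank family test.

    ``method`` is one of 'gehan_wilcoxon', 'logrank', 'tarone_ware'. With
    ``exact=True`` (small n) the p-value is computed by exhaustive
    enumeration of all group-label assignments, comparing |statistic|.
    """
    if method not in _METHOD_WEIGHTS:
        raise ValueError(f"unknown method {method!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray([str(g) for g in group])
    labels = sorted(set(group))
    if len(labels) != 2:
        raise ValidationError(f"need exactly two non-empty groups, got {labels}")
    if event.sum() == 0:
        raise ValidationError("no events; test undefined")
    in_a = group == labels[0]
    stat, var = _weighted_oe(time, event, in_a, method)
    if var <= 0:
        raise ValidationError("test variance is zero")
    chi2 = stat**2 / var
    if exact:
        n = len(time)
        if n > max_exact_n:
            raise ValidationError(f"exact enumeration limited to n <= {max_exact_n}")
        n_a = int(in_a.sum())
        count = 0
        total = 0
        obs = abs(stat)
        for combo in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            s, _ = _weighted_oe(time, event, mask, method)
            total += 1
            if abs(s) >= obs - 1e-12:
                count += 1
        p = count / total
        return TwoSampleTestResult(method, float(stat), float(chi2), float(p),
                                   labels[0], labels[1], exact=True)
    p = float(stats.chi2.sf(chi2, df=1))
    p = max(p, np.finfo(float).tiny)
    return TwoSampleTestResult(method, float(stat), float(chi2), p, labels[0], labels[1])


def median_split_survival(
    expr: ExpressionCohort,
    survival: SurvivalTable,
    gene: str,
    horizon_days: float = FIVE_YEARS_DAYS,
    method: str = "gehan_wilcoxon",
) -> TwoSampleTestResult:
    """Median-split a gene's expression and test survival within a horizon.

    Follow-up is administratively censored at ``horizon_days`` (default
    five years = 1826 days) before testing.
    """
    if not expr.has_gene(gene):
        raise ValidationError(f"gene {gene!r} absent from cohort")
    overlap = [s for s in expr.sample_ids if s in set(survival.sample_ids)]
    if not overlap:
        raise ValidationError("no samples shared between expression and survival tables")
    col_idx = [expr.sample_ids.index(s) for s in overlap]
    vals = expr.gene_values(gene)[col_idx]
    if np.ptp(vals) == 0:
        raise ValidationError(f"gene {gene!r} constant across samples; split degenerate")
    med = float(np.median(vals))
    group = np.where(vals > med, "high", "low")
    if len(set(group)) != 2:
        raise ValidationError(f"median split of {gene!r} left one group empty")
    surv = survival.df.set_index("sample_id").loc[overlap]
    time = surv["time_days"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    capped = np.minimum(time, horizon_days)
    event = np.where(time > horizon_days, 0, event)
    return two_sample_test(capped, event, group, method=method)
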