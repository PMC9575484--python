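"""Prognostic assessment: median-split log-rank test and univariate Cox.

The log-rank path dichotomizes expression at the cohort median (ties go to
the low-expression group), compares the two Kaplan–Meier curves with the
standard hypergeometric-variance log-rank statistic, and can export the KM
step functions as a table. The Cox path fits the proportional-hazards
partial likelihood on the continuous expression by Newton–Raphson from
β = 0 with Efron (default) or Breslow tie handling, and reports β, exp(β),
the Wald 95% CI and Wald p.

Samples with a missing risk group are NOT excluded here: survival uses all
annotated samples with follow-up, matching a cohort-wide prognosis question
rather than the risk contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io import CohortAnnotation, RunConfig

logger = logging.getLogger("rbpnet")


@dataclass
class KMResult:
    gene_id: str
    split_value: float
    n_high: int
    n_low: int
    statistic: float  # log-rank chi-square, 1 df
    p_value: float


@dataclass
class CoxResult:
    gene_id: str
    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    n_events: int
    diagnostic: str = ""


def _aligned(expr: pd.Series, ann: CohortAnnotation):
    common = [s for s in expr.index if s in set(ann.sample_ids)]
    x = expr.loc[common].to_numpy(dtype=float)
    t = ann.table.loc[common, "os_time"].to_numpy(dtype=float)
    e = ann.table.loc[common, "os_event"].to_numpy(dtype=int)
    return x, t, e


def km_logrank(expr: pd.Series, ann: CohortAnnotation,
               gene_id: str | None = None) -> KMResult:
    """Median-split two-group log-rank test for one gene.

    Ties at the median fall in the low-expression group, so the high group
    is strictly above the median.
    """
    gene_id = gene_id or str(expr.name)
    x, t, e = _aligned(expr, ann)
    if e.sum() < 2:
        raise ValueError("need >= 2 observed events for a log-rank test")
    cut = float(np.median(x))
    high = x > cut
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("median split produced an empty group")
    res = logrank_test(t[high], t[~high], event_observed_A=e[high],
                       event_observed_B=e[~high])
    return KMResult(gene_id=gene_id, split_value=cut,
                    n_high=int(high.sum()), n_low=int((~high).sum()),
                    statistic=float(res.test_statistic),
                    p_value=float(res.p_value))


def km_table(expr: pd.Series, ann: CohortAnnotation) -> pd.DataFrame:
    """Kaplan–Meier step functions per median-split group: time, at-risk, survival."""
    x, t, e = _aligned(expr, ann)
    cut = float(np.median(x))
    frames = []
    for label, mask in (("high_expression", x > cut), ("low_expression", x <= cut)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=label)
        tbl = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
        surv = kmf.survival_function_[label].to_numpy()
        frames.append(pd.DataFrame({
            "group": label,
            "time": tbl["time"],
            "at_risk": tbl["at_risk"].astype(int),
            "survival": surv,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Univariate Cox proportional hazards
# ---------------------------------------------------------------------------

def _cox_loglik(beta: float, x: np.ndarray, t: np.ndarray, e: np.ndarray,
                ties: str) -> tuple[float, float, float]:
    """Partial log-likelihood, score and information at ``beta``.

    Groups tied event times; Efron down-weights tied deaths' own
    contribution to the risk-set sum, Breslow does not.
    """
    order = np.argsort(t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    n = len(t)
    theta = np.exp(beta * x)

    # cumulative risk-set sums from the largest time downward
    s0 = np.cumsum(theta[::-1])[::-1]             # sum theta over risk set at t_i
    s1 = np.cumsum((theta * x)[::-1])[::-1]
    s2 = np.cumsum((theta * x * x)[::-1])[::-1]

    loglik = 0.0
    score = 0.0
    info = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = [k for k in range(i, j) if e[k] == 1]
        d = len(deaths)
        if d:
            r0, r1, r2 = s0[i], s1[i], s2[i]
            d0 = theta[deaths].sum()
            d1 = (theta[deaths] * x[deaths]).sum()
            d2 = (theta[deaths] * x[deaths] ** 2).sum()
            xsum = x[deaths].sum()
            loglik += beta * xsum
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                z0 = r0 - frac * d0
                z1 = r1 - frac * d1
                z2 = r2 - frac * d2
                loglik -= np.log(z0)
                score -= z1 / z0
                info += z2 / z0 - (z1 / z0) ** 2
            score += xsum
        i = j
    return loglik, score, info


def cox_univariate(expr: pd.Series, ann: CohortAnnotation, cfg: RunConfig,
                   gene_id: str | None = None) -> CoxResult:
    """Newton–Raphson fit of the univariate Cox partial likelihood.

    Starts at β = 0; converges when the score drops below 1e−9 (or after 50
    iterations, in which case the result is flagged rather than silently
    reported). Perfect separation / monotone likelihood is detected via a
    runaway coefficient and flagged the same way.
    """
    gene_id = gene_id or str(expr.name)
    x, t, e = _aligned(expr, ann)
    if e.sum() < 2:
        raise ValueError("need >= 2 observed events for Cox regression")
    if np.ptp(x) == 0.0:
        raise ValueError(f"constant expression for {gene_id}")

    beta = 0.0
    converged = False
    diagnostic = ""
    _, _, info0 = _cox_loglik(0.0, x, t, e, cfg.cox_tie_method)
    for _ in range(50):
        _, score, info = _cox_loglik(beta, x, t, e, cfg.cox_tie_method)
        if info <= 0:
            diagnostic = "non-positive information (degenerate risk sets)"
            break
        step = score / info
        # dampen wild steps so a monotone likelihood walks out slowly enough
        # to be caught by the runaway guard rather than overflowing exp()
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > 50.0:
            diagnostic = "monotone partial likelihood (perfect separation)"
            break
        if abs(score) < 1e-9:
            converged = True
            break
    else:
        diagnostic = "Newton-Raphson did not converge in 50 iterations"

    _, _, info = _cox_loglik(beta, x, t, e, cfg.cox_tie_method)
    # a flat likelihood at a huge |beta| means the score vanished because the
    # information collapsed, not because a maximum was reached
    if converged and info0 > 0 and (info < 1e-6 * info0 or abs(beta) > 20.0):
        converged = False
        diagnostic = "monotone partial likelihood (perfect separation)"
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    hr = float(np.exp(beta))
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    if not converged:
        logger.warning("cox fit for %s flagged: %s", gene_id, diagnostic)
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(beta - 1.96 * se))
        ci_high = float(np.exp(beta + 1.96 * se))
    return CoxResult(gene_id=gene_id, beta=float(beta), se=se,
                     hazard_ratio=hr, ci_low=ci_low, ci_high=ci_high,
                     p_value=p, converged=converged,
                     n_events=int(e.sum()), diagnostic=diagnostic)


def survival_screen(m, gene_ids, ann: CohortAnnotation,
                    cfg: RunConfig) -> pd.DataFrame:
    """Log-rank + Cox for a list of genes; one row per gene."""
    rows = []
    for g in gene_ids:
        expr = m.values.loc[g]
        km = km_logrank(expr, ann, gene_id=g)
        cox = cox_univariate(expr, ann, cfg, gene_id=g)
        rows.append({
            "gene_id": g,
            "logrank_stat": km.statistic,
            "logrank_p": km.p_value,
            "beta": cox.beta,
            "hazard_ratio": cox.hazard_ratio,
            "ci_low": cox.ci_low,
            "ci_high": cox.ci_high,
            "cox_p": cox.p_value,
            "converged": cox.converged,
        })
    return pd.DataFrame(rows).set_index("gene_id", drop=False)
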