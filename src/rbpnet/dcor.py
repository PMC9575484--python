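"""Unbiased distance correlation and its chi-square independence test.

The screening statistic of the pipeline: for a gene pair (x, y) observed in n
samples, build the Euclidean distance matrices, U-center them with the
unbiased (n−1)/(n−2) denominators, form the unbiased distance covariance /
variances via the trace inner product, and refer n·R_D to the distribution of
(χ²₁ − 1) for a fast, conservative p-value. R_D is zero (asymptotically) if
and only if the pair is independent, and is sensitive to nonlinear,
Pearson-blind dependence.

Everything here is O(n²) dense, which is ample for cohort sizes of a few
hundred samples; ``pairwise_screen`` is the only place that loops over pairs,
so a faster univariate algorithm could be swapped in behind ``dcor_test``
without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("rbpnet")

_CLIP_TOL = 1e-12


class DegenerateInputError(ValueError):
    """A constant vector: distance variance is zero, R_D undefined."""


@dataclass(frozen=True)
class DcorTestResult:
    """One screened RBP–target pair."""

    rbp_id: str
    target_id: str
    n: int
    cov_d: float
    var_x: float
    var_y: float
    r_d: float
    p_raw: float


def distance_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances |x_i − x_j| of a 1-d sample."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-d vector with n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")
    return np.abs(x[:, None] - x[None, :])


def u_center(d: np.ndarray) -> np.ndarray:
    """U-centered (unbiased) version of a distance matrix.

    Off-diagonal entries subtract row and column means with denominator n−2
    and add back the grand sum scaled by 1/((n−1)(n−2)); the diagonal is
    forced to zero. Every off-diagonal row sum of the result is analytically
    zero.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 4:
        raise ValueError(f"U-centering needs n >= 4, got n={n}")
    col = d.sum(axis=0)
    row = d.sum(axis=1)
    grand = d.sum()
    out = d - col[None, :] / (n - 2) - row[:, None] / (n - 2) \
        + grand / ((n - 1) * (n - 2))
    np.fill_diagonal(out, 0.0)
    return out


def dcov_u(au: np.ndarray, bu: np.ndarray) -> float:
    """Unbiased distance covariance trace(A_u · B_u) / (n(n−3)).

    Passing the same matrix twice yields the distance variance, a sum of
    squares and hence nonnegative.
    """
    au = np.asarray(au, dtype=float)
    bu = np.asarray(bu, dtype=float)
    if au.shape != bu.shape:
        raise ValueError(f"mismatched sizes {au.shape} vs {bu.shape}")
    n = au.shape[0]
    if n < 4:
        raise ValueError(f"need n >= 4, got n={n}")
    # both matrices symmetric, so trace(A_u B_u) = sum_ij a_ij * b_ij
    return float((au * bu).sum() / (n * (n - 3)))


def _degenerate(var: float, d: np.ndarray) -> bool:
    """True when a distance variance is zero up to rounding at the data's scale.

    The U-statistic variance vanishes analytically not only for constant
    vectors but also e.g. for a two-valued vector with a single off-value;
    rounding then leaves a residual of order (eps·scale)², so the test is
    relative to the squared mean distance.
    """
    scale = d.mean()
    return var <= 1e-14 * scale * scale


def dcor_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Unbiased distance correlation R_D = Cov_D / sqrt(Var_D(x)·Var_D(y)).

    Returns ``(r_d, cov_d, var_x, var_y)``. R_D lies in [−1, 1]; negative
    values are possible under the unbiased estimator and reported as-is.

    Raises
    ------
    DegenerateInputError
        when either vector is constant (Var_D = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    da, db = distance_matrix(x), distance_matrix(y)
    au, bu = u_center(da), u_center(db)
    n = x.size
    cov_d = dcov_u(au, bu)
    var_x = dcov_u(au, au)
    var_y = dcov_u(bu, bu)
    if _degenerate(var_x, da) or _degenerate(var_y, db):
        raise DegenerateInputError(
            f"distance variance is zero (var_x={var_x:.3g}, var_y={var_y:.3g}); "
            "constant input vector"
        )
    r_d = cov_d / np.sqrt(var_x * var_y)
    if abs(r_d) > 1.0:
        if abs(r_d) - 1.0 < _CLIP_TOL:
            r_d = float(np.clip(r_d, -1.0, 1.0))
        else:  # pragma: no cover - internal consistency guard
            raise AssertionError(f"R_D={r_d!r} outside [-1,1] beyond rounding")
    return float(r_d), cov_d, var_x, var_y


def chisq_pvalue(r_d: float, n: int) -> float:
    """Upper-tail p-value referring n·R_D to the distribution of (χ²₁ − 1).

    p = P(χ²₁ > n·R_D + 1). Arguments below the support (n·R_D + 1 < 0)
    return 1. Conservative: the chi-square bound never rejects more often
    than the nominal level asymptotically.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got n={n}")
    arg = n * r_d + 1.0
    if arg < 0:
        return 1.0
    return float(stats.chi2.sf(arg, df=1))


def dcor_test(x: np.ndarray, y: np.ndarray,
              rbp_id: str = "x", target_id: str = "y") -> DcorTestResult:
    """Full unbiased distance-correlation independence test for one pair."""
    x = np.asarray(x, dtype=float)
    r_d, cov_d, var_x, var_y = dcor_u(x, y)
    n = int(x.size)
    return DcorTestResult(rbp_id=rbp_id, target_id=target_id, n=n,
                          cov_d=cov_d, var_x=var_x, var_y=var_y,
                          r_d=r_d, p_raw=chisq_pvalue(r_d, n))


def pairwise_screen(m, rbp_ids, target_ids) -> list[DcorTestResult]:
    """Test every (RBP, target) pair with rbp ≠ target.

    ``m`` is a log2-normalized :class:`~rbpnet.io.ExpressionMatrix`. Degenerate
    (constant) genes are skipped with a logged reason rather than silently
    dropped, so downstream edge counts stay auditable.
    """
    rbp_ids = list(rbp_ids)
    target_ids = list(target_ids)
    if not rbp_ids:
        raise ValueError("empty RBP set")
    missing = (set(rbp_ids) | set(target_ids)) - set(m.gene_ids)
    if missing:
        raise KeyError(f"ids absent from matrix: {sorted(missing)[:5]}")

    values = m.values
    # U-centered matrices are reused across pairs; cache per gene.
    cache: dict[str, np.ndarray | None] = {}

    def centered(gene: str) -> tuple[np.ndarray, float] | None:
        if gene not in cache:
            v = values.loc[gene].to_numpy(dtype=float)
            if np.ptp(v) == 0.0:
                logger.info("skipping degenerate (constant) gene %s", gene)
                cache[gene] = None
            else:
                d = distance_matrix(v)
                au = u_center(d)
                var = dcov_u(au, au)
                if _degenerate(var, d):
                    logger.info("skipping degenerate gene %s (zero distance "
                                "variance)", gene)
                    cache[gene] = None
                else:
                    cache[gene] = (au, var)
        return cache[gene]

    n = len(m.sample_ids)
    results: list[DcorTestResult] = []
    for rbp in rbp_ids:
        entry = centered(rbp)
        if entry is None:
            continue
        au, var_x = entry
        for target in target_ids:
            if target == rbp:
                continue
            entry_t = centered(target)
            if entry_t is None:
                continue
            bu, var_y = entry_t
            cov_d = dcov_u(au, bu)
            r_d = cov_d / np.sqrt(var_x * var_y)
            if abs(r_d) > 1.0 and abs(r_d) - 1.0 < _CLIP_TOL:
                r_d = float(np.clip(r_d, -1.0, 1.0))
            results.append(DcorTestResult(
                rbp_id=rbp, target_id=target, n=n, cov_d=cov_d,
                var_x=var_x, var_y=var_y, r_d=float(r_d),
                p_raw=chisq_pvalue(float(r_d), n)))
    return results
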