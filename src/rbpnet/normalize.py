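"""Between-sample normalization: log2+quantile, and TMM-scaled log2 CPM.

Two independent paths, never mixed within a run:

* ``log2_quantile_normalize`` — log2(x+1) per cell, then classic quantile
  normalization: each sample's order statistics are replaced by the
  across-sample means of order statistics, with ties receiving the mean of
  the reference values they span.
* ``tmm_log2cpm_normalize`` — trimmed-mean-of-M-values scale factors against
  a 75th-percentile-matched reference sample, then log2(CPM + 0.5) with
  TMM-adjusted effective library sizes. The trimming recipe (two-tailed 30%
  trim on M, 5% on A, inverse-delta-variance weights) follows the method's
  original definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import LOG2_NORMALIZED, RAW_COUNTS, ExpressionMatrix

logger = logging.getLogger("rbpnet")


@dataclass
class NormalizationReport:
    method: str
    scale_factors: pd.Series | None = None  # TMM path only
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if self.scale_factors is not None:
            if (self.scale_factors <= 0).any():
                raise ValueError("TMM factors must be strictly positive")


# ---------------------------------------------------------------------------
# Quantile path
# ---------------------------------------------------------------------------

def log2_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1) then quantile normalization across samples.

    After normalization every sample has identical sorted values (the mean
    order-statistic reference distribution). Requires at least two samples.
    """
    if m.units != RAW_COUNTS:
        raise ValueError("expected raw counts")
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    logged = np.log2(m.values.to_numpy(dtype=float) + 1.0)
    n_genes, n_samples = logged.shape
    reference = np.sort(logged, axis=0).mean(axis=1)

    out = np.empty_like(logged)
    for j in range(n_samples):
        col = logged[:, j]
        # average ranks; ties map to the mean of the reference values spanned
        ranks = rankdata(col, method="average")  # 1-based, fractional at ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        mapped = 0.5 * (reference[lo] + reference[hi])
        # ties of size > 2 span more than two reference slots: average exactly
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 2).any():
            order = np.argsort(col, kind="stable")
            pos = np.empty(n_genes, dtype=int)
            pos[order] = np.arange(n_genes)
            for value_idx in np.nonzero(counts > 2)[0]:
                members = np.nonzero(inv == value_idx)[0]
                span = np.sort(pos[members])
                mapped[members] = reference[span].mean()
        out[:, j] = mapped
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, LOG2_NORMALIZED)


# ---------------------------------------------------------------------------
# TMM path
# ---------------------------------------------------------------------------

def _tmm_factor(obs: np.ndarray, ref: np.ndarray,
                log_ratio_trim: float = 0.3, abundance_trim: float = 0.05) -> float:
    """One sample's TMM factor against the reference (both raw count vectors)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m_vals = np.log2((obs / n_obs) / (ref / n_ref))
        a_vals = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    # asymptotic delta-method variance of M
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m_vals) & np.isfinite(a_vals)
    m_vals, a_vals, v = m_vals[finite], a_vals[finite], v[finite]
    if m_vals.size == 0:
        raise ValueError("sample shares no nonzero gene with the reference")
    if np.max(np.abs(m_vals)) < 1e-6:
        return 1.0
    n = m_vals.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m_vals)
    rank_a = rankdata(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m_vals[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_log2cpm_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """TMM scale factors plus log2(CPM + 0.5) with effective library sizes.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the across-sample mean. Factors are rescaled to geometric
    mean 1, so they are pure composition corrections; sequencing depth is
    absorbed by the library sizes.
    """
    if m.units != RAW_COUNTS:
        raise ValueError("expected raw counts")
    counts = m.values.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        bad = [m.sample_ids[j] for j in np.nonzero(lib_sizes <= 0)[0]]
        raise ValueError(f"zero library size for samples {bad}")

    f75 = np.quantile(counts / lib_sizes, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[:, ref_idx]

    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        try:
            factors[j] = _tmm_factor(counts[:, j], ref)
        except ValueError as exc:
            raise ValueError(f"sample {m.sample_ids[j]!r}: {exc}") from exc
    factors /= np.exp(np.mean(np.log(factors)))

    effective = lib_sizes * factors
    cpm = counts / effective[None, :] * 1e6
    log2cpm = np.log2(cpm + 0.5)
    values = pd.DataFrame(log2cpm, index=m.values.index, columns=m.values.columns)
    report = NormalizationReport(
        method="tmm_log2cpm",
        scale_factors=pd.Series(factors, index=m.sample_ids, name="tmm_factor"),
        reference_sample=m.sample_ids[ref_idx],
    )
    return ExpressionMatrix(values, LOG2_NORMALIZED), report
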