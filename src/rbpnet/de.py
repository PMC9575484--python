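"""Upregulated-gene selection: high-risk vs rest two-sample t-test + fold change.

Samples with a missing risk group are excluded before testing. The contrast
is high vs (low ∪ intermediate); the test is Student's pooled-variance
two-sided t by default (Welch behind a config flag). A gene is flagged
upregulated when p < de_p_threshold AND mean log2 difference ≥
de_log2fc_threshold (one-directional: downregulation is reported but never
flagged). No multiple-testing correction is applied at this stage; the
family-wise control happens at the network-edge stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import LOG2_NORMALIZED, CohortAnnotation, ExpressionMatrix, RunConfig

logger = logging.getLogger("rbpnet")

DE_COLUMNS = ["gene_id", "mean_high", "mean_rest", "log2fc", "t_stat",
              "p_value", "upregulated"]


def de_screen(m: ExpressionMatrix, ann: CohortAnnotation,
              cfg: RunConfig) -> pd.DataFrame:
    """One row per gene: means, log2 fold change, t statistic, p, upregulated flag.

    Genes with zero pooled variance get t=0, p=1. Requires at least two
    samples in the high group and two in the rest.
    """
    if m.units != LOG2_NORMALIZED:
        raise ValueError("DE screen expects a log2-normalized matrix")
    ann = ann.with_risk()
    common = [s for s in m.sample_ids if s in set(ann.sample_ids)]
    dropped = set(m.sample_ids) - set(common)
    if dropped:
        logger.warning("dropping %d samples absent from annotation", len(dropped))
    risk = ann.table.loc[common, "risk_group"]
    high_ids = [s for s in common if risk[s] == "high"]
    rest_ids = [s for s in common if risk[s] != "high"]
    if len(high_ids) < 2 or len(rest_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got high={len(high_ids)}, "
            f"rest={len(rest_ids)}"
        )

    xh = m.values.loc[:, high_ids].to_numpy(dtype=float)
    xr = m.values.loc[:, rest_ids].to_numpy(dtype=float)
    n1, n2 = xh.shape[1], xr.shape[1]
    mean_high = xh.mean(axis=1)
    mean_rest = xr.mean(axis=1)
    log2fc = mean_high - mean_rest
    var_high = xh.var(axis=1, ddof=1)
    var_rest = xr.var(axis=1, ddof=1)

    if cfg.de_welch:
        se2 = var_high / n1 + var_rest / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(se2)
            df = se2 ** 2 / ((var_high / n1) ** 2 / (n1 - 1)
                             + (var_rest / n2) ** 2 / (n2 - 1))
    else:
        pooled = ((n1 - 1) * var_high + (n2 - 1) * var_rest) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(t, float(n1 + n2 - 2))

    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)

    up = (p < cfg.de_p_threshold) & (log2fc >= cfg.de_log2fc_threshold)
    return pd.DataFrame({
        "gene_id": m.gene_ids,
        "mean_high": mean_high,
        "mean_rest": mean_rest,
        "log2fc": log2fc,
        "t_stat": t,
        "p_value": p,
        "upregulated": up,
    }).set_index("gene_id", drop=False)


def upregulated_ids(de_table: pd.DataFrame) -> list[str]:
    return list(de_table.index[de_table["upregulated"]])


def overlap(list_a, list_b) -> tuple[set[str], tuple[int, int, int]]:
    """Set intersection plus (only_a, common, only_b) sizes for a Venn summary."""
    a, b = set(list_a), set(list_b)
    common = a & b
    return common, (len(a - b), len(common), len(b - a))
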