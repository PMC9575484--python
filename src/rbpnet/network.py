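"""Bipartite RBP→target network assembly under the dual edge threshold.

An edge is kept when its raw distance-correlation p-value clears the
family-wise cutoff AND R_D exceeds the effect-size gate (signed R_D, as the
rule is stated). The family-wise cutoff is either the fixed raw-p value
1e−6 (default) or α divided by the number of tested pairs
(``bonferroni_mode = alpha_over_m``). Targets carry their gene class so the
summaries can tally noncoding classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import pandas as pd

from .dcor import DcorTestResult
from .io import EDGE_COLUMNS, GeneAnnotation, RunConfig

logger = logging.getLogger("rbpnet")


@dataclass
class RegulatoryNetwork:
    """Retained edges plus derived degree / shared-target summaries."""

    edges: pd.DataFrame  # columns EDGE_COLUMNS
    p_threshold: float
    n_tested: int

    @property
    def rbp_degrees(self) -> dict[str, int]:
        return dict(Counter(self.edges["rbp_id"]))

    @property
    def shared_target_counts(self) -> dict[int, int]:
        """k -> number of targets with exactly k incident RBPs."""
        per_target = Counter(self.edges["target_id"])
        return dict(Counter(per_target.values()))

    @property
    def n_targets(self) -> int:
        return self.edges["target_id"].nunique()


def build_network(results: list[DcorTestResult], gene_ann: GeneAnnotation,
                  cfg: RunConfig) -> RegulatoryNetwork:
    """Filter screened pairs to the edge set and attach target classes."""
    if not results:
        raise ValueError("no screened pairs to build a network from")
    if cfg.bonferroni_mode == "alpha_over_m":
        p_threshold = cfg.bonferroni_alpha / len(results)
    else:
        p_threshold = cfg.edge_p_threshold
    rows = []
    for r in results:
        if r.p_raw < p_threshold and r.r_d > cfg.edge_rd_threshold:
            rows.append({
                "rbp_id": r.rbp_id,
                "target_id": r.target_id,
                "target_class": gene_ann.class_of(r.target_id),
                "n": r.n,
                "r_d": r.r_d,
                "p_raw": r.p_raw,
            })
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    edges = edges.sort_values(["rbp_id", "target_id"]).reset_index(drop=True)
    logger.info("network: %d edges from %d tested pairs (p<%g, R_D>%g)",
                len(edges), len(results), p_threshold, cfg.edge_rd_threshold)
    return RegulatoryNetwork(edges=edges, p_threshold=p_threshold,
                             n_tested=len(results))


def network_from_edges(edges: pd.DataFrame, p_threshold: float = float("nan"),
                       n_tested: int = 0) -> RegulatoryNetwork:
    """Rebuild a network object from a written edge list (round trip)."""
    edges = edges.loc[:, EDGE_COLUMNS].copy()
    edges = edges.sort_values(["rbp_id", "target_id"]).reset_index(drop=True)
    return RegulatoryNetwork(edges=edges, p_threshold=p_threshold,
                             n_tested=n_tested)


def network_summary(net: RegulatoryNetwork) -> dict:
    """Degree, shared-target, and target-class tallies.

    ``targets_with_at_least_k`` answers questions like "how many targets are
    controlled by at least two RBPs"; ``target_class_counts`` tallies the
    noncoding classes among distinct targets.
    """
    exact = net.shared_target_counts
    max_k = max(exact, default=0)
    at_least = {k: sum(v for kk, v in exact.items() if kk >= k)
                for k in range(1, max_k + 1)}
    per_target_class = (net.edges.drop_duplicates("target_id")
                        .set_index("target_id")["target_class"])
    return {
        "n_edges": len(net.edges),
        "n_rbps": net.edges["rbp_id"].nunique(),
        "n_targets": net.n_targets,
        "rbp_degrees": dict(sorted(net.rbp_degrees.items(),
                                   key=lambda kv: (-kv[1], kv[0]))),
        "targets_with_exactly_k_rbps": dict(sorted(exact.items())),
        "targets_with_at_least_k_rbps": at_least,
        "target_class_counts": dict(Counter(per_target_class)),
    }
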