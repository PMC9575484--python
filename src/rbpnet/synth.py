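"""Synthetic risk-stratified expression cohorts with planted ground truth.

The generator emulates the statistical structure the downstream stages
assume: negative-binomial counts around gene-specific latent log2 means,
a three-group risk stratification with a planted high-risk fold change,
planted RBP→target dependencies (linear, centered-quadratic or sinusoidal
on the latent scale, so the quadratic kind is Pearson-blind by design),
and exponential survival whose log hazard is linear in standardized latent
expression, with independent uniform censoring calibrated to a requested
rate. Every draw flows from one seed, so identical designs give
byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (RAW_COUNTS, CohortAnnotation, ExpressionMatrix,
                 GeneAnnotation)

EDGE_KINDS = ("linear", "quadratic", "sinusoidal")


@dataclass
class SimulationDesign:
    """Knobs of the synthetic cohort.

    Group sizes default to an adult-style cohort (37 high / 101 intermediate
    / 32 low); :func:`pediatric_design` gives the childhood-style 12/93/72
    split. ``noise_sd`` is the residual SD on the latent log2 scale around a
    planted dependency; ``latent_sd`` is the per-gene biological variation
    that drives all pairwise dependence.
    """

    n_high: int = 37
    n_intermediate: int = 101
    n_low: int = 32
    n_genes: int = 1000
    n_rbps: int = 5
    n_planted_up: int = 50
    planted_log2fc: float = 1.5
    n_planted_edges: int = 15
    edge_kinds: tuple[str, ...] = EDGE_KINDS
    noise_sd: float = 0.3
    latent_sd: float = 1.0
    nb_dispersion: float = 0.1
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    depth_range: tuple[float, float] = (0.7, 1.3)
    upregulate_network_genes: bool = True
    baseline_hazard: float = 1e-3  # events per day
    survival_betas: dict = field(default_factory=dict)  # gene_id -> beta
    censoring_rate: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_high, self.n_intermediate, self.n_low, self.n_genes,
                  self.n_rbps)
        if any(c <= 0 for c in counts):
            raise ValueError("sample/gene/RBP counts must be positive")
        if self.n_planted_up > self.n_genes:
            raise ValueError("more planted upregulated genes than genes")
        if self.n_planted_edges > self.n_rbps * (self.n_genes - self.n_rbps):
            raise ValueError("more planted edges than available (rbp, target) pairs")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must be in [0, 1)")
        bad = set(self.edge_kinds) - set(EDGE_KINDS)
        if bad:
            raise ValueError(f"unknown edge kinds: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.n_high + self.n_intermediate + self.n_low


def pediatric_design(**overrides) -> SimulationDesign:
    """Childhood-style cohort preset: 12 high / 93 intermediate / 72 low."""
    return SimulationDesign(n_high=12, n_intermediate=93, n_low=72, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    upregulated: list[str]
    edges: list[tuple[str, str, str]]  # (rbp_id, target_id, kind)
    betas: dict[str, float]


def _edge_response(u: np.ndarray, kind: str) -> np.ndarray:
    """Latent response of a target to its RBP's centered latent signal.

    Each response is scaled to roughly unit variance for a standard-normal
    driver so the signal-to-noise ratio is governed by ``noise_sd`` alone.
    The quadratic kind is centered, making its Pearson correlation with the
    driver approximately zero.
    """
    if kind == "linear":
        return u
    if kind == "quadratic":
        c = u - u.mean()
        return (c * c - (c * c).mean()) / np.sqrt(2.0)
    if kind == "sinusoidal":
        return np.sin(u) / 0.658
    raise ValueError(f"unknown edge kind {kind!r}")


def _calibrate_censoring(hazards: np.ndarray, rate: float) -> float:
    """Upper bound of the uniform censoring window giving the target rate.

    For C ~ U(0, c) and T ~ Exp(h), P(censored) = (1 − e^{−hc})/(hc);
    averaged over subjects this is decreasing in c, so bisection applies.
    """

    def mean_censored(c: float) -> float:
        z = hazards * c
        return float(np.mean((1.0 - np.exp(-z)) / z))

    lo, hi = 1e-9, 1.0
    while mean_censored(hi) > rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_censored(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, CohortAnnotation, GeneAnnotation, SyntheticTruth]:
    """Draw one cohort: counts, sample annotation, gene annotation, truth."""
    rng = np.random.default_rng(design.rng_seed)
    n = design.n_samples

    rbp_ids = [f"RBP{i + 1:03d}" for i in range(design.n_rbps)]
    other_ids = [f"G{i + 1:05d}" for i in range(design.n_genes - design.n_rbps)]
    gene_ids = rbp_ids + other_ids
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    risk = (["high"] * design.n_high + ["intermediate"] * design.n_intermediate
            + ["low"] * design.n_low)

    # --- latent log2 expression -------------------------------------------
    lo, hi = design.baseline_log2_mean_range
    mu = rng.uniform(lo, hi, size=design.n_genes)
    latent = mu[:, None] + rng.normal(0.0, design.latent_sd,
                                      size=(design.n_genes, n))

    # planted RBP -> target edges overwrite the target's variation
    edges: list[tuple[str, str, str]] = []
    if design.n_planted_edges:
        target_pool = rng.permutation(len(other_ids))[: design.n_planted_edges]
        for k, tpos in enumerate(target_pool):
            rbp_idx = k % design.n_rbps
            kind = design.edge_kinds[k % len(design.edge_kinds)]
            tgt_idx = design.n_rbps + int(tpos)
            u = (latent[rbp_idx] - mu[rbp_idx]) / design.latent_sd
            latent[tgt_idx] = (mu[tgt_idx]
                               + design.latent_sd * _edge_response(u, kind)
                               + rng.normal(0.0, design.noise_sd, size=n))
            edges.append((gene_ids[rbp_idx], gene_ids[tgt_idx], kind))

    # planted high-risk upregulation
    up_set: set[int] = set()
    if design.upregulate_network_genes:
        for rbp_id, tgt_id, _ in edges:
            up_set.add(gene_ids.index(rbp_id))
            up_set.add(gene_ids.index(tgt_id))
    free = [i for i in rng.permutation(design.n_genes) if i not in up_set]
    while len(up_set) < design.n_planted_up and free:
        up_set.add(int(free.pop()))
    high_mask = np.array([g == "high" for g in risk])
    for idx in up_set:
        latent[idx, high_mask] += design.planted_log2fc
    upregulated = sorted(gene_ids[i] for i in up_set)

    # --- negative-binomial counts -----------------------------------------
    depth = rng.uniform(*design.depth_range, size=n)
    mean_counts = (2.0 ** latent) * depth[None, :]
    if design.nb_dispersion > 0:
        shape = 1.0 / design.nb_dispersion
        lam = rng.gamma(shape, mean_counts / shape)
    else:
        lam = mean_counts
    counts = rng.poisson(lam).astype(np.int64)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), RAW_COUNTS)

    # --- survival ----------------------------------------------------------
    betas = dict(design.survival_betas)
    unknown = set(betas) - set(gene_ids)
    if unknown:
        raise ValueError(f"survival betas for unknown genes: {sorted(unknown)}")
    log_hr = np.zeros(n)
    for gene_id, beta in betas.items():
        row = latent[gene_ids.index(gene_id)]
        z = (row - row.mean()) / row.std()
        log_hr += beta * z
    hazards = design.baseline_hazard * np.exp(log_hr)
    event_times = rng.exponential(1.0 / hazards)
    if design.censoring_rate > 0:
        c_max = _calibrate_censoring(hazards, design.censoring_rate)
        censor_times = rng.uniform(0.0, c_max, size=n)
    else:
        censor_times = np.full(n, np.inf)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)
    ann = CohortAnnotation(pd.DataFrame({
        "risk_group": risk,
        "os_time": os_time,
        "os_event": os_event,
    }, index=pd.Index(sample_ids, name="sample_id")), time_units="days")

    # --- gene classes -------------------------------------------------------
    classes = np.array(["coding"] * design.n_genes, dtype=object)
    classes[: design.n_rbps] = "RBP"
    n_other = design.n_genes - design.n_rbps
    nc = rng.permutation(n_other)
    n_lnc = int(0.10 * n_other)
    n_sno = int(0.05 * n_other)
    n_circ = int(0.02 * n_other)
    classes[design.n_rbps + nc[:n_lnc]] = "lncRNA"
    classes[design.n_rbps + nc[n_lnc:n_lnc + n_sno]] = "snoRNA"
    classes[design.n_rbps + nc[n_lnc + n_sno:n_lnc + n_sno + n_circ]] = "circRNA_host"
    gene_ann = GeneAnnotation(pd.DataFrame({
        "symbol": gene_ids,
        "gene_class": classes,
    }, index=pd.Index(gene_ids, name="gene_id")))

    truth = SyntheticTruth(upregulated=upregulated, edges=edges, betas=betas)
    return expr, ann, gene_ann, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "upregulated": truth.upregulated,
            "edges": [list(e) for e in truth.edges],
            "betas": truth.betas,
        }, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        data = json.load(fh)
    return SyntheticTruth(upregulated=list(data["upregulated"]),
                          edges=[tuple(e) for e in data["edges"]],
                          betas=dict(data["betas"]))
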