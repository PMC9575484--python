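"""Tabular readers/writers and the domain containers shared by the pipeline.

All tables are UTF-8, tab-delimited, "." decimal. Networks are exported both
as an edge list (the canonical, round-trippable form) and as GraphML for
graph consumers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rbpnet")

RAW_COUNTS = "raw_counts"
LOG2_NORMALIZED = "log2_normalized"

RISK_GROUPS = ("low", "intermediate", "high", "missing")
GENE_CLASSES = ("RBP", "lncRNA", "snoRNA", "circRNA_host", "coding", "other")

#: float format used by every writer so that equal inputs give byte-identical files
FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A table is missing required columns or violates a field contract."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the offending position."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a units tag.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``units`` is ``raw_counts`` (nonnegative integers/floats) or
    ``log2_normalized``.
    """

    values: pd.DataFrame
    units: str

    def __post_init__(self) -> None:
        if self.units not in (RAW_COUNTS, LOG2_NORMALIZED):
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if self.units == RAW_COUNTS and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.units)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.units)


@dataclass
class CohortAnnotation:
    """Per-sample risk group and overall-survival endpoint.

    ``table`` is indexed by sample id with columns ``risk_group``, ``os_time``,
    ``os_event``. Samples with an unknown risk group are retained with
    ``risk_group == "missing"``; downstream stages filter them.
    """

    table: pd.DataFrame
    time_units: str = "days"

    def __post_init__(self) -> None:
        required = {"risk_group", "os_time", "os_event"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise SchemaError("duplicate sample ids in annotation")
        bad_group = set(self.table["risk_group"]) - set(RISK_GROUPS)
        if bad_group:
            raise SchemaError(f"unknown risk groups: {sorted(bad_group)}")
        events = self.table["os_event"]
        if not events.isin([0, 1]).all():
            bad = sorted(set(events) - {0, 1})
            raise SchemaError(f"os_event must be 0/1, found {bad}")
        if (self.table["os_time"] < 0).any():
            raise SchemaError("os_time must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def with_risk(self) -> "CohortAnnotation":
        """Drop samples whose risk group is unknown."""
        keep = self.table["risk_group"] != "missing"
        return CohortAnnotation(self.table.loc[keep], self.time_units)

    def group_sizes(self) -> dict[str, int]:
        return self.table["risk_group"].value_counts().to_dict()


@dataclass
class GeneAnnotation:
    """Per-gene class label (RBP / ncRNA classes / coding / other)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "gene_class" not in self.table.columns:
            raise SchemaError("gene annotation missing 'gene_class' column")
        if self.table.index.has_duplicates:
            raise SchemaError("duplicate gene ids in gene annotation")
        bad = set(self.table["gene_class"]) - set(GENE_CLASSES)
        if bad:
            raise SchemaError(f"unknown gene classes: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def genes_of_class(self, gene_class: str) -> list[str]:
        return list(self.table.index[self.table["gene_class"] == gene_class])

    def class_of(self, gene_id: str) -> str:
        if gene_id in self.table.index:
            return str(self.table.loc[gene_id, "gene_class"])
        logger.warning("gene %s absent from annotation; classed 'other'", gene_id)
        return "other"


@dataclass
class RunConfig:
    """Thresholds and modes steering a pipeline run.

    The differential-expression p threshold is deliberately surfaced in every
    report header because published analyses often leave it implicit.
    """

    de_p_threshold: float = 0.05
    de_log2fc_threshold: float = 1.0
    de_welch: bool = False
    edge_p_threshold: float = 1e-6
    edge_rd_threshold: float = 0.2
    bonferroni_mode: str = "fixed_threshold"  # or "alpha_over_m"
    bonferroni_alpha: float = 0.05
    survival_split: str = "median"
    cox_tie_method: str = "efron"  # or "breslow"
    normalize_method: str = "log2_quantile"  # or "tmm_log2cpm"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_p_threshold", "de_log2fc_threshold", "edge_p_threshold",
                     "edge_rd_threshold", "bonferroni_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("de_p_threshold", "edge_p_threshold", "bonferroni_alpha"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")
        if self.bonferroni_mode not in ("fixed_threshold", "alpha_over_m"):
            raise ValueError(f"unknown bonferroni_mode {self.bonferroni_mode!r}")
        if self.survival_split != "median":
            raise ValueError("only median survival split is supported")
        if self.cox_tie_method not in ("efron", "breslow"):
            raise ValueError(f"unknown cox_tie_method {self.cox_tie_method!r}")
        if self.normalize_method not in ("log2_quantile", "tmm_log2cpm"):
            raise ValueError(f"unknown normalize_method {self.normalize_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Expression matrix IO
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, units: str) -> ExpressionMatrix:
    """Read a tab-delimited gene-by-sample matrix.

    First column holds gene identifiers, first row sample identifiers.
    Duplicate gene rows collapse to the row with the highest total signal
    (with a warning); duplicate sample ids are an error; any non-numeric
    cell raises :class:`ParseError` naming its position.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = pd.Index(header[1:])
    if samples.has_duplicates:
        dups = samples[samples.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {df.iat[gi, si]!r} at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r} in {path}"
        )
    if numeric.index.has_duplicates:
        dup_ids = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.warning(
            "collapsing duplicate gene rows (keeping max total signal): %s", dup_ids
        )
        totals = numeric.sum(axis=1)
        order = np.argsort(-totals.to_numpy(), kind="stable")
        first_best = numeric.iloc[order]
        first_best = first_best[~first_best.index.duplicated(keep="first")]
        numeric = first_best.loc[pd.unique(numeric.index)]
    return ExpressionMatrix(numeric, units)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Annotation IO
# ---------------------------------------------------------------------------

def read_cohort_annotation(path: str | Path, time_units: str = "days") -> CohortAnnotation:
    """Read sample annotation with columns sample_id, risk_group, os_time, os_event.

    Rows with an empty/unknown risk group are flagged ``missing`` rather than
    dropped; filtering happens in the stages that need a risk label.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = ["sample_id", "risk_group", "os_time", "os_event"]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"annotation {path} missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    rg = df["risk_group"].astype("string").str.strip().str.lower()
    df["risk_group"] = rg.where(rg.isin(["low", "intermediate", "high"]), "missing")
    df["risk_group"] = df["risk_group"].fillna("missing").astype(str)
    df["os_time"] = pd.to_numeric(df["os_time"])
    df["os_event"] = pd.to_numeric(df["os_event"])
    return CohortAnnotation(df[["risk_group", "os_time", "os_event"]], time_units)


def write_cohort_annotation(ann: CohortAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "gene_class"]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"gene annotation {path} missing columns: {sorted(missing)}")
    if "symbol" not in df.columns:
        df["symbol"] = df["gene_id"]
    return GeneAnnotation(df.set_index("gene_id")[["symbol", "gene_class"]])


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Network IO  (RegulatoryNetwork lives in network.py; imported lazily to
# avoid a cycle)
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["rbp_id", "target_id", "target_class", "n", "r_d", "p_raw"]


def write_network(network, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a regulatory network as <prefix>.edges.tsv and <prefix>.graphml.

    The edge list is the canonical round-trippable representation; GraphML
    carries a ``role`` node attribute (rbp / target) for graph viewers.
    """
    prefix = Path(path_prefix)
    edge_path = prefix.with_suffix(".edges.tsv")
    graphml_path = prefix.with_suffix(".graphml")

    edges = network.edges.loc[:, EDGE_COLUMNS]
    edges.to_csv(edge_path, sep="\t", index=False, float_format=FLOAT_FMT)

    g = nx.DiGraph()
    rbps = list(dict.fromkeys(edges["rbp_id"]))
    targets = [t for t in dict.fromkeys(edges["target_id"]) if t not in rbps]
    for r in rbps:
        g.add_node(r, role="rbp")
    for t in targets:
        g.add_node(t, role="target")
    for row in edges.itertuples(index=False):
        g.add_edge(row.rbp_id, row.target_id, target_class=row.target_class,
                   n=int(row.n), r_d=float(row.r_d), p_raw=float(row.p_raw))
    nx.write_graphml(g, graphml_path)
    return edge_path, graphml_path


def read_network_edges(path: str | Path) -> pd.DataFrame:
    """Read an edge-list file written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"rbp_id": str, "target_id": str,
                                            "target_class": str})
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"edge list {path} missing columns: {sorted(missing)}")
    df["n"] = df["n"].astype(int)
    return df[EDGE_COLUMNS]
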