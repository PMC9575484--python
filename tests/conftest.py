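import numpy as np
import pandas as pd
import pytest

from rbpnet.io import (LOG2_NORMALIZED, RAW_COUNTS, CohortAnnotation,
                       ExpressionMatrix, GeneAnnotation, RunConfig)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, gene_ids=None, sample_ids=None, units=LOG2_NORMALIZED):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), units)


def make_annotation(risk_groups, os_time=None, os_event=None, sample_ids=None):
    n = len(risk_groups)
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n)]
    return CohortAnnotation(pd.DataFrame({
        "risk_group": list(risk_groups),
        "os_time": list(os_time) if os_time is not None else [1.0] * n,
        "os_event": list(os_event) if os_event is not None else [1] * n,
    }, index=pd.Index(sample_ids, name="sample_id")))


def make_gene_annotation(classes: dict[str, str]) -> GeneAnnotation:
    return GeneAnnotation(pd.DataFrame({
        "symbol": list(classes),
        "gene_class": list(classes.values()),
    }, index=pd.Index(list(classes), name="gene_id")))
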