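import numpy as np
import pandas as pd
import pytest

import deggnet as dg
from deggnet.io_formats import ExpressionMatrix, SampleAnnotation


@pytest.fixture(scope="session")
def fixture_study():
    """The bundled deterministic toy study (40 genes x 30 samples)."""
    return dg.fixture_small()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_expression(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_annotation(subgroups, samples=None, **covariates) -> SampleAnnotation:
    samples = samples or [f"s{i}" for i in range(len(subgroups))]
    return SampleAnnotation(
        pd.DataFrame({"subgroup": list(subgroups), **covariates}, index=samples)
    )


def two_gene_study(x, y, subgroups):
    """Minimal two-gene study for edge tests (gene GA predicts GB)."""
    expr = make_expression(np.vstack([x, y]), genes=["GA", "GB"])
    annot = make_annotation(subgroups)
    return expr, annot
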