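import numpy as np
import pandas as pd
import pytest

from flaresig.io import CountMatrix, SampleTable
from flaresig.normalization import ExpressionMatrix
from flaresig.simulate import SimConfig, simulate_study


def make_counts(values, probe_class, assays=None):
    """Build a CountMatrix from a 2-D array and a list of probe classes."""
    values = np.asarray(values)
    probes = [f"P{i}" for i in range(values.shape[0])]
    assays = assays or [f"A{j}" for j in range(values.shape[1])]
    return CountMatrix(
        values=pd.DataFrame(values, index=probes, columns=assays),
        probe_class=pd.Series(probe_class, index=probes, name="probe_class"),
    )


def make_expr(values, genes=None, assays=None, provenance=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    assays = assays or [f"a{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=assays),
        provenance=list(provenance or []),
    )


def make_meta(rows):
    """rows: list of (assay_id, sample_id, group, batch)."""
    return SampleTable(pd.DataFrame(
        rows, columns=["assay_id", "sample_id", "group", "batch"]))


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across read-only tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def no_noise_kwargs():
    """SimConfig overrides that suppress every noise source but counting."""
    return dict(dispersion=0.0, lane_factor_sd=0.0, batch_offset_sd=0.0,
                pos_dispersion=0.0)
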