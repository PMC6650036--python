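import numpy as np
import pandas as pd
import pytest

from refstab import CqMatrix, collapse_replicates, generate
from refstab.synthetic import coregulated_spec, developmental_spec, recovery_spec


def make_matrix(values, groups, genes=None, samples=None, calibrator=None) -> CqMatrix:
    """Build a CqMatrix from a plain array and a group label per sample."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return CqMatrix(df, pd.Series(list(groups), index=samples), calibrator)


@pytest.fixture(scope="session")
def developmental_matrix():
    """Collapsed candidate-gene matrix from the default developmental panel."""
    spec = developmental_spec(0)
    raw, truth = generate(spec, 0)
    m, _ = collapse_replicates(raw, calibrator_group="P5")
    return m.subset(truth["candidate_genes"])


@pytest.fixture(scope="session")
def coreg_matrix():
    spec = coregulated_spec(0)
    raw, _ = generate(spec, 0)
    m, _ = collapse_replicates(raw, calibrator_group="P5")
    return m


@pytest.fixture(scope="session")
def recovery_setup():
    spec = recovery_spec(0)
    raw, truth = generate(spec, 0)
    m, _ = collapse_replicates(raw, calibrator_group="P5")
    return m, truth
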