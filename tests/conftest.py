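import numpy as np
import pandas as pd
import pytest

import trioexpress as tx

LIBS = ("AA", "BB", "CC", "AC", "BC")


@pytest.fixture(scope="session")
def roles():
    return {r: r for r in LIBS}


@pytest.fixture(scope="session")
def experiment():
    """Default synthetic experiment with planted patterns (seed 1)."""
    return tx.generate_experiment(tx.SimConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(experiment, roles):
    counts, _ = experiment
    return tx.TrioExpressionModel(counts, roles).fit()


@pytest.fixture(scope="session")
def null_de():
    """Hybrid-vs-paternal DE calls on a fully null experiment (seed 3)."""
    counts, _ = tx.generate_experiment(tx.null_config(seed=3))
    norm = tx.normalize(counts, reference="CC")
    return tx.pairwise_de(norm, "AC", "CC")


def make_count_table(arr, libs=("L1", "L2"), genes=None):
    arr = np.asarray(arr, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    frame = pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"),
                         columns=list(libs))
    return tx.CountTable(frame)
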