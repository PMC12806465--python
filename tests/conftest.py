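import numpy as np
import pandas as pd
import pytest

from senoconverge.io import DETable, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_de_table(study_id, genes, log2fc, se=None, pvalue=None, padj=None):
    """Small DE table with sensible defaults for omitted columns."""
    n = len(genes)
    data = {"log2fc": np.asarray(log2fc, dtype=float)}
    data["se"] = np.full(n, 0.2) if se is None else np.asarray(se, dtype=float)
    if pvalue is None:
        from scipy import stats
        z = data["log2fc"] / data["se"]
        data["pvalue"] = 2 * stats.norm.sf(np.abs(z))
    else:
        data["pvalue"] = np.asarray(pvalue, dtype=float)
    if padj is not None:
        data["padj"] = np.asarray(padj, dtype=float)
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return DETable(study_id=study_id, data=df)


@pytest.fixture
def toy_tables():
    """Three toy studies over overlapping gene universes."""
    t1 = make_de_table("s1", ["a", "b", "c", "d"], [2.0, -1.0, 0.5, 0.1],
                       padj=[0.001, 0.01, 0.5, 0.9])
    t2 = make_de_table("s2", ["b", "c", "d", "e"], [-1.2, 0.4, 0.2, 3.0],
                       padj=[0.005, 0.6, 0.8, 0.0001])
    t3 = make_de_table("s3", ["a", "b", "c", "d", "e"], [1.8, -0.9, 0.3, 0.0, 2.5],
                       padj=[0.002, 0.02, 0.7, 1.0, 0.001])
    return [t1, t2, t3]


@pytest.fixture
def small_sets():
    return GeneSetCollection("toy", {
        "S1": ["a", "b"],
        "S2": ["c", "d", "e"],
        "S3": ["a", "c", "e"],
    })
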