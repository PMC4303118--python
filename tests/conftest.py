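import numpy as np
import pandas as pd
import pytest

from phosphoflow.preprocess import PROV_MEASURED, IntensityMatrix
from phosphoflow.tables_io import EvidenceRecord


def make_record(**kwargs) -> EvidenceRecord:
    defaults = dict(
        sample_id="s1",
        protein_id="P00001",
        gene_symbol="GeneA",
        residue="Y",
        position=100,
        localization_prob=0.99,
        raw_intensity=1000.0,
    )
    defaults.update(kwargs)
    return EvidenceRecord(**defaults)


def make_matrix(values, class_of, sites=None, observed=None) -> IntensityMatrix:
    """Build an IntensityMatrix from a 2-D array and sample->class mapping."""
    values = np.asarray(values, dtype=float)
    samples = list(class_of)
    sites = sites or [f"P{i:05d}_Y00100" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=sites, columns=samples)
    if observed is None:
        odf = ~vdf.isna()
    else:
        odf = pd.DataFrame(np.asarray(observed, dtype=bool), index=sites, columns=samples)
    prov = odf.map(lambda o: PROV_MEASURED if o else "")
    return IntensityMatrix(vdf, odf, prov, dict(class_of))


@pytest.fixture
def three_class_labels():
    class_of = {}
    for cls, n in [("p53", 8), ("PyMT", 8), ("Her2", 5)]:
        for i in range(n):
            class_of[f"{cls}_{i + 1:02d}"] = cls
    return class_of


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
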