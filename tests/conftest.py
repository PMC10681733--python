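import numpy as np
import pandas as pd
import pytest

from ptmquant import QuantTable, SampleDesign


def make_quant_table(values, samples=None, scale="log2", feature_ids=None, **meta_cols):
    """Build a QuantTable from a 2-D array with default metadata."""
    X = np.asarray(values, dtype=float)
    n, m = X.shape
    feature_ids = feature_ids or [f"F{i}" for i in range(n)]
    samples = samples or [f"s{j}" for j in range(m)]
    index = pd.Index(feature_ids, name="feature_id")
    meta = pd.DataFrame(
        {
            "gene_name": [f"G{i}" for i in range(n)],
            "protein_ids": [[fid] for fid in feature_ids],
            "razor_unique_peptides": 5,
            "is_contaminant": False,
            "is_reverse": False,
        },
        index=index,
    )
    for k, v in meta_cols.items():
        meta[k] = v
    return QuantTable(pd.DataFrame(X, index=index, columns=samples), meta, scale=scale)


def make_design(groups, plex_ids=None, references=None):
    """Design from a {sample: group} mapping (group None = reference)."""
    samples = list(groups)
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": [groups[s] for s in samples],
                "replicate": list(range(1, len(samples) + 1)),
                "plex_id": [plex_ids[s] for s in samples] if plex_ids else None,
                "channel": None,
                "is_reference": [s in (references or ())for s in samples],
            }
        )
    )


@pytest.fixture
def two_group_design():
    return make_design({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"})
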