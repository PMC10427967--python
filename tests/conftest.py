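import numpy as np
import pandas as pd
import pytest

from mscpotency.core import FeatureTable, PotencyAssayPanel, default_feature_meta
from mscpotency.synth import SyntheticSpec, generate_study


def make_table(values, roles=None, batches=None, lines=None, stage="raw", **meta_cols):
    """Small FeatureTable from a 2-D array; defaults: all experimental, one batch."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sids = [f"s{i + 1}" for i in range(n)]
    fids = [f"f{j + 1}" for j in range(p)]
    sample_meta = pd.DataFrame(
        {
            "line_id": lines if lines is not None else [f"L{i + 1}" for i in range(n)],
            "batch_id": batches if batches is not None else ["B1"] * n,
            "role": roles if roles is not None else ["experimental"] * n,
            "replicate_id": ["r01"] * n,
            **meta_cols,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return FeatureTable(
        values=pd.DataFrame(values, index=sample_meta.index, columns=fids),
        sample_meta=sample_meta,
        feature_meta=default_feature_meta(fids),
        stage=stage,
    )


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 0)."""
    return generate_study(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_lines=8,
        n_replicates_nmr=3,
        n_features={"ms_lipid": 40, "ms_polar": 40, "nmr": 30},
        n_informative={"ms_lipid": 4, "ms_polar": 4, "nmr": 4},
        seed=11,
    )
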