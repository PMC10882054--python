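import numpy as np
import pandas as pd
import pytest

from synvar.filtering import SYNAPSE_COLUMNS, ConnectivityMatrix, run_pipeline
from synvar.synthetic import ConnectomeConfig, InputTypeSpec, generate_connectome


@pytest.fixture(scope="session")
def small_connectome():
    """Two-hemisphere connectome at 40 columns/side with all noise sources."""
    cfg = ConnectomeConfig(n_columns_per_hemisphere=40, seed=7)
    return generate_connectome(cfg), cfg


@pytest.fixture(scope="session")
def small_pipeline(small_connectome):
    (syn, ann, truth), cfg = small_connectome
    matrix, agg, deduped = run_pipeline(syn, ann)
    return matrix, agg, deduped, truth


def random_synapse_table(rng, n, n_pairs=3, extent=300.0):
    """Small random table with clustered positions to provoke redundancy."""
    pre = rng.integers(0, n_pairs, n)
    rows = {
        "pre_segment_id": [f"p{i}" for i in pre],
        "post_cell_id": ["T0"] * n,
        "x_nm": rng.uniform(0, extent, n),
        "y_nm": rng.uniform(0, extent, n),
        "z_nm": rng.uniform(0, extent, n),
        "cleft_score": rng.uniform(40, 120, n),
        "compartment": ["dendritic"] * n,
    }
    return pd.DataFrame(rows)[SYNAPSE_COLUMNS]


def matrix_from_frame(df, mode="absolute"):
    return ConnectivityMatrix(pd.DataFrame(df), mode)
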