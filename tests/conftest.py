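import numpy as np
import pandas as pd
import pytest

from riverdiv.river_network import RiverNetwork
from riverdiv.tables_io import CommunityMatrix, ReadCountTable


def make_table(counts: dict, meta_overrides: dict | None = None) -> ReadCountTable:
    """Build a small ReadCountTable from {sample_id: {taxon: count}}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    df.index.name = "sample_id"
    meta = pd.DataFrame(
        {
            "site_id": [s.split("_")[0] for s in df.index],
            "replicate_index": [1] * len(df),
            "bank": ["centre"] * len(df),
            "primer": ["kelly"] * len(df),
            "is_negative": [s.startswith("NEG") for s in df.index],
        },
        index=df.index,
    )
    for (row, col), val in (meta_overrides or {}).items():
        meta.loc[row, col] = val
    return ReadCountTable(counts=df, meta=meta)


@pytest.fixture
def tiny_table() -> ReadCountTable:
    return make_table(
        {
            "A_r1": {"t1": 100, "t2": 0, "t3": 7},
            "A_r2": {"t1": 80, "t2": 5, "t3": 0},
            "B_r1": {"t1": 0, "t2": 900, "t3": 3},
            "NEG1": {"t1": 2, "t2": 0, "t3": 5},
        }
    )


@pytest.fixture
def presence_matrix() -> CommunityMatrix:
    values = pd.DataFrame(
        {
            "t1": [1, 1, 0, 0],
            "t2": [1, 0, 1, 0],
            "t3": [0, 1, 1, 1],
            "t4": [1, 0, 0, 0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="site_id"),
    )
    return CommunityMatrix(values=values, mode="presence")


@pytest.fixture
def y_network() -> RiverNetwork:
    # outlet - 4 km - confluence, two branches of 10 and 5 km
    return RiverNetwork.from_edges(
        [("out", "conf", 4.0), ("conf", "A", 10.0), ("conf", "B", 5.0)],
        outlet="out",
    )


def random_presence(rng: np.random.Generator, n_sites: int, n_taxa: int) -> CommunityMatrix:
    values = pd.DataFrame(
        (rng.random((n_sites, n_taxa)) < 0.5).astype(np.int64),
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    return CommunityMatrix(values=values, mode="presence")
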