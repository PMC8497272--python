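import numpy as np
import pandas as pd
import pytest

from fusionsig import DERecord, SimConfig, simulate_atac, simulate_de_table
from fusionsig.io import from_records


def make_random_table(seed: int, n: int = 400) -> pd.DataFrame:
    """Randomized canonical DE frame stressing all filter branches:
    zeros in either condition, sub-threshold reads, missing numerics."""
    rng = np.random.default_rng(seed)
    mock = rng.choice([0.0, 3.0, 15.0, 120.0, 800.0], size=n, p=[0.1, 0.15, 0.25, 0.3, 0.2])
    exp = rng.choice([0.0, 3.0, 15.0, 120.0, 800.0], size=n, p=[0.1, 0.15, 0.25, 0.3, 0.2])
    log2fc = rng.normal(0, 2.2, size=n)
    pvals = rng.uniform(0, 1, size=n) ** 2
    # a few incomplete rows
    miss = rng.choice(n, size=n // 40, replace=False)
    log2fc[miss] = np.nan
    chroms = rng.choice([str(i) for i in range(1, 23)] + ["X", "Y", "MT", "other"], size=n)
    df = pd.DataFrame(
        {"gene_id": [f"R{i:05d}" for i in range(n)],
         "symbol": [f"SYM{i}" for i in range(n)],
         "chromosome": pd.array(chroms, dtype="string"),
         "biotype": pd.array(rng.choice(["protein_coding", "processed_pseudogene",
                                         "lincRNA", None], size=n), dtype="string"),
         "mock_reads": mock, "exp_reads": exp,
         "log2fc": log2fc, "pvalue": pvals, "padj": np.minimum(pvals * 3, 1.0)}
    )
    from fusionsig.io import finalize_table

    frame, _ = finalize_table(df)
    return frame


@pytest.fixture
def random_table():
    return make_random_table


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """Five hand-written records covering up/down/null/de-novo/shut-down."""
    return from_records([
        DERecord("g1", "ALPHA1", "1", "protein_coding", 20.0, 900.0, 5.5, 1e-8),
        DERecord("g2", "BETA2", "2", "protein_coding", 400.0, 30.0, -3.7, 1e-6),
        DERecord("g3", "GAMMA3", "X", "protein_coding", 55.0, 60.0, 0.1, 0.8),
        DERecord("g4", "DELTA4", "3", None, 0.0, 57.0, 6.8, 1e-4),
        DERecord("g5", "EPS5", "MT", None, 12.0, 0.0, -4.6, 1e-3),
    ])


@pytest.fixture(scope="session")
def strong_cfg() -> SimConfig:
    """Strong-effect regime: 8-fold changes, low dispersion."""
    return SimConfig(n_genes=1500, n_up=50, n_down=30, n_denovo=20, n_shutdown=10,
                     dispersion=0.05, seed=11)


@pytest.fixture(scope="session")
def strong_sim(strong_cfg):
    """(de_table, atac_table, truth) for the strong-effect regime."""
    table, truth = simulate_de_table(strong_cfg)
    atac, truth = simulate_atac(strong_cfg, truth)
    return table, atac, truth
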