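"""Shared cohort definition for the numbered analysis scripts.

Six synthetic cell lines vs one mock, mirroring the batch design of a
two-construct fusion-protein experiment: each single fusion construct, its
reciprocal partner, and the two co-expression lines.  Planted signature
sizes keep the single < reciprocal < co-expression pattern at one-tenth of
the original study's scale; every line also carries planted de novo and
shut-down genes and a linked accessibility table.
"""

from pathlib import Path

from fusionsig import SimConfig, read_de_table

COHORT = {
    "direct_1": (9, 1), "reciprocal_1": (20, 1), "co_1": (98, 48),
    "direct_2": (61, 8), "reciprocal_2": (5, 1), "co_2": (66, 7),
}
N_GENES = 2000
SEED = 1

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"


def line_config(label: str, seed: int = SEED) -> SimConfig:
    n_up, n_down = COHORT[label]
    i = list(COHORT).index(label)
    return SimConfig(n_genes=N_GENES, n_up=n_up, n_down=n_down,
                     n_denovo=15, n_shutdown=8, dispersion=0.05,
                     seed=(seed * 1000 + i) % (2**31))


def load_cohort():
    """Reload the generated cohort tables through the ingestion layer."""
    out = {}
    for label in COHORT:
        d = COHORT_DIR / label
        mace, _ = read_de_table(d / "mace.tsv")
        atac, _ = read_de_table(d / "atac.tsv")
        out[label] = (mace, atac)
    return out
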