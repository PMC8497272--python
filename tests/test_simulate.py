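"""Synthetic generator: construction guarantees, determinism, and the
minimal DE routine against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionsig import SimConfig, simple_de, simulate_atac, simulate_counts, size_factors
from fusionsig.simulate import simulate_de_table


def test_truth_counts_and_matrix_shape():
    cfg = SimConfig(n_genes=1000, n_up=50, n_down=20, n_denovo=10, n_shutdown=5, seed=1)
    counts, truth = simulate_counts(cfg)
    assert counts.shape == (1000, 6)
    vc = truth["status"].value_counts()
    assert vc["up"] == 50 and vc["down"] == 20
    assert vc["denovo"] == 10 and vc["shutdown"] == 5
    assert (counts.to_numpy() >= 0).all()
    assert counts.to_numpy().dtype.kind == "i"


def test_structural_zero_patterns():
    cfg = SimConfig(n_genes=800, n_denovo=30, n_shutdown=15, seed=3)
    counts, truth = simulate_counts(cfg)
    mock_cols = [c for c in counts.columns if c.startswith("mock")]
    exp_cols = [c for c in counts.columns if c.startswith("exp")]
    denovo = truth.loc[truth["status"] == "denovo", "gene_id"]
    shut = truth.loc[truth["status"] == "shutdown", "gene_id"]
    assert (counts.loc[denovo, mock_cols].to_numpy() == 0).all()
    assert (counts.loc[denovo, exp_cols].sum(axis=1) > 0).all()
    assert (counts.loc[shut, exp_cols].to_numpy() == 0).all()


def test_same_seed_bit_identical():
    cfg = SimConfig(n_genes=500, seed=42)
    c1, t1 = simulate_counts(cfg)
    c2, t2 = simulate_counts(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(t1, t2)


def test_overplanting_is_hard_error():
    with pytest.raises(ValueError, match="exceed"):
        simulate_counts(SimConfig(n_genes=100, n_up=60, n_down=60))


def test_size_factors_recover_doubled_library():
    # sample B is exactly 2x sample A: median of ratios to the per-gene
    # geometric mean sqrt(2*k^2)=k*sqrt(2) is (1/sqrt(2), sqrt(2)) -> 1:2
    a = np.array([10.0, 100.0, 50.0, 7.0])
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    sf = size_factors(counts)
    np.testing.assert_allclose(sf[1] / sf[0], 2.0, rtol=1e-12)
    np.testing.assert_allclose(sf[0] * sf[1], 1.0, rtol=1e-12)


def test_identical_counts_give_null_result():
    rng = np.random.default_rng(0)
    # per-gene constant profiles: size factors are all 1, so identical
    # counts must give exactly log2fc = 0 and p = 1
    mat = np.repeat(rng.poisson(100, size=(50, 1)).astype(float) + 1, 6, axis=1)
    counts = pd.DataFrame(mat, columns=["mock_1", "mock_2", "mock_3", "exp_1", "exp_2", "exp_3"],
                          index=[f"g{i}" for i in range(50)])
    de = simple_de(counts)
    assert de["log2fc"].abs().max() == pytest.approx(0.0)
    assert de["pvalue"].min() == pytest.approx(1.0)


def test_all_zero_matrix_is_error():
    counts = pd.DataFrame(np.zeros((5, 6)),
                          columns=["mock_1", "mock_2", "mock_3", "exp_1", "exp_2", "exp_3"])
    with pytest.raises(ValueError):
        simple_de(counts)


def test_two_replicates_required():
    counts = pd.DataFrame(np.ones((5, 2)), columns=["mock_1", "exp_1"])
    with pytest.raises(ValueError, match="replicates"):
        simple_de(counts)


def test_planted_fold_change_recovered():
    """With 8-fold planted effects and low dispersion the estimated log2FC
    lands within +-0.5 of 3 for at least 95% of planted genes."""
    cfg = SimConfig(n_genes=1000, n_up=100, n_down=0, n_denovo=0, n_shutdown=0,
                    fc_up=8.0, dispersion=0.05, seed=7)
    table, truth = simulate_de_table(cfg)
    up_ids = truth.loc[truth["status"] == "up", "gene_id"]
    est = table.set_index("gene_id").loc[up_ids, "log2fc"]
    assert (np.abs(est - 3.0) <= 0.5).mean() >= 0.95


def test_atac_link_certainty_boundary():
    cfg = SimConfig(n_genes=600, n_up=40, accessibility_link=1.0, seed=5)
    _, truth = simulate_counts(cfg)
    atac, truth = simulate_atac(cfg, truth)
    up_ids = truth.loc[truth["status"] == "up", "gene_id"].astype(str)
    sub = atac.set_index("gene_id").loc[up_ids]
    assert (sub["log2fc"] > 0).all() and (sub["pvalue"] < 0.05).all()
    assert (truth.loc[truth["status"] == "up", "accessibility_status"] == "accessible").all()


def test_atac_link_binomial_interval():
    """pi=0.6 with 50 planted up genes: accessible count within the central
    99% interval of Bin(50, 0.6)."""
    cfg = SimConfig(n_genes=800, n_up=50, accessibility_link=0.6, seed=9)
    _, truth = simulate_counts(cfg)
    _, truth = simulate_atac(cfg, truth)
    k = int((truth["accessibility_status"] == "accessible").sum())
    lo, hi = stats.binom.interval(0.99, 50, 0.6)
    assert lo <= k <= hi


def test_atac_requires_matching_truth():
    cfg_a = SimConfig(n_genes=300, seed=1)
    cfg_b = SimConfig(n_genes=300, seed=2)
    _, truth = simulate_counts(cfg_a)
    with pytest.raises(ValueError, match="SimConfig"):
        simulate_atac(cfg_b, truth)


def test_atac_deterministic():
    cfg = SimConfig(n_genes=300, n_up=20, seed=13)
    _, truth = simulate_counts(cfg)
    a1, _ = simulate_atac(cfg, truth)
    a2, _ = simulate_atac(cfg, truth)
    pd.testing.assert_frame_equal(a1, a2)


def test_proportion_validation():
    with pytest.raises(ValueError, match="biotype_mix"):
        SimConfig(biotype_mix={"PCG": 0.9}).validate()
    with pytest.raises(ValueError, match="accessibility_link"):
        SimConfig(accessibility_link=1.2).validate()
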