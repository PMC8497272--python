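"""Chromosome-usage fingerprints: hand oracle, conservation laws and the
resampling null."""

import numpy as np
import pandas as pd
import pytest

from fusionsig import DERecord, fingerprint, fingerprint_null
from fusionsig.io import from_records


def _background(n=100, n_chr1=10):
    """n expressed genes, n_chr1 on chromosome 1, the rest spread over 2-5."""
    recs = []
    for i in range(n):
        chrom = "1" if i < n_chr1 else str(2 + i % 4)
        recs.append(DERecord(f"b{i:03d}", f"S{i}", chrom, None, 50.0, 50.0, 0.0, 0.5))
    return from_records(recs)


def test_hand_computed_delta():
    """Background: 10/100 genes on chr1; signature: 2/5 on chr1.
    delta(chr1) = 40 - 10 = +30 percentage points."""
    bg = _background()
    sig = bg.iloc[[0, 1, 10, 20, 30]]  # two chr1 members out of five
    fp = fingerprint(sig, bg)
    assert fp.delta("1") == pytest.approx(30.0)
    assert fp.frame["background_pct"].sum() == pytest.approx(100.0)
    assert fp.frame["signature_pct"].sum() == pytest.approx(100.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("reference", ["background", "uniform"])
def test_deltas_sum_to_zero(random_table, seed, reference):
    table = random_table(seed)
    bg = table.loc[table["expressed"]]
    rng = np.random.default_rng(seed)
    sig = bg.iloc[rng.choice(len(bg), size=40, replace=False)]
    fp = fingerprint(sig, table, reference=reference)
    assert abs(fp.frame["delta"].sum()) < 1e-9


def test_scale_invariance_under_background_duplication(random_table):
    table = random_table(8)
    sig = table.loc[table["expressed"]].head(30)
    doubled = pd.concat([table, table], ignore_index=True)
    fp1 = fingerprint(sig, table)
    fp2 = fingerprint(sig, doubled)
    np.testing.assert_allclose(fp1.frame["delta"], fp2.frame["delta"])


def test_empty_signature_all_zero():
    bg = _background()
    fp = fingerprint(bg.iloc[0:0], bg)
    assert (fp.frame["delta"] == 0).all()


def test_empty_background_is_error():
    bg = _background()
    with pytest.raises(ValueError, match="expressed"):
        fingerprint(bg.head(3), bg.iloc[0:0])


def test_unplaced_genes_excluded_and_counted():
    recs = [DERecord(f"g{i}", None, "1", None, 10.0, 10.0, 0.0, 0.5) for i in range(9)]
    recs.append(DERecord("g9", None, "GL000220.1", None, 10.0, 10.0, 0.0, 0.5))
    bg = from_records(recs)
    fp = fingerprint(bg.head(5), bg)
    assert fp.n_excluded == 1  # the scaffold gene, normalized to "other"
    assert fp.n_background == 9


def test_uniform_signatures_stay_inside_null_envelope(strong_sim):
    """Signatures drawn uniformly from the background are, by construction,
    null: their max |delta| should sit below the 99.9% resampling envelope
    in the vast majority of draws (20 seeds, allow one excursion)."""
    table, _, _ = strong_sim
    bg = table.loc[table["expressed"]]
    env = fingerprint_null(200, table, n_resamples=500, seed=123)
    cap = float(env.loc[env["chromosome"] == "__max_abs__", "hi"].iloc[0])
    excursions = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        sig = bg.iloc[rng.choice(len(bg), size=200, replace=False)]
        _, worst = fingerprint(sig, table).max_abs_delta()
        excursions += abs(worst) > cap
    assert excursions <= 1


def test_null_envelope_properties(strong_sim):
    table, _, _ = strong_sim
    n_bg = int(table["expressed"].sum())
    # full-background "signature": every resample is the background itself
    env_full = fingerprint_null(n_bg, table, n_resamples=100, seed=1)
    assert np.allclose(env_full[["lo", "hi"]].to_numpy(), 0.0)
    # envelope widens as the signature shrinks
    env_500 = fingerprint_null(500, table, n_resamples=300, seed=2)
    env_50 = fingerprint_null(50, table, n_resamples=300, seed=2)
    w500 = (env_500["hi"] - env_500["lo"]).iloc[:-1].mean()
    w50 = (env_50["hi"] - env_50["lo"]).iloc[:-1].mean()
    assert w50 > w500
    # deterministic under a fixed seed
    again = fingerprint_null(500, table, n_resamples=300, seed=2)
    pd.testing.assert_frame_equal(env_500, again)


def test_null_envelope_input_contracts(strong_sim):
    table, _, _ = strong_sim
    with pytest.raises(ValueError, match="n_resamples"):
        fingerprint_null(10, table, n_resamples=50, seed=0)
    with pytest.raises(ValueError, match="exceeds"):
        fingerprint_null(10**7, table, n_resamples=100, seed=0)
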