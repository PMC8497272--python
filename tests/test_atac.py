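"""Accessibility signatures, expression x chromatin cross-tabs and the
per-chromosome track counts."""

import numpy as np
import pandas as pd
import pytest

from fusionsig import (
    DERecord, SimConfig, atac_signature, circos_track_data, crosstab_mace_atac,
    filter_down, filter_up, simulate_atac, simulate_counts,
)
from fusionsig.atac import ACCESSIBLE, NO_DATA, NON_ACCESSIBLE, PG_NA
from fusionsig.genetypes import PCG
from fusionsig.io import CIRCOS, from_records
from fusionsig.simulate import simulate_de_table


def test_accessibility_rule_forced():
    frame = from_records([
        DERecord("a", "A1", "1", None, 10.0, 50.0, 1.4, 0.001),   # accessible
        DERecord("b", "B1", "2", None, 10.0, 50.0, -2.0, 0.001),  # non-accessible
        DERecord("c", "C1", "3", None, 10.0, 50.0, 0.0, 0.001),   # log2 = 0: neither
        DERecord("d", "D1", "4", None, 10.0, 2.0, 1.4, 0.001),    # reads floor exclusive
        DERecord("e", "E1", "5", None, 10.0, 50.0, 1.4, 0.2),     # p too large
        DERecord("f", "F1", "6", None, 10.0, 50.0, 0.5, 0.001),   # |log2| below floor
    ])
    acc, nonacc = atac_signature(frame, log2_min=1.0)
    assert set(acc["gene_id"]) == {"a"}
    assert set(nonacc["gene_id"]) == {"b"}


def test_certain_link_all_planted_up_accessible():
    cfg = SimConfig(n_genes=500, n_up=30, accessibility_link=1.0, seed=4)
    _, truth = simulate_counts(cfg)
    atac, truth = simulate_atac(cfg, truth)
    acc, _ = atac_signature(atac)
    up_ids = set(truth.loc[truth["status"] == "up", "gene_id"])
    assert up_ids <= set(acc["gene_id"])


@pytest.fixture(scope="module")
def linked_line():
    cfg = SimConfig(n_genes=1500, n_up=60, n_down=30, n_denovo=10, n_shutdown=5,
                    dispersion=0.05, accessibility_link=0.8, seed=77)
    table, truth = simulate_de_table(cfg)
    atac, truth = simulate_atac(cfg, truth)
    return table, atac, truth


def test_crosstab_partitions_each_signature(linked_line):
    table, atac, _ = linked_line
    up = filter_up(table, CIRCOS, "L")
    down = filter_down(table, CIRCOS, "L")
    xtab = crosstab_mace_atac(up, down, atac_signature(atac))
    assert xtab.direction_total("up") == len(up)
    assert xtab.direction_total("down") == len(down)


def test_crosstab_cells_match_bruteforce(linked_line):
    table, atac, truth = linked_line
    up = filter_up(table, CIRCOS, "L")
    down = filter_down(table, CIRCOS, "L")
    acc, nonacc = atac_signature(atac)
    xtab = crosstab_mace_atac(up, down, (acc, nonacc))

    acc_ids, nonacc_ids = set(acc["gene_id"]), set(nonacc["gene_id"])
    bio = truth.set_index("gene_id")["biotype"]
    for direction, sig in (("up", up), ("down", down)):
        brute = {ch: {gc: 0 for gc in (PCG, PG_NA)} for ch in (ACCESSIBLE, NON_ACCESSIBLE, NO_DATA)}
        for gid in sig.gene_ids:
            ch = ACCESSIBLE if gid in acc_ids else NON_ACCESSIBLE if gid in nonacc_ids else NO_DATA
            gc = PCG if bio.get(gid) == "PCG" else PG_NA  # non-coding folds into PG/NA
            brute[ch][gc] += 1
        assert xtab.counts[direction] == brute


def test_crosstab_respects_accessibility_link(linked_line):
    """Planted up genes made accessible by the generator surface in the
    accessible column of the up direction."""
    table, atac, truth = linked_line
    up = filter_up(table, CIRCOS, "L")
    xtab = crosstab_mace_atac(up, filter_down(table, CIRCOS, "L"), atac_signature(atac))
    linked = set(truth.loc[truth["accessibility_status"] == "accessible", "gene_id"])
    n_linked_in_sig = len(linked & up.gene_ids)
    n_accessible = sum(xtab.counts["up"][ACCESSIBLE].values())
    assert n_accessible >= n_linked_in_sig  # null passers may add a few


def test_track_totals_match_bruteforce(linked_line):
    table, atac, _ = linked_line
    tracks = circos_track_data(table, atac, log2_cut=1.0)
    brute_up = sum(
        1 for _, r in table.iterrows()
        if not r["incomplete"] and r["pvalue"] < 0.05 and r["log2fc"] >= 1
    )
    brute_acc_dn = sum(
        1 for _, r in atac.iterrows()
        if not r["incomplete"] and r["pvalue"] < 0.05 and r["log2fc"] < 0
    )
    assert tracks.totals["expression_up"] == brute_up
    assert tracks.totals["accessibility_down"] == brute_acc_dn
    for col in tracks.TRACKS:
        assert tracks.frame[col].sum() == tracks.totals[col]


def test_tightening_cut_never_increases_tracks(linked_line):
    table, atac, _ = linked_line
    t1 = circos_track_data(table, atac, log2_cut=1.0)
    t2 = circos_track_data(table, atac, log2_cut=2.0)
    for col in ("expression_up", "expression_down"):
        assert (t2.frame[col] <= t1.frame[col]).all()


def test_empty_tables_all_zero_tracks():
    empty = from_records([]).iloc[0:0]
    for col in ("gene_id", "symbol", "chromosome", "biotype"):
        empty[col] = empty.get(col, pd.Series(dtype="string"))
    tracks = circos_track_data(empty, empty)
    assert all(v == 0 for v in tracks.totals.values())
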