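"""Signature filters against a naive per-row oracle, plus summaries and
volcano classification."""

import math

import numpy as np
import pandas as pd
import pytest

from fusionsig import (
    DERecord, SimConfig, Thresholds, combined_total_reads, filter_down,
    filter_up, summarize, volcano_points,
)
from fusionsig.io import STRICT, from_records, thresholds_preset
from fusionsig.signatures import DOWN_SIG, NOT_SIG, UP_SIG
from fusionsig.simulate import simulate_de_table


def oracle_filter(table: pd.DataFrame, thr: Thresholds, direction: str) -> set[str]:
    """Independent per-row predicate scan."""
    keep = set()
    for _, row in table.iterrows():
        if row["incomplete"] or not row["expressed"]:
            continue
        p = row["pvalue"]
        if not (p < thr.p_max):
            continue
        if direction == "up":
            reads, lfc_ok = row["exp_reads"], False
            if not math.isnan(row["log2fc"]):
                lfc_ok = row["log2fc"] >= thr.log2_min if thr.log2_inclusive else row["log2fc"] > thr.log2_min
        else:
            reads, lfc_ok = row["mock_reads"], False
            if not math.isnan(row["log2fc"]):
                lfc_ok = row["log2fc"] <= -thr.log2_min if thr.log2_inclusive else row["log2fc"] < -thr.log2_min
        reads_ok = reads >= thr.min_reads if thr.reads_inclusive else reads > thr.min_reads
        if reads_ok and lfc_ok:
            keep.add(str(row["gene_id"]))
    return keep


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("preset", ["strict", "circos"])
def test_filters_match_rowwise_oracle(random_table, seed, preset):
    table = random_table(seed)
    thr = thresholds_preset(preset)
    assert filter_up(table, thr).gene_ids == oracle_filter(table, thr, "up")
    assert filter_down(table, thr).gene_ids == oracle_filter(table, thr, "down")


@pytest.mark.parametrize("tighten", [
    {"min_reads": 50.0}, {"p_max": 0.01}, {"log2_min": 3.0}, {"reads_inclusive": False},
])
def test_tightening_never_grows_signature(random_table, tighten):
    table = random_table(5)
    loose, tight = STRICT, Thresholds(**{**STRICT.__dict__, **tighten})
    assert filter_up(table, tight).gene_ids <= filter_up(table, loose).gene_ids
    assert filter_down(table, tight).gene_ids <= filter_down(table, loose).gene_ids


@pytest.mark.parametrize("seed", [0, 7])
def test_up_down_disjoint(random_table, seed):
    table = random_table(seed)
    assert not (filter_up(table).gene_ids & filter_down(table).gene_ids)


def test_shutdown_record_can_enter_down_signature():
    """A gene with ample mock reads but zero induced reads passes the down
    filter (and is simultaneously a shut-down candidate)."""
    frame = from_records([DERecord("s1", "SHUT1", "4", None, 500.0, 0.0, -9.9, 1e-12)])
    assert filter_down(frame).gene_ids == {"s1"}


def test_planted_strong_up_genes_recovered_exactly():
    cfg = SimConfig(n_genes=1200, n_up=50, n_down=0, n_denovo=0, n_shutdown=0,
                    fc_up=8.0, dispersion=0.05, seed=21)
    table, truth = simulate_de_table(cfg)
    planted = set(truth.loc[truth["status"] == "up", "gene_id"].astype(str))
    assert filter_up(table).gene_ids == planted


def test_null_table_signature_within_binomial_bound():
    """With nothing planted, the chance of passing p < p_max alone bounds
    the signature size; check against the 3-sigma binomial envelope."""
    cfg = SimConfig(n_genes=3000, n_up=0, n_down=0, n_denovo=0, n_shutdown=0, seed=2)
    table, _ = simulate_de_table(cfg)
    n = int(table["expressed"].sum())
    bound = n * STRICT.p_max + 3 * math.sqrt(n * STRICT.p_max * (1 - STRICT.p_max))
    assert len(filter_up(table)) + len(filter_down(table)) <= bound


def test_summary_statistics(toy_table):
    up = filter_up(toy_table, label="toy")
    down = filter_down(toy_table, label="toy")
    s_up, s_down = summarize(up), summarize(down)
    assert s_up.n_genes == len(up) and sum(s_up.per_biotype.values()) == s_up.n_genes
    # total reads sum the direction-relevant condition
    assert s_up.total_reads == pytest.approx(up.frame["exp_reads"].sum())
    assert s_down.total_reads == pytest.approx(down.frame["mock_reads"].sum())
    assert combined_total_reads(up, down) == pytest.approx(s_up.total_reads + s_down.total_reads)


def test_empty_signature_summary_is_zero(toy_table):
    empty = filter_up(toy_table, Thresholds(min_reads=1e9))
    s = summarize(empty)
    assert s.n_genes == 0 and s.total_reads == 0.0
    assert sum(s.per_biotype.values()) == 0


@pytest.mark.parametrize(
    "log2fc,p,expected",
    [(3.0, 1e-6, UP_SIG), (1.0, 1e-6, NOT_SIG), (-3.0, 1e-6, DOWN_SIG),
     (3.0, 1e-4, NOT_SIG), (-1.5, 1e-9, NOT_SIG)],
)
def test_volcano_rule_forced_labels(log2fc, p, expected):
    frame = from_records([DERecord("v", "V1", "1", None, 10.0, 10.0, log2fc, p)])
    pts = volcano_points(frame)
    assert list(pts["category"]) == [expected]


def test_volcano_zero_p_capped():
    frame = from_records([DERecord("v", "V1", "1", None, 10.0, 10.0, 3.0, 0.0)])
    assert volcano_points(frame)["neg_log10_p"].iloc[0] == 300.0


def test_volcano_counts_match_bruteforce(random_table):
    table = random_table(3, n=1000)
    pts = volcano_points(table)
    brute = {UP_SIG: 0, DOWN_SIG: 0, NOT_SIG: 0}
    for _, row in table.iterrows():
        if math.isnan(row["log2fc"]) or math.isnan(row["pvalue"]):
            continue
        nlp = min(-math.log10(row["pvalue"]) if row["pvalue"] > 0 else math.inf, 300.0)
        if row["log2fc"] > 2 and nlp > 5:
            brute[UP_SIG] += 1
        elif row["log2fc"] < -2 and nlp > 5:
            brute[DOWN_SIG] += 1
        else:
            brute[NOT_SIG] += 1
    assert pts["category"].value_counts().to_dict() == {k: v for k, v in brute.items() if v}
    assert len(pts) == sum(brute.values())
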