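"""Threshold signatures, their summary statistics and volcano classification.

A *signature* is the set of genes from one cell line's DE table that pass a
direction-specific rule: up-regulated genes need the read floor on the
induced condition, p below the ceiling and log2FC above the floor; the
down rule mirrors it on the mock condition and negative log2FC.  Records
flagged incomplete or unexpressed never pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetypes import ClassificationRules, DEFAULT_RULES, GENE_TYPES, breakdown
from .io import Thresholds, STRICT, thresholds_preset


@dataclass
class Signature:
    """Direction-labeled gene set passing a threshold rule."""

    label: str
    direction: str  # "up" | "down"
    frame: pd.DataFrame
    thresholds: Thresholds = STRICT

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    @property
    def gene_ids(self) -> set[str]:
        return set(self.frame["gene_id"].astype(str))

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        from .io import write_de_table

        write_de_table(self.frame, path)


@dataclass
class SignatureSummary:
    """Size, read mass and gene-type composition of a signature."""

    label: str
    direction: str
    n_genes: int
    total_reads: float
    per_biotype: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"label": self.label, "direction": self.direction, "n_genes": self.n_genes,
             "total_reads": self.total_reads, "per_biotype": self.per_biotype},
            sort_keys=True,
        )


def _eligible(table: pd.DataFrame) -> pd.Series:
    ok = ~table["incomplete"].astype(bool) & table["expressed"].astype(bool)
    return ok


def _pvals(table: pd.DataFrame, thr: Thresholds) -> pd.Series:
    if thr.use_adjusted_p and "padj" in table.columns and table["padj"].notna().any():
        return table["padj"]
    return table["pvalue"]


def filter_up(table: pd.DataFrame, thr: Thresholds = STRICT, label: str = "") -> Signature:
    """Up-regulated signature: induced-condition read floor, p ceiling,
    positive log2FC floor."""
    p = _pvals(table, thr)
    mask = (
        _eligible(table)
        & thr.reads_pass(table["exp_reads"].fillna(0.0))
        & (p < thr.p_max).fillna(False)
        & pd.Series(thr.log2_pass_up(table["log2fc"]), index=table.index).fillna(False)
    )
    return Signature(label=label, direction="up", frame=table.loc[mask].copy(), thresholds=thr)


def filter_down(table: pd.DataFrame, thr: Thresholds = STRICT, label: str = "") -> Signature:
    """Down-regulated signature: mock-condition read floor, p ceiling,
    negative log2FC floor."""
    p = _pvals(table, thr)
    mask = (
        _eligible(table)
        & thr.reads_pass(table["mock_reads"].fillna(0.0))
        & (p < thr.p_max).fillna(False)
        & pd.Series(thr.log2_pass_down(table["log2fc"]), index=table.index).fillna(False)
    )
    return Signature(label=label, direction="down", frame=table.loc[mask].copy(), thresholds=thr)


def summarize(sig: Signature, rules: ClassificationRules = DEFAULT_RULES) -> SignatureSummary:
    """Summary statistics of one signature.

    ``total_reads`` sums the direction-relevant condition's mean reads over
    member genes: induced for up signatures, mock for down signatures
    (mirroring each filter's read floor).
    """
    reads_col = "exp_reads" if sig.direction == "up" else "mock_reads"
    bd = breakdown(sig, rules)
    return SignatureSummary(
        label=sig.label,
        direction=sig.direction,
        n_genes=len(sig),
        total_reads=float(sig.frame[reads_col].fillna(0.0).sum()),
        per_biotype=dict(bd.counts),
    )


def combined_total_reads(up: Signature, down: Signature) -> float:
    """Read mass of a combined up+down signature: each member contributes
    its direction-relevant condition's reads."""
    return float(up.frame["exp_reads"].fillna(0.0).sum()) + float(
        down.frame["mock_reads"].fillna(0.0).sum()
    )


UP_SIG, DOWN_SIG, NOT_SIG = "up-significant", "down-significant", "not-significant"


def volcano_points(
    table: pd.DataFrame,
    fc_cut: float = 2.0,
    logp_cut: float = 5.0,
    logp_cap: float = 300.0,
) -> pd.DataFrame:
    """Classify every record with finite log2FC and p for a volcano plot.

    Returns a frame (gene_id, symbol, log2fc, neg_log10_p, category); p = 0
    is capped at ``logp_cap`` on the -log10 scale.
    """
    ok = table["log2fc"].notna() & table["pvalue"].notna() & np.isfinite(table["log2fc"])
    sub = table.loc[ok, ["gene_id", "symbol", "log2fc", "pvalue"]].copy()
    with np.errstate(divide="ignore"):
        nlp = -np.log10(sub["pvalue"].to_numpy(dtype=float))
    nlp = np.minimum(nlp, logp_cap)
    sub["neg_log10_p"] = nlp
    sig = sub["neg_log10_p"] > logp_cut
    cat = np.full(len(sub), NOT_SIG, dtype=object)
    cat[(sub["log2fc"] > fc_cut) & sig] = UP_SIG
    cat[(sub["log2fc"] < -fc_cut) & sig] = DOWN_SIG
    sub["category"] = cat
    return sub.drop(columns="pvalue")
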