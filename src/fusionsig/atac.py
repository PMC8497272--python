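"""Chromatin-accessibility signatures and MACE x ATAC cross-tabulation.

ATAC inputs arrive as gene-indexed DESeq2-style tables (peak-to-gene
assignment happens upstream); the same canonical frame layout as expression
tables is used, with ``log2fc`` holding the accessibility log2 change.

The accessibility filter keeps regions with more than ``min_reads`` induced
mean reads (exclusive by default), p below the ceiling and |log2| beyond the
floor; the sign of log2 then splits accessible (log2 > 0) from
non-accessible (log2 < 0) fractions.  Expression signatures are
cross-tabulated against those fractions by gene class (PG/NA composite vs
protein-coding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetypes import (PCG, PG, NA, ClassificationRules, DEFAULT_RULES, classify_frame)

ACCESSIBLE, NON_ACCESSIBLE, NO_DATA = "accessible", "non-accessible", "no-data"
CHROMATIN_CATEGORIES = (ACCESSIBLE, NON_ACCESSIBLE, NO_DATA)
PG_NA = "PG/NA"
GENE_CLASSES = (PCG, PG_NA)


def atac_signature(
    atac_table: pd.DataFrame,
    min_reads: float = 2.0,
    reads_inclusive: bool = False,
    p_max: float = 0.05,
    log2_min: float = 1.0,
    log2_inclusive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an ATAC DE table into (accessible, non-accessible) signatures.

    Regions with log2 exactly 0 land in neither set.  The read floor is
    applied to the induced condition's mean reads, exclusive by default.
    """
    reads = atac_table["exp_reads"].fillna(0.0)
    lfc = atac_table["log2fc"]
    p = atac_table["pvalue"]
    base = (
        ~atac_table["incomplete"].astype(bool)
        & (reads >= min_reads if reads_inclusive else reads > min_reads)
        & (p < p_max).fillna(False)
    )
    mag = lfc.abs()
    mag_ok = (mag >= log2_min) if log2_inclusive else (mag > log2_min)
    base &= mag_ok.fillna(False)
    accessible = atac_table.loc[base & (lfc > 0)].copy()
    non_accessible = atac_table.loc[base & (lfc < 0)].copy()
    return accessible, non_accessible


def _gene_class(frame: pd.DataFrame, rules: ClassificationRules, fold_other: str) -> pd.Series:
    """Collapse the seven gene types onto the PCG vs PG/NA dichotomy."""
    labels = classify_frame(frame, rules)
    out = labels.copy()
    out[labels.isin([PG, NA])] = PG_NA
    other = ~labels.isin([PCG, PG, NA])
    if fold_other == PG_NA:
        out[other] = PG_NA
    elif fold_other == PCG:
        out[other] = PCG
    else:
        raise ValueError("fold_other must be 'PG/NA' or 'PCG'")
    return out


@dataclass
class AccessibilityCrossTab:
    """Counts over direction x chromatin category x gene class.

    Per direction the cells partition the expression signature, so each
    direction's cell sum equals that signature's size.
    """

    counts: dict[str, dict[str, dict[str, int]]]
    labels: dict = field(default_factory=dict)

    def cell(self, direction: str, chromatin: str, gene_class: str) -> int:
        return self.counts[direction][chromatin][gene_class]

    def direction_total(self, direction: str) -> int:
        return sum(sum(c.values()) for c in self.counts[direction].values())

    def class_total(self, direction: str, gene_class: str) -> int:
        return sum(self.counts[direction][ch][gene_class] for ch in CHROMATIN_CATEGORIES)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": d, "chromatin": ch, "gene_class": gc, "n_genes": self.counts[d][ch][gc]}
            for d in self.counts
            for ch in CHROMATIN_CATEGORIES
            for gc in GENE_CLASSES
        ]
        return pd.DataFrame(rows)


def crosstab_mace_atac(
    mace_up,
    mace_down,
    atac_sets: tuple[pd.DataFrame, pd.DataFrame],
    rules: ClassificationRules = DEFAULT_RULES,
    fold_other: str = PG_NA,
) -> AccessibilityCrossTab:
    """Cross-tabulate expression signatures by chromatin status and class.

    Every signature gene gets exactly one chromatin category — accessible /
    non-accessible by membership in the ATAC signatures, ``no-data`` when
    absent from both — and one gene class (non-coding classes fold into
    PG/NA by default).
    """
    acc_ids = set(atac_sets[0]["gene_id"].astype(str))
    nonacc_ids = set(atac_sets[1]["gene_id"].astype(str))
    counts = {
        d: {ch: {gc: 0 for gc in GENE_CLASSES} for ch in CHROMATIN_CATEGORIES}
        for d in ("up", "down")
    }
    for direction, sig in (("up", mace_up), ("down", mace_down)):
        frame = sig.frame
        if not len(frame):
            continue
        classes = _gene_class(frame, rules, fold_other)
        for gid, gc in zip(frame["gene_id"].astype(str), classes):
            if gid in acc_ids:
                ch = ACCESSIBLE
            elif gid in nonacc_ids:
                ch = NON_ACCESSIBLE
            else:
                ch = NO_DATA
            counts[direction][ch][gc] += 1
    return AccessibilityCrossTab(counts=counts, labels={"fold_other": fold_other})


@dataclass
class CircosTracks:
    """Per-chromosome counts feeding a circular genome plot."""

    frame: pd.DataFrame  # chromosome x 4 count columns
    totals: dict[str, int]

    TRACKS = ("expression_up", "expression_down", "accessibility_up", "accessibility_down")


def circos_track_data(
    mace_table: pd.DataFrame,
    atac_table: pd.DataFrame,
    log2_cut: float = 1.0,
    p_max: float = 0.05,
    log2_inclusive: bool = True,
) -> CircosTracks:
    """Per-chromosome counts of deregulated genes and accessibility changes.

    Expression tracks count genes with |log2FC| beyond ``log2_cut``
    (inclusive by default) and p < ``p_max``, split by sign; accessibility
    tracks count ATAC regions with p < ``p_max`` split by log2 sign.
    """
    from .chromusage import CANONICAL_CHROMOSOMES

    order = CANONICAL_CHROMOSOMES + ["other"]

    def counts_for(table: pd.DataFrame, mask: pd.Series) -> np.ndarray:
        chroms = table.loc[mask.fillna(False), "chromosome"].astype(str)
        vc = chroms.value_counts()
        return np.array([int(vc.get(c, 0)) for c in order])

    m_lfc, m_p = mace_table["log2fc"], mace_table["pvalue"]
    ok = ~mace_table["incomplete"].astype(bool) & (m_p < p_max)
    up_mask = ok & ((m_lfc >= log2_cut) if log2_inclusive else (m_lfc > log2_cut))
    down_mask = ok & ((m_lfc <= -log2_cut) if log2_inclusive else (m_lfc < -log2_cut))

    a_ok = ~atac_table["incomplete"].astype(bool) & (atac_table["pvalue"] < p_max)
    a_up = a_ok & (atac_table["log2fc"] > 0)
    a_down = a_ok & (atac_table["log2fc"] < 0)

    data = {
        "expression_up": counts_for(mace_table, up_mask),
        "expression_down": counts_for(mace_table, down_mask),
        "accessibility_up": counts_for(atac_table, a_up),
        "accessibility_down": counts_for(atac_table, a_down),
    }
    frame = pd.DataFrame({"chromosome": order, **data})
    totals = {k: int(v.sum()) for k, v in data.items()}
    return CircosTracks(frame=frame, totals=totals)
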