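"""Detection of de novo induced and shut-down transcription (DAGE).

A gene is *de novo induced* when it has zero mean reads in the mock
condition but positive reads after induction, and *shut-down* in the
converse case.  Count-based DE tools still emit a log2 fold change for such
genes; the ``log2var`` discriminator, ln(fold change)/ln 2, gives a fast
numeric flag for them, but the authoritative rule here is the zero-read
pattern itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetypes import ClassificationRules, DEFAULT_RULES, classify_frame


def log2var(fold_change):
    """ln(fold change) / ln 2 — the log2 of a positive fold change.

    Satisfies exact reciprocal antisymmetry: log2var(1/x) = -log2var(x).
    Accepts a scalar or array; non-positive input is a domain error.
    """
    x = np.asarray(fold_change, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("fold change must be positive and finite")
    out = np.log(x) / math.log(2.0)
    return float(out) if np.isscalar(fold_change) or out.ndim == 0 else out


@dataclass
class DageSets:
    """De novo and shut-down gene sets detected from one DE table."""

    de_novo: pd.DataFrame
    shutdown: pd.DataFrame
    de_novo_reads: float  # induced-condition read mass of the de novo set
    shutdown_reads: float  # mock-condition read mass of the shut-down set

    @property
    def de_novo_ids(self) -> set[str]:
        return set(self.de_novo["gene_id"].astype(str))

    @property
    def shutdown_ids(self) -> set[str]:
        return set(self.shutdown["gene_id"].astype(str))


def detect_transitions(table: pd.DataFrame) -> DageSets:
    """Split a DE table into de novo and shut-down sets by zero-read pattern.

    Each member carries the table's log2fc plus a recomputed ``log2var_flag``
    audit column (True when the table log2fc is missing/non-finite, i.e. the
    fast discriminator would have caught it too).  Genes unexpressed in both
    conditions belong to neither set.
    """
    mock = table["mock_reads"].fillna(0.0)
    exp = table["exp_reads"].fillna(0.0)
    de_novo = table.loc[(mock == 0) & (exp > 0)].copy()
    shutdown = table.loc[(exp == 0) & (mock > 0)].copy()
    for sub in (de_novo, shutdown):
        lfc = sub["log2fc"]
        sub["log2var_flag"] = (~np.isfinite(lfc.to_numpy(dtype=float))) | lfc.isna()
    return DageSets(
        de_novo=de_novo,
        shutdown=shutdown,
        de_novo_reads=float(de_novo["exp_reads"].sum()),
        shutdown_reads=float(shutdown["mock_reads"].sum()),
    )


def intersect_significant(
    dage: DageSets,
    sig,
    restrict_to: str | None = "PCG",
    rules: ClassificationRules = DEFAULT_RULES,
) -> list[str]:
    """Overlap a transition set with a highly significant signature.

    Uses the de novo set against an up signature and the shut-down set
    against a down signature; optionally restricted to one gene-type class
    (default protein-coding).  Output is sorted for stability.
    """
    trans = dage.de_novo if sig.direction == "up" else dage.shutdown
    ids = set(trans["gene_id"].astype(str)) & sig.gene_ids
    if restrict_to is not None and ids:
        frame = sig.frame.loc[sig.frame["gene_id"].astype(str).isin(ids)]
        labels = classify_frame(frame, rules)
        ids = set(frame.loc[(labels == restrict_to).to_numpy(), "gene_id"].astype(str))
    return sorted(ids)
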