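"""Cross-signature set algebra and heatmap-matrix construction.

Gene identity throughout is the stable ``gene_id`` (symbols collide).
Venn decomposition supports two or three named sets; the heatmap builder
assembles a genes x cell-lines log2FC matrix over the protein-coding union
of the supplied signatures, with an explicit fill policy for genes missing
from a table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetypes import ClassificationRules, DEFAULT_RULES, classify_frame


@dataclass
class VennCounts:
    """Exclusive-region decomposition of 2-3 named gene sets.

    Region keys join member names with ``&`` in the input order, e.g. for
    sets A, B, C the regions are A, B, C, A&B, A&C, B&C, A&B&C; each gene
    of the union belongs to exactly one region.
    """

    names: list[str]
    regions: dict[str, int]
    members: dict[str, list[str]]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def shared_all(self) -> int:
        return self.regions.get("&".join(self.names), 0)


def venn(sets: Mapping[str, Iterable[str]]) -> VennCounts:
    """Exact exclusive-region decomposition of 2 or 3 named gene sets."""
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn supports exactly 2 or 3 sets")
    as_sets = {n: set(map(str, sets[n])) for n in names}
    regions: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(set(), *(as_sets[n] for n in names if n not in combo))
            excl = inside - outside
            key = "&".join(combo)
            regions[key] = len(excl)
            members[key] = sorted(excl)
    return VennCounts(names=names, regions=regions, members=members)


def idiosyncratic(sig_a: Iterable[str], sig_b: Iterable[str]) -> tuple[set[str], set[str], set[str]]:
    """Split two gene sets into (A-only, B-only, shared); the three parts
    are disjoint and union to A | B."""
    a, b = set(map(str, sig_a)), set(map(str, sig_b))
    return a - b, b - a, a & b


@dataclass
class HeatmapMatrix:
    """Genes x cell-lines log2FC matrix plus its fill bookkeeping."""

    frame: pd.DataFrame          # index gene_id, one column per cell line
    filled: pd.DataFrame         # boolean; True where fill value was used
    fill_value: float
    restrict_to: str | None

    @property
    def n_genes(self) -> int:
        return len(self.frame)


def _member_ids(sig, tables: Mapping[str, pd.DataFrame], restrict_to: str | None,
                rules: ClassificationRules) -> set[str]:
    frame = sig.frame
    if restrict_to is not None and len(frame):
        labels = classify_frame(frame, rules)
        frame = frame.loc[(labels == restrict_to).to_numpy()]
    return set(frame["gene_id"].astype(str))


def heatmap_matrix(
    signatures: Sequence,
    tables: Mapping[str, pd.DataFrame],
    restrict_to: str | None = "PCG",
    fill_value: float = 0.0,
    rules: ClassificationRules = DEFAULT_RULES,
) -> HeatmapMatrix:
    """Build the clustering input matrix from deregulated genes.

    Rows are the union (deduplicated by gene_id) of the given signatures'
    members, restricted by default to protein-coding genes; columns are the
    cell lines in ``tables``; values are each table's log2FC.  A gene absent
    from a table (or lacking a finite log2FC there) takes ``fill_value``
    and is flagged in ``filled``.
    """
    union: set[str] = set()
    for sig in signatures:
        union |= _member_ids(sig, tables, restrict_to, rules)
    genes = sorted(union)
    labels = list(tables)
    values = pd.DataFrame(fill_value, index=genes, columns=labels, dtype=float)
    filled = pd.DataFrame(True, index=genes, columns=labels, dtype=bool)
    for label in labels:
        t = tables[label]
        lfc = pd.to_numeric(t.set_index(t["gene_id"].astype(str))["log2fc"], errors="coerce")
        lfc = lfc[np.isfinite(lfc)]
        lfc = lfc[~lfc.index.duplicated()]
        hit = lfc.reindex(genes)
        have = hit.notna()
        values.loc[have, label] = hit[have]
        filled.loc[have, label] = False
    return HeatmapMatrix(frame=values, filled=filled, fill_value=fill_value, restrict_to=restrict_to)
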