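"""Gene-type classification and per-signature decomposition (DAGT).

Every gene entry is assigned exactly one of seven classes:

==========  =================================================
``PCG``     protein-coding gene
``PG``      pseudogene (processed, unprocessed, unitary, ...)
``NA``      non-annotated (accession-style or missing symbol)
``LINC``    long intergenic non-coding RNA
``MIR``     microRNA
``SNO``     small nucleolar RNA
``MT``      mitochondrially encoded gene
==========  =================================================

The classification is an explicit ordered rule table: an annotated biotype
always wins; symbol heuristics (prefix/suffix patterns) are the fallback.
The composite ``PG/NA`` class used by the chromatin cross-tabulation is the
union of ``PG`` and ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

PCG, PG, NA, LINC, MIR, SNO, MT = "PCG", "PG", "NA", "LINC", "MIR", "SNO", "MT"
GENE_TYPES = (PCG, PG, NA, LINC, MIR, SNO, MT)

# biotype keyword -> label; substring match, checked in order (pseudogene
# variants such as processed_pseudogene / unitary_pseudogene all map to PG)
DEFAULT_BIOTYPE_RULES: list[tuple[str, str]] = [
    ("pseudogene", PG),
    ("lincrna", LINC),
    ("lncrna", LINC),
    ("mirna", MIR),
    ("snorna", SNO),
    ("mt_", MT),
    ("protein_coding", PCG),
]

# symbol regex -> label; first match wins
DEFAULT_SYMBOL_RULES: list[tuple[str, str]] = [
    (r"^MT-", MT),
    (r"^MIR\d", MIR),
    (r"^LINC\d", LINC),
    (r"^SNOR[DA]?\d", SNO),
    (r"^LOC\d+$", NA),
    (r"^(AC|AL|AP|AD|BX|CR|CT|CU|FP)\d{6}(\.\d+)?$", NA),
    (r"^RP\d+-", NA),
    (r"^CT[ABD]-", NA),
    (r"^ENSG\d+$", NA),
    (r"^[A-Z][A-Z0-9]{1,9}P\d+$", PG),
]


@dataclass
class ClassificationRules:
    """Ordered, overridable rule table driving :func:`classify_gene_type`."""

    biotype_rules: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_BIOTYPE_RULES))
    symbol_rules: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_SYMBOL_RULES))

    def __post_init__(self) -> None:
        self._compiled = [(re.compile(pat), label) for pat, label in self.symbol_rules]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationRules":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            biotype_rules=[tuple(r) for r in data.get("biotype_rules", DEFAULT_BIOTYPE_RULES)],
            symbol_rules=[tuple(r) for r in data.get("symbol_rules", DEFAULT_SYMBOL_RULES)],
        )


DEFAULT_RULES = ClassificationRules()


def classify_gene_type(
    symbol: str | None,
    biotype: str | None = None,
    chromosome: str | None = None,
    rules: ClassificationRules = DEFAULT_RULES,
) -> str:
    """Classify one gene entry; an explicit biotype always dominates the
    symbol heuristics.  A record with neither symbol nor biotype is NA."""
    if biotype is not None and not pd.isna(biotype) and str(biotype).strip():
        b = str(biotype).strip().lower()
        for key, label in rules.biotype_rules:
            if key in b:
                return label
    if chromosome is not None and str(chromosome) == "MT":
        return MT
    if symbol is None or pd.isna(symbol) or not str(symbol).strip():
        return NA
    s = str(symbol).strip()
    for pat, label in rules._compiled:
        if pat.match(s):
            return label
    return PCG


def classify_frame(df: pd.DataFrame, rules: ClassificationRules = DEFAULT_RULES) -> pd.Series:
    """Vector of labels for a canonical DE frame (one per row)."""
    return pd.Series(
        [
            classify_gene_type(sym, bio, chrom, rules)
            for sym, bio, chrom in zip(df["symbol"], df["biotype"], df["chromosome"])
        ],
        index=df.index,
        name="gene_type",
    )


@dataclass
class GeneTypeBreakdown:
    """Per-class gene and read counts of one signature."""

    counts: dict[str, int]
    reads: dict[str, float]

    @property
    def n_genes(self) -> int:
        return sum(self.counts.values())

    @property
    def pg_na_count(self) -> int:
        """Composite pseudogene + non-annotated count (PG/NA)."""
        return self.counts.get(PG, 0) + self.counts.get(NA, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_type": list(GENE_TYPES),
             "n_genes": [self.counts.get(t, 0) for t in GENE_TYPES],
             "reads": [self.reads.get(t, 0.0) for t in GENE_TYPES]}
        )


def breakdown(sig, rules: ClassificationRules = DEFAULT_RULES) -> GeneTypeBreakdown:
    """Decompose a signature by gene type.

    ``sig`` is a :class:`fusionsig.signatures.Signature`; reads are summed
    from the signature's direction-relevant condition (induced for up,
    mock for down).
    """
    frame = sig.frame
    reads_col = "exp_reads" if sig.direction == "up" else "mock_reads"
    counts = {t: 0 for t in GENE_TYPES}
    reads = {t: 0.0 for t in GENE_TYPES}
    if len(frame):
        labels = classify_frame(frame, rules)
        for label, r in zip(labels, frame[reads_col].fillna(0.0)):
            counts[label] += 1
            reads[label] += float(r)
    return GeneTypeBreakdown(counts=counts, reads=reads)
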