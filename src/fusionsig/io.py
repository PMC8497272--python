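"""Reading, validation and normalization of DESeq2-style result tables.

The pipeline consumes per-cell-line differential-expression tables produced
upstream (one row per gene: identifier, symbol, chromosome, optional biotype,
mean normalized reads per condition, log2 fold change, p-value).  Internally a
table is a :class:`pandas.DataFrame` with the canonical columns listed in
:data:`CANONICAL_COLUMNS` plus two bookkeeping flags:

``incomplete``
    row had an unparseable/missing mandatory numeric; retained for audit but
    excluded from every downstream filter.
``expressed``
    at least one condition has non-zero mean reads; genes with zero reads in
    both conditions never enter signature filters or backgrounds.

:class:`DERecord` is the row atom; :func:`records` / :func:`from_records`
convert between the dataclass view and the DataFrame view.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: canonical column order of a normalized DE table
CANONICAL_COLUMNS = [
    "gene_id",
    "symbol",
    "chromosome",
    "biotype",
    "mock_reads",
    "exp_reads",
    "log2fc",
    "pvalue",
    "padj",
]

_MANDATORY = ["gene_id", "log2fc", "pvalue"]
_NUMERIC = ["mock_reads", "exp_reads", "log2fc", "pvalue", "padj"]

_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result row."""

    gene_id: str
    symbol: str | None = None
    chromosome: str | None = None
    biotype: str | None = None
    mock_reads: float = 0.0
    exp_reads: float = 0.0
    log2fc: float | None = None
    pvalue: float | None = None
    padj: float | None = None

    @property
    def expressed(self) -> bool:
        return (self.mock_reads or 0) + (self.exp_reads or 0) > 0


@dataclass(frozen=True)
class Thresholds:
    """Signature filter thresholds.

    Defaults encode the strict rule: read floor of 10 (inclusive) on the
    direction-relevant condition, raw p-value below 0.05 and |log2 fold
    change| strictly above 2.  ``reads_inclusive`` exists because the source
    convention is ambiguous between "a minimum of ten reads" (>=) and "more
    than 10 reads" (>); the default is >=.
    """

    min_reads: float = 10.0
    reads_inclusive: bool = True
    p_max: float = 0.05
    log2_min: float = 2.0
    log2_inclusive: bool = False
    use_adjusted_p: bool = False

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")
        if self.log2_min < 0:
            raise ValueError("log2_min must be >= 0")

    def reads_pass(self, reads) -> "np.ndarray":
        reads = np.asarray(reads, dtype=float)
        return reads >= self.min_reads if self.reads_inclusive else reads > self.min_reads

    def log2_pass_up(self, log2fc) -> "np.ndarray":
        x = np.asarray(log2fc, dtype=float)
        with np.errstate(invalid="ignore"):
            return x >= self.log2_min if self.log2_inclusive else x > self.log2_min

    def log2_pass_down(self, log2fc) -> "np.ndarray":
        x = np.asarray(log2fc, dtype=float)
        with np.errstate(invalid="ignore"):
            return x <= -self.log2_min if self.log2_inclusive else x < -self.log2_min


#: strict signature preset (|log2FC| > 2, i.e. FC beyond 4x)
STRICT = Thresholds()
#: looser preset used for per-chromosome track counting (|log2FC| >= 1)
CIRCOS = Thresholds(log2_min=1.0, log2_inclusive=True)

_PRESETS = {"strict": STRICT, "circos": CIRCOS}


def thresholds_preset(name: str) -> Thresholds:
    """Return a named threshold preset (``strict`` or ``circos``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown thresholds preset {name!r}; choose from {sorted(_PRESETS)}")


@dataclass(frozen=True)
class AnnotationEntry:
    gene_id: str
    symbol: str | None = None
    chromosome: str | None = None
    biotype: str | None = None


@dataclass
class LoadReport:
    """Accounting of one table load: every input row is either retained
    complete, retained incomplete, or (never) dropped silently."""

    path: str
    n_rows: int = 0
    n_complete: int = 0
    n_incomplete: int = 0
    n_unexpressed: int = 0
    missing_optional: list[str] = dataclasses.field(default_factory=list)

    @property
    def balanced(self) -> bool:
        """Retained complete + incomplete rows account for every input row."""
        return self.n_complete + self.n_incomplete == self.n_rows


def normalize_chromosome(label: object) -> str:
    """Map a raw chromosome label to its canonical form.

    ``chr1``/``1`` -> ``1``; ``chrX`` -> ``X``; ``chrM``/``MT`` -> ``MT``;
    anything else (scaffolds, patches, haplotypes, missing) -> ``other``.
    Total and idempotent.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return "other"
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s in ("M", "MT"):
        return "MT"
    if s in _AUTOSOMES or s in ("X", "Y"):
        return s
    return "other"


def _resolve_reads(df: pd.DataFrame, spec: str | Sequence[str] | None) -> pd.Series | None:
    """A reads column spec may name one condition-mean column or a list of
    per-replicate columns, averaged on load."""
    if spec is None:
        return None
    if isinstance(spec, str):
        spec = [spec]
    for col in spec:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from table")
    vals = df[list(spec)].apply(pd.to_numeric, errors="coerce")
    return vals.mean(axis=1)


def read_de_table(
    path: str | Path,
    column_map: Mapping[str, object] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a delimited DE result table into canonical form.

    Parameters
    ----------
    path:
        TSV/CSV file (``.gz`` handled transparently).
    column_map:
        Mapping from canonical names (:data:`CANONICAL_COLUMNS`) to source
        column names.  ``mock_reads``/``exp_reads`` may map to a list of
        per-replicate columns which are averaged.  Unmapped canonical names
        are looked up verbatim.
    sep:
        Field separator; sniffed from the extension when ``None``
        (``.csv`` -> comma, else tab).

    Returns
    -------
    (frame, report):
        canonical DataFrame plus a :class:`LoadReport`.  Rows whose mandatory
        numerics fail to parse are flagged ``incomplete`` and counted; rows
        with zero reads in both conditions are flagged unexpressed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        sep = "," if name.endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty:
        raise ValueError(f"empty table: {path}")

    cmap = dict(column_map or {})
    out = pd.DataFrame(index=raw.index)

    for canon in ("gene_id", "symbol", "chromosome", "biotype"):
        src = cmap.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src].astype("string")
        elif canon == "gene_id":
            raise ValueError("mandatory column 'gene_id' missing from table")
        else:
            out[canon] = pd.Series(pd.NA, index=raw.index, dtype="string")

    report = LoadReport(path=str(path), n_rows=len(raw))
    for canon in ("mock_reads", "exp_reads"):
        series = _resolve_reads(raw, cmap.get(canon, canon if canon in raw.columns else None))
        if series is None:
            report.missing_optional.append(canon)
            out[canon] = 0.0
        else:
            out[canon] = series
    if "mock_reads" in report.missing_optional and "exp_reads" in report.missing_optional:
        raise ValueError("mandatory column: at least one reads column (mock_reads/exp_reads) required")

    for canon in ("log2fc", "pvalue", "padj"):
        src = cmap.get(canon, canon)
        if src in raw.columns:
            out[canon] = pd.to_numeric(raw[src], errors="coerce")
        elif canon in _MANDATORY:
            raise ValueError(f"mandatory column {canon!r} missing from table")
        else:
            out[canon] = np.nan

    out["chromosome"] = out["chromosome"].map(normalize_chromosome)
    out["mock_reads"] = pd.to_numeric(out["mock_reads"], errors="coerce")
    out["exp_reads"] = pd.to_numeric(out["exp_reads"], errors="coerce")
    return finalize_table(out, report)


def finalize_table(out: pd.DataFrame, report: LoadReport | None = None) -> tuple[pd.DataFrame, LoadReport]:
    """Attach the ``incomplete``/``expressed`` flags and finish the report."""
    if report is None:
        report = LoadReport(path="<memory>", n_rows=len(out))
    incomplete = (
        out["log2fc"].isna()
        | out["pvalue"].isna()
        | out["mock_reads"].isna()
        | out["exp_reads"].isna()
        | ~out["pvalue"].between(0, 1)
    )
    reads = out[["mock_reads", "exp_reads"]].fillna(0.0)
    out = out.copy()
    out["incomplete"] = incomplete.to_numpy(dtype=bool)
    out["expressed"] = (reads.sum(axis=1) > 0).to_numpy(dtype=bool)
    report.n_rows = len(out)
    report.n_incomplete = int(incomplete.sum())
    report.n_complete = report.n_rows - report.n_incomplete
    report.n_unexpressed = int((~out["expressed"]).sum())
    return out, report


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    """Emit a canonical TSV (gzip by extension)."""
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def records(df: pd.DataFrame) -> Iterator[DERecord]:
    """Iterate a canonical frame as :class:`DERecord` atoms."""
    for row in df.itertuples(index=False):
        yield DERecord(
            gene_id=str(row.gene_id),
            symbol=None if pd.isna(row.symbol) else str(row.symbol),
            chromosome=None if pd.isna(row.chromosome) else str(row.chromosome),
            biotype=None if pd.isna(row.biotype) else str(row.biotype),
            mock_reads=float(row.mock_reads) if not pd.isna(row.mock_reads) else 0.0,
            exp_reads=float(row.exp_reads) if not pd.isna(row.exp_reads) else 0.0,
            log2fc=None if pd.isna(row.log2fc) else float(row.log2fc),
            pvalue=None if pd.isna(row.pvalue) else float(row.pvalue),
            padj=None if pd.isna(row.padj) else float(row.padj),
        )


def from_records(recs: Iterable[DERecord]) -> pd.DataFrame:
    """Build a canonical frame from record atoms (with flags attached)."""
    rows = [dataclasses.asdict(r) for r in recs]
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    for c in ("symbol", "chromosome", "biotype"):
        df[c] = df[c].astype("string")
    for c in _NUMERIC:
        df[c] = pd.to_numeric(df[c])
    df, _ = finalize_table(df)
    return df


def load_column_map(path: str | Path) -> dict:
    """Load a YAML/JSON column-name mapping config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("column map config must be a mapping")
    return data
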