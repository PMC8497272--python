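"""Chromosome-usage fingerprints of gene signatures (GUDC).

Each expressed gene in a DE table derives from one chromosome; a signature
is a subset of those genes.  The fingerprint compares, chromosome by
chromosome, the signature's percentage composition with a reference
composition, and reports the difference in percentage points:

    delta(c) = signature_pct(c) - reference_pct(c)

The default reference is the expressed background's own chromosome
distribution, so a positive delta means the signature over-uses genes from
that chromosome relative to what is expressed at all.  A uniform reference
(every chromosome weighted equally) is available as an alternative
interpretation of "deviation from the mean".  Deltas always sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CANONICAL_CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
#: chromosomes reported but typically carried by very few genes
LOW_COUNT_FLAGGED = ("Y", "MT", "other")


def _expressed_with_chrom(background: pd.DataFrame) -> pd.DataFrame:
    bg = background
    if "expressed" in bg.columns:
        bg = bg.loc[bg["expressed"].astype(bool)]
    else:
        bg = bg.loc[(bg["mock_reads"].fillna(0) + bg["exp_reads"].fillna(0)) > 0]
    return bg


@dataclass
class ChromosomeFingerprint:
    """Per-chromosome composition of a signature vs its reference."""

    frame: pd.DataFrame  # chromosome, background_pct, signature_pct, delta
    n_signature: int
    n_background: int
    n_excluded: int  # genes lacking a placeable chromosome
    reference: str = "background"

    def delta(self, chrom: str) -> float:
        row = self.frame.loc[self.frame["chromosome"] == str(chrom), "delta"]
        return float(row.iloc[0]) if len(row) else 0.0

    def max_abs_delta(self) -> tuple[str, float]:
        i = self.frame["delta"].abs().idxmax()
        return str(self.frame.loc[i, "chromosome"]), float(self.frame.loc[i, "delta"])


def _composition(chroms: pd.Series, order: list[str]) -> np.ndarray:
    counts = chroms.value_counts()
    vec = np.array([counts.get(c, 0) for c in order], dtype=float)
    total = vec.sum()
    return 100.0 * vec / total if total > 0 else np.zeros(len(order))


def fingerprint(
    sig,
    background: pd.DataFrame,
    reference: str = "background",
    include_other: bool = False,
) -> ChromosomeFingerprint:
    """Compute the per-chromosome fingerprint of a signature.

    Parameters
    ----------
    sig:
        a :class:`~fusionsig.signatures.Signature` or a canonical frame of
        member records (must be a subset of the background's genes).
    background:
        the full DE table; restricted internally to expressed genes.
    reference:
        ``"background"`` (default) compares against the expressed genes'
        own chromosome distribution; ``"uniform"`` against an equal share
        per chromosome.
    include_other:
        whether the ``other`` pseudo-chromosome participates; by default
        unplaced genes are excluded (and counted in ``n_excluded``).
    """
    sig_frame = sig.frame if hasattr(sig, "frame") else sig
    bg = _expressed_with_chrom(background)
    if bg.empty:
        raise ValueError("background contains no expressed genes")

    order = CANONICAL_CHROMOSOMES + (["other"] if include_other else [])
    bg_chroms = bg["chromosome"].astype(str)
    sig_chroms = sig_frame["chromosome"].astype(str)
    n_excluded = int((~sig_chroms.isin(order)).sum() + (~bg_chroms.isin(order)).sum())
    bg_chroms = bg_chroms[bg_chroms.isin(order)]
    sig_chroms = sig_chroms[sig_chroms.isin(order)]

    bg_pct = _composition(bg_chroms, order)
    if reference == "background":
        ref_pct = bg_pct
    elif reference == "uniform":
        ref_pct = np.full(len(order), 100.0 / len(order))
    else:
        raise ValueError(f"unknown reference {reference!r}")

    if len(sig_chroms) == 0:
        sig_pct = ref_pct.copy()  # empty signature: all deltas 0 by convention
    else:
        sig_pct = _composition(sig_chroms, order)

    frame = pd.DataFrame(
        {"chromosome": order, "background_pct": bg_pct,
         "signature_pct": sig_pct, "delta": sig_pct - ref_pct}
    )
    return ChromosomeFingerprint(
        frame=frame,
        n_signature=len(sig_chroms),
        n_background=len(bg_chroms),
        n_excluded=n_excluded,
        reference=reference,
    )


def fingerprint_null(
    sig_size: int,
    background: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int | None = None,
    quantile: float = 0.999,
    reference: str = "background",
) -> pd.DataFrame:
    """Resampling envelope for fingerprint deltas under the null.

    Draws ``n_resamples`` uniform signatures of ``sig_size`` genes (without
    replacement) from the expressed background and returns, per chromosome,
    the empirical ``(1-quantile, quantile)`` band of delta plus the envelope
    of max |delta| across chromosomes (row ``__max_abs__``).
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    bg = _expressed_with_chrom(background)
    order = CANONICAL_CHROMOSOMES
    bg_chroms = bg["chromosome"].astype(str)
    bg_chroms = bg_chroms[bg_chroms.isin(order)].to_numpy()
    if sig_size > len(bg_chroms):
        raise ValueError("sig_size exceeds background size")

    rng = np.random.default_rng(seed)
    bg_pct = _composition(pd.Series(bg_chroms), order)
    ref = bg_pct if reference == "background" else np.full(len(order), 100.0 / len(order))

    chrom_index = {c: i for i, c in enumerate(order)}
    codes = np.array([chrom_index[c] for c in bg_chroms])
    deltas = np.empty((n_resamples, len(order)))
    for b in range(n_resamples):
        take = rng.choice(codes, size=sig_size, replace=False)
        counts = np.bincount(take, minlength=len(order))
        deltas[b] = 100.0 * counts / sig_size - ref

    lo = np.quantile(deltas, 1 - quantile, axis=0)
    hi = np.quantile(deltas, quantile, axis=0)
    out = pd.DataFrame({"chromosome": order, "lo": lo, "hi": hi})
    max_abs = np.abs(deltas).max(axis=1)
    out.loc[len(out)] = ["__max_abs__", 0.0, float(np.quantile(max_abs, quantile))]
    return out
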