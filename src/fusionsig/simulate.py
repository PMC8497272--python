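"""Synthetic MACE-style count data with planted ground truth.

The generator emulates the statistical shape of a 3'-end tag-counting
experiment analyzed gene-wise: negative-binomial counts for three mock vs
three induced replicates, a log-normal spread of baseline expression, a
configurable fraction of planted up/down-regulated genes at fixed fold
changes, structural-zero "de novo" genes (no mock expression at all) and
"shut-down" genes (no induced expression), gene annotations with a
realistic chromosome and biotype composition, and a linked
chromatin-accessibility table in which planted up-regulated genes become
accessible with probability ``accessibility_link``.

``simple_de`` is a deliberately minimal differential-expression routine for
closing the loop in tests: geometric-mean (median-of-ratios) size factors,
condition-mean fold changes and a Welch test on log-scale normalized
counts.  It is not a shrinkage-based DE tool and makes no claim to be one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import finalize_table
from .genetypes import PCG, PG, NA, LINC, MIR, SNO, MT

# approximate share of annotated human genes per chromosome
DEFAULT_CHROM_WEIGHTS: dict[str, float] = {
    "1": 0.099, "2": 0.064, "3": 0.054, "4": 0.040, "5": 0.045, "6": 0.052,
    "7": 0.048, "8": 0.035, "9": 0.039, "10": 0.037, "11": 0.063, "12": 0.052,
    "13": 0.017, "14": 0.038, "15": 0.031, "16": 0.042, "17": 0.055, "18": 0.014,
    "19": 0.065, "20": 0.027, "21": 0.012, "22": 0.024, "X": 0.041, "Y": 0.004,
    "MT": 0.002,
}

# biotype composition loosely following a whole-annotation gene census
DEFAULT_BIOTYPE_MIX: dict[str, float] = {
    PCG: 0.60, PG: 0.16, NA: 0.10, LINC: 0.09, MIR: 0.025, SNO: 0.02, MT: 0.005,
}

STATUSES = ("null", "up", "down", "denovo", "shutdown")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cell line vs mock.

    ``fc_up`` is the induced/mock mean ratio of planted up genes (> 1);
    ``fc_down`` likewise for planted down genes (< 1).  ``denovo_mean`` is
    the expressed-condition mean for structural-zero transition genes.
    ``dispersion`` is the NB overdispersion alpha in var = mu + alpha*mu^2.
    """

    n_genes: int = 10_000
    n_reps: int = 3
    baseline_mean: float = 200.0
    baseline_sigma: float = 0.6  # log-normal spread of per-gene baselines
    dispersion: float = 0.1
    n_up: int = 100
    n_down: int = 50
    fc_up: float = 8.0
    fc_down: float = 0.125
    n_denovo: int = 40
    n_shutdown: int = 20
    denovo_mean: float = 50.0
    biotype_mix: dict = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_MIX))
    chrom_weights: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_WEIGHTS))
    accessibility_link: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_up + self.n_down + self.n_denovo + self.n_shutdown
        if planted > self.n_genes:
            raise ValueError(f"planted counts ({planted}) exceed n_genes ({self.n_genes})")
        if not 0 <= self.accessibility_link <= 1:
            raise ValueError("accessibility_link must be in [0, 1]")
        for name, mix in (("biotype_mix", self.biotype_mix), ("chrom_weights", self.chrom_weights)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} proportions sum to {total}, expected 1")
        if self.n_reps < 1 or self.n_genes < 1:
            raise ValueError("n_genes and n_reps must be positive")

    def token(self) -> str:
        """Stable fingerprint tying derived tables back to this config."""
        payload = repr(sorted(asdict(self).items(), key=lambda kv: kv[0]))
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent child streams per sub-table so each is reproducible alone
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


_SAFE_LETTERS = "BDEFGHJKQUVWXYZ"  # avoids forming reserved symbol prefixes


def _make_symbols(statuses_biotypes, rng: np.random.Generator) -> list[str]:
    symbols = []
    for i, biotype in enumerate(statuses_biotypes):
        if biotype == PCG:
            stem = "".join(rng.choice(list(_SAFE_LETTERS), size=3))
            symbols.append(f"{stem}{i % 97 + 1}")
        elif biotype == PG:
            stem = "".join(rng.choice(list(_SAFE_LETTERS), size=3))
            symbols.append(f"{stem}{i % 11 + 1}P{i % 7 + 1}")
        elif biotype == NA:
            symbols.append(f"LOC{100000 + i}" if i % 2 else f"AC{100000 + i:06d}.1")
        elif biotype == LINC:
            symbols.append(f"LINC{i % 99999:05d}")
        elif biotype == MIR:
            symbols.append(f"MIR{i + 1}")
        elif biotype == SNO:
            symbols.append(f"SNORD{i + 1}")
        else:  # MT
            symbols.append(f"MT-G{i + 1}")
    return symbols


def _annotate(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, 1)
    n = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(n)]

    bl, bp = zip(*sorted(config.biotype_mix.items()))
    biotypes = rng.choice(bl, size=n, p=np.asarray(bp) / np.sum(bp))
    cl, cp = zip(*sorted(config.chrom_weights.items(), key=lambda kv: kv[0]))
    chroms = rng.choice(cl, size=n, p=np.asarray(cp) / np.sum(cp))
    chroms = np.where(biotypes == MT, "MT", chroms)  # mito genes live on MT

    order = rng.permutation(n)
    status = np.full(n, "null", dtype=object)
    cursor = 0
    for label, count in (("up", config.n_up), ("down", config.n_down),
                         ("denovo", config.n_denovo), ("shutdown", config.n_shutdown)):
        status[order[cursor:cursor + count]] = label
        cursor += count

    true_fc = np.ones(n)
    true_fc[status == "up"] = config.fc_up
    true_fc[status == "down"] = config.fc_down
    true_fc[status == "denovo"] = np.inf
    true_fc[status == "shutdown"] = 0.0

    return pd.DataFrame(
        {"gene_id": gene_ids,
         "status": status,
         "true_fc": true_fc,
         "symbol": _make_symbols(biotypes, rng),
         "chromosome": chroms,
         "biotype": biotypes,
         "accessibility_status": "none"}
    )


_BIOTYPE_NAMES = {  # annotation-style biotype strings carried in DE tables
    PCG: "protein_coding", PG: "processed_pseudogene", NA: "",
    LINC: "lincRNA", MIR: "miRNA", SNO: "snoRNA", MT: "Mt_rRNA",
}


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the count matrix (genes x 2*n_reps) and its truth table.

    De novo genes are structural zeros in every mock replicate (their
    induced mean is ``denovo_mean``); shut-down genes are the converse.
    Identical config + seed gives bit-identical output.
    """
    config.validate()
    truth = _annotate(config)
    rng = _rng(config, 2)
    n, r = config.n_genes, config.n_reps

    mu = np.log(config.baseline_mean) - config.baseline_sigma**2 / 2
    baseline = rng.lognormal(mean=mu, sigma=config.baseline_sigma, size=n)

    status = truth["status"].to_numpy()
    mock_mu = baseline.copy()
    exp_mu = baseline.copy()
    exp_mu[status == "up"] = baseline[status == "up"] * config.fc_up
    exp_mu[status == "down"] = baseline[status == "down"] * config.fc_down
    mock_mu[status == "denovo"] = 0.0
    exp_mu[status == "denovo"] = config.denovo_mean
    mock_mu[status == "shutdown"] = config.denovo_mean
    exp_mu[status == "shutdown"] = 0.0

    def draw(mu_vec: np.ndarray) -> np.ndarray:
        mu_mat = np.repeat(mu_vec[:, None], r, axis=1)
        if config.dispersion <= 0:
            return rng.poisson(mu_mat)
        shape = 1.0 / config.dispersion
        lam = np.where(mu_mat > 0, rng.gamma(shape, 1.0, size=mu_mat.shape) * mu_mat / shape, 0.0)
        return rng.poisson(lam)

    mock = draw(mock_mu)
    exp = draw(exp_mu)
    mock[status == "denovo"] = 0      # structural, not sampled
    exp[status == "shutdown"] = 0

    counts = pd.DataFrame(
        np.hstack([mock, exp]),
        index=pd.Index(truth["gene_id"], name="gene_id"),
        columns=[f"mock_{j+1}" for j in range(r)] + [f"exp_{j+1}" for j in range(r)],
    )
    truth.attrs["sim_token"] = config.token()
    counts.attrs["sim_token"] = config.token()
    return counts, truth


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios (geometric-mean reference) normalization factors.

    Each sample's factor is the median over genes of its count divided by
    that gene's geometric mean across samples; genes with any zero count
    drop out of the reference, as in count-based DE tools.
    """
    mat = np.asarray(counts, dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample; cannot normalize")
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return sf


def simple_de(
    counts: pd.DataFrame,
    design: list[str] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Minimal condition-vs-condition DE over a count matrix.

    Size factors by the geometric-mean method; log2FC of condition means of
    normalized counts; Welch's t-test on log2(normalized + 1).  With the
    default pseudocount of 0, a gene expressed in exactly one condition
    gets a finite fold change from a 0.5 pseudocount on both means (the
    zero-read pattern itself is what marks it de novo / shut-down); a gene
    with zero reads everywhere gets no fold change at all.
    """
    if design is None:
        design = ["mock" if c.startswith("mock") else "exp" for c in counts.columns]
    design = np.asarray(design)
    if (design == "mock").sum() < 2 or (design == "exp").sum() < 2:
        raise ValueError("need at least two replicates per condition")
    mat = counts.to_numpy(dtype=float)
    if not mat.any():
        raise ValueError("all-zero count matrix")

    sf = size_factors(mat)
    norm = mat / sf
    mock = norm[:, design == "mock"]
    exp = norm[:, design == "exp"]
    mock_mean = mock.mean(axis=1)
    exp_mean = exp.mean(axis=1)

    c = pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        if c > 0:
            log2fc = np.log2((exp_mean + c) / (mock_mean + c))
        else:
            log2fc = np.log2(exp_mean / mock_mean)
            one_sided = (mock_mean == 0) ^ (exp_mean == 0)
            log2fc[one_sided] = np.log2((exp_mean[one_sided] + 0.5) / (mock_mean[one_sided] + 0.5))
            log2fc[(mock_mean == 0) & (exp_mean == 0)] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(np.log2(exp + 1), np.log2(mock + 1), axis=1, equal_var=False)
    p = np.asarray(p)
    zero_var = (np.var(exp, axis=1) == 0) & (np.var(mock, axis=1) == 0)
    p[zero_var & (exp_mean == mock_mean)] = 1.0
    p[np.isnan(p)] = 1.0

    from statsmodels.stats.multitest import multipletests

    padj = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {"gene_id": counts.index.astype(str),
         "mock_reads": mock_mean, "exp_reads": exp_mean,
         "log2fc": log2fc, "pvalue": p, "padj": padj}
    )
    out.attrs["size_factors"] = sf.tolist()
    return out


def attach_annotation(de: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join symbol/chromosome/biotype from the truth table onto a DE frame
    and attach the canonical flags."""
    ann = truth.set_index("gene_id")[["symbol", "chromosome", "biotype"]]
    merged = de.set_index("gene_id").join(ann).reset_index()
    merged["biotype"] = merged["biotype"].map(lambda b: _BIOTYPE_NAMES.get(b, b))
    merged["biotype"] = merged["biotype"].replace("", pd.NA)
    for col in ("symbol", "chromosome", "biotype"):
        merged[col] = merged[col].astype("string")
    frame, _ = finalize_table(merged)
    frame.attrs["sim_token"] = truth.attrs.get("sim_token")
    return frame


def simulate_de_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end synthetic DE table: counts -> simple_de -> annotation."""
    counts, truth = simulate_counts(config)
    de = simple_de(counts)
    return attach_annotation(de, truth), truth


def planted_recovery(table: pd.DataFrame, truth: pd.DataFrame, thresholds=None) -> dict:
    """Sensitivity/precision of signature filters and transition detection
    against the planted truth.

    Up/down precision is judged on regulation calls proper: genes planted as
    structural transitions (de novo / shut-down) legitimately enter the
    signatures too, so they are removed from the predicted sets before
    scoring and scored separately via the zero-pattern detector.
    """
    from .io import STRICT
    from .signatures import filter_down, filter_up
    from .transitions import detect_transitions

    thr = thresholds or STRICT
    by_status = {s: set(truth.loc[truth["status"] == s, "gene_id"].astype(str))
                 for s in STATUSES}
    transition_ids = by_status["denovo"] | by_status["shutdown"]
    dage = detect_transitions(table)

    def score(predicted: set, expected: set) -> tuple[float, float]:
        tp = len(predicted & expected)
        sens = tp / len(expected) if expected else 1.0
        prec = tp / len(predicted) if predicted else 1.0
        return sens, prec

    out: dict = {}
    for direction, fn in (("up", filter_up), ("down", filter_down)):
        pred = fn(table, thr).gene_ids - transition_ids
        out[f"{direction}_sensitivity"], out[f"{direction}_precision"] = score(
            pred, by_status[direction])
    out["denovo_sensitivity"], out["denovo_precision"] = score(
        dage.de_novo_ids, by_status["denovo"])
    out["shutdown_sensitivity"], out["shutdown_precision"] = score(
        dage.shutdown_ids, by_status["shutdown"])
    return out


def simulate_atac(config: SimConfig, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accessibility table linked to the planted expression truth.

    Planted up-regulated genes become accessible (clearly positive log2,
    small p, ample reads) with probability ``accessibility_link``; every
    other gene draws from a null (log2 centred on 0, uniform p).  Returns
    the table plus the truth with ``accessibility_status`` filled in.
    """
    if truth.attrs.get("sim_token") != config.token():
        raise ValueError("truth table does not derive from this SimConfig")
    rng = _rng(config, 3)
    n = len(truth)
    status = truth["status"].to_numpy()

    log2 = rng.normal(0.0, 0.4, size=n)
    pvals = rng.uniform(0.0, 1.0, size=n)
    exp_reads = rng.lognormal(np.log(10.0), 0.8, size=n)
    mock_reads = rng.lognormal(np.log(10.0), 0.8, size=n)

    linked = (status == "up") & (rng.uniform(size=n) < config.accessibility_link)
    n_link = int(linked.sum())
    log2[linked] = rng.uniform(1.1, 3.0, size=n_link)
    pvals[linked] = rng.uniform(1e-8, 0.01, size=n_link)
    exp_reads[linked] = rng.uniform(5.0, 100.0, size=n_link)

    atac = pd.DataFrame(
        {"gene_id": truth["gene_id"].astype(str),
         "symbol": truth["symbol"].astype("string"),
         "chromosome": truth["chromosome"].astype("string"),
         "biotype": pd.Series([_BIOTYPE_NAMES.get(b, b) or pd.NA for b in truth["biotype"]],
                              dtype="string"),
         "mock_reads": mock_reads, "exp_reads": exp_reads,
         "log2fc": log2, "pvalue": pvals, "padj": np.nan}
    )
    atac, _ = finalize_table(atac)
    atac.attrs["sim_token"] = config.token()

    truth_out = truth.copy()
    truth_out["accessibility_status"] = np.where(linked, "accessible", "none")
    truth_out.attrs["sim_token"] = truth.attrs.get("sim_token")
    return atac, truth_out
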