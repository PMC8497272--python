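"""End-to-end orchestration: one config -> a reproducible report bundle.

A run covers a batch of cell lines (each contrasted against one mock),
either loaded from DESeq2-style tables on disk or simulated with planted
truth.  For each line it computes strict and loose signatures, summaries,
gene-type breakdowns, chromosome fingerprints, transition sets and — when
an accessibility table exists — the MACE x ATAC cross-tab and per-chromosome
track counts; configured pairs of lines additionally get Venn/idiosyncratic
overlaps and a heatmap matrix.  Every number in the metrics JSON is
regenerable from the TSV artifacts written next to it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import Thresholds, read_de_table, thresholds_preset, write_de_table
from .signatures import Signature, combined_total_reads, filter_down, filter_up, summarize
from .genetypes import DEFAULT_RULES, breakdown
from .chromusage import fingerprint
from .transitions import detect_transitions, intersect_significant
from .compare import heatmap_matrix, idiosyncratic, venn
from .atac import atac_signature, circos_track_data, crosstab_mace_atac
from .simulate import SimConfig, simulate_atac, simulate_de_table


@dataclass
class RunConfig:
    """Declarative description of one batch run."""

    outdir: str
    seed: int = 0
    thresholds: str | Thresholds = "strict"
    circos_thresholds: str | Thresholds = "circos"
    simulate: dict | None = None     # {label: SimConfig overrides}
    inputs: dict | None = None       # {label: {mace: path, atac: path, column_map: {...}}}
    sim_shared: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)   # [[labelA, labelB], ...]
    heatmap_sets: list = field(default_factory=list)  # [[labelA, labelB, ...], ...]
    restrict_to: str = "PCG"
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' and 'inputs' must be given")
        if isinstance(self.thresholds, str):
            self.thresholds = thresholds_preset(self.thresholds)
        if isinstance(self.circos_thresholds, str):
            self.circos_thresholds = thresholds_preset(self.circos_thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()


@dataclass
class ReportBundle:
    outdir: Path
    metrics: dict
    manifest: dict
    tables: dict = field(default_factory=dict)       # label -> DE frame
    atac_tables: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)   # label -> {"up": Signature, "down": ...}
    truths: dict = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Thresholds):
        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _line_seed(seed: int, label: str) -> int:
    digest = hashlib.md5(f"{seed}:{label}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _load_inputs(config: RunConfig) -> tuple[dict, dict, dict]:
    tables, atacs, truths = {}, {}, {}
    if config.inputs is not None:
        # fail before any output if an input is unreadable
        for label, entry in config.inputs.items():
            for key in ("mace", "atac"):
                p = entry.get(key)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{label}: {key} table not found: {p}")
        for label, entry in config.inputs.items():
            cmap = entry.get("column_map")
            tables[label], _ = read_de_table(entry["mace"], column_map=cmap)
            if entry.get("atac"):
                atacs[label], _ = read_de_table(entry["atac"], column_map=entry.get("atac_column_map", cmap))
    else:
        for label, overrides in config.simulate.items():
            params = {**config.sim_shared, **(overrides or {})}
            params.setdefault("seed", _line_seed(config.seed, label))
            sim = SimConfig(**params)
            table, truth = simulate_de_table(sim)
            atac, truth = simulate_atac(sim, truth)
            tables[label], atacs[label], truths[label] = table, atac, truth
    return tables, atacs, truths


def run(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute the configured batch; deterministic under a fixed seed."""
    tables, atacs, truths = _load_inputs(config)
    outdir = Path(config.outdir)
    thr, thr_loose = config.thresholds, config.circos_thresholds

    metrics: dict = {"cell_lines": {}, "comparisons": {}, "heatmaps": {}}
    signatures: dict = {}
    artifacts: list[tuple[pd.DataFrame, Path]] = []

    for label, table in tables.items():
        up = filter_up(table, thr, label)
        down = filter_down(table, thr, label)
        up_loose = filter_up(table, thr_loose, label)
        down_loose = filter_down(table, thr_loose, label)
        signatures[label] = {"up": up, "down": down, "up_loose": up_loose, "down_loose": down_loose}

        sum_up, sum_down = summarize(up), summarize(down)
        fp = fingerprint(Signature(label, "up", pd.concat([up.frame, down.frame])), table)
        dage = detect_transitions(table)
        line: dict = {
            "n_genes_table": int(len(table)),
            "up": {"n_genes": sum_up.n_genes, "total_reads": sum_up.total_reads,
                   "per_biotype": sum_up.per_biotype},
            "down": {"n_genes": sum_down.n_genes, "total_reads": sum_down.total_reads,
                     "per_biotype": sum_down.per_biotype},
            "combined_total_reads": combined_total_reads(up, down),
            "loose_up_n": len(up_loose), "loose_down_n": len(down_loose),
            "fingerprint_max_abs": dict(zip(("chromosome", "delta"), fp.max_abs_delta())),
            "dage": {"n_de_novo": len(dage.de_novo), "n_shutdown": len(dage.shutdown),
                     "de_novo_reads": dage.de_novo_reads, "shutdown_reads": dage.shutdown_reads,
                     "de_novo_in_up_pcg": len(intersect_significant(dage, up, config.restrict_to))},
        }

        if label in atacs:
            atac_sets = atac_signature(atacs[label])
            xtab = crosstab_mace_atac(up_loose, down_loose, atac_sets)
            tracks = circos_track_data(table, atacs[label])
            line["atac"] = {
                "n_accessible": int(len(atac_sets[0])),
                "n_non_accessible": int(len(atac_sets[1])),
                "crosstab": xtab.counts,
                "circos_totals": tracks.totals,
            }
            artifacts.append((xtab.to_frame(), outdir / label / "crosstab.tsv"))
            artifacts.append((tracks.frame, outdir / label / "circos_tracks.tsv"))

        metrics["cell_lines"][label] = line
        artifacts += [
            (up.frame, outdir / label / "signature_up.tsv"),
            (down.frame, outdir / label / "signature_down.tsv"),
            (fp.frame, outdir / label / "fingerprint.tsv"),
            (dage.de_novo, outdir / label / "de_novo.tsv"),
            (dage.shutdown, outdir / label / "shutdown.tsv"),
        ]

    from .compare import _member_ids  # PCG-restricted id sets for overlaps

    for pair in config.comparisons:
        a, b = pair
        key = f"{a}|{b}"
        ida_up = _member_ids(signatures[a]["up"], tables, config.restrict_to, DEFAULT_RULES)
        idb_up = _member_ids(signatures[b]["up"], tables, config.restrict_to, DEFAULT_RULES)
        ida_dn = _member_ids(signatures[a]["down"], tables, config.restrict_to, DEFAULT_RULES)
        idb_dn = _member_ids(signatures[b]["down"], tables, config.restrict_to, DEFAULT_RULES)
        v_up, v_dn = venn({a: ida_up, b: idb_up}), venn({a: ida_dn, b: idb_dn})
        a_only, b_only, shared = idiosyncratic(ida_up, idb_up)
        metrics["comparisons"][key] = {
            "up_regions": v_up.regions, "down_regions": v_dn.regions,
            "idiosyncratic_up": {a: len(a_only), b: len(b_only), "shared": len(shared)},
        }

    for i, labels in enumerate(config.heatmap_sets):
        sigs = [signatures[l][d] for l in labels for d in ("up", "down")]
        hm = heatmap_matrix(sigs, {l: tables[l] for l in labels}, restrict_to=config.restrict_to)
        metrics["heatmaps"][f"set_{i + 1}"] = {"labels": list(labels), "n_genes": hm.n_genes}
        artifacts.append((hm.frame.reset_index(names="gene_id"), outdir / f"heatmap_set_{i + 1}.tsv"))

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "fusionsig_version": __version__,
        "mode": "simulate" if config.simulate is not None else "inputs",
    }

    bundle = ReportBundle(
        outdir=outdir, metrics=_jsonable(metrics), manifest=manifest,
        tables=tables, atac_tables=atacs, signatures=signatures, truths=truths,
    )
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        for frame, path in artifacts:
            path.parent.mkdir(parents=True, exist_ok=True)
            frame.to_csv(path, sep="\t", index=False)
        for label, table in tables.items():
            write_de_table(table, outdir / label / "de_table.tsv")
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(bundle.metrics, fh, sort_keys=True, indent=1)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
        if config.plots:
            from .plots import render_plots

            render_plots(bundle)
    return bundle
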