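"""Plot rendering: volcano, Venn, fingerprint bars, heatmap, circular tracks.

Rendering is strictly downstream of the analysis layer — every number shown
comes from a module result, and a failed render never alters metrics.  The
Venn and circular-track renderers are small matplotlib constructions (two
or three overlapping circles; a polar bar chart of per-chromosome counts).
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .signatures import DOWN_SIG, UP_SIG

log = logging.getLogger(__name__)

_COLORS = {UP_SIG: "#c0392b", DOWN_SIG: "#2471a3", "not-significant": "#b3b3b3"}


def volcano_plot(points: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Scatter of log2FC vs -log10 p, colored by significance category."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, sub in points.groupby("category"):
        ax.scatter(sub["log2fc"], sub["neg_log10_p"], s=6, alpha=0.6,
                   color=_COLORS.get(cat, "#777"), label=f"{cat} ({len(sub)})")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def venn_plot(vc, path: str | Path, title: str = "") -> None:
    """Two- or three-circle Venn with exclusive-region counts."""
    n = len(vc.names)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    centers = {2: [(-0.35, 0), (0.35, 0)], 3: [(-0.35, -0.2), (0.35, -0.2), (0, 0.42)]}[n]
    colors = ["#e74c3c", "#3498db", "#2ecc71"]
    for (x, y), c, name in zip(centers, colors, vc.names):
        ax.add_patch(plt.Circle((x, y), 0.62, alpha=0.3, color=c))
        ax.annotate(name, (x, y + 0.68), ha="center", fontsize=8)
    # region label positions (exclusive regions)
    if n == 2:
        pos = {vc.names[0]: (-0.65, 0), vc.names[1]: (0.65, 0),
               "&".join(vc.names): (0, 0)}
    else:
        a, b, c3 = vc.names
        pos = {a: (-0.75, -0.3), b: (0.75, -0.3), c3: (0, 0.75),
               f"{a}&{b}": (0, -0.35), f"{a}&{c3}": (-0.42, 0.2),
               f"{b}&{c3}": (0.42, 0.2), f"{a}&{b}&{c3}": (0, -0.02)}
    for key, (x, y) in pos.items():
        ax.annotate(str(vc.regions.get(key, 0)), (x, y), ha="center", fontsize=10)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.2, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fingerprint_plot(fp, path: str | Path, title: str = "") -> None:
    """Per-chromosome delta bar chart (the 'chromosome fingerprint')."""
    frame = fp.frame
    fig, ax = plt.subplots(figsize=(7, 3))
    colors = ["#c0392b" if d > 0 else "#2471a3" for d in frame["delta"]]
    ax.bar(frame["chromosome"].astype(str), frame["delta"], color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("delta (percentage points)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap_plot(hm, path: str | Path, title: str = "") -> None:
    """Clustered heatmap of the log2FC matrix (Euclidean, average linkage)."""
    import seaborn as sns

    if hm.n_genes < 2:
        log.warning("heatmap skipped: fewer than 2 genes")
        return
    g = sns.clustermap(hm.frame, method="average", metric="euclidean",
                       cmap="RdBu_r", center=0, figsize=(5, 7),
                       yticklabels=False)
    g.fig.suptitle(title)
    g.savefig(path, dpi=120)
    plt.close(g.fig)


def circos_plot(tracks, path: str | Path, title: str = "") -> None:
    """Polar bar rendering of the four per-chromosome count tracks."""
    frame = tracks.frame[tracks.frame["chromosome"] != "other"]
    n = len(frame)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    width = 2 * np.pi / n * 0.8
    fig, ax = plt.subplots(figsize=(5.5, 5.5), subplot_kw={"projection": "polar"})
    radii = {"expression_up": (3.0, "#2ecc71"), "expression_down": (2.4, "#c0392b"),
             "accessibility_up": (1.8, "#27ae60"), "accessibility_down": (1.2, "#a93226")}
    for track, (base, color) in radii.items():
        vals = frame[track].to_numpy(dtype=float)
        scaled = 0.5 * vals / max(vals.max(), 1)
        ax.bar(theta, scaled, width=width, bottom=base, color=color, alpha=0.8,
               label=f"{track} ({tracks.totals[track]})")
    ax.set_xticks(theta)
    ax.set_xticklabels(frame["chromosome"], fontsize=7)
    ax.set_yticks([])
    ax.legend(loc="lower left", bbox_to_anchor=(0.85, 0.9), fontsize=6)
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_plots(bundle) -> list[Path]:
    """Render the standard plot set for a report bundle; failures are
    logged, never fatal, and metrics are never touched."""
    from .chromusage import fingerprint
    from .signatures import Signature, volcano_points
    from .atac import atac_signature, circos_track_data

    written: list[Path] = []
    for label, table in bundle.tables.items():
        d = bundle.outdir / label
        d.mkdir(parents=True, exist_ok=True)
        jobs = [
            (volcano_plot, (volcano_points(table), d / "volcano.png", label)),
            (fingerprint_plot,
             (fingerprint(Signature(label, "up",
                                    pd.concat([bundle.signatures[label]["up"].frame,
                                               bundle.signatures[label]["down"].frame])), table),
              d / "fingerprint.png", label)),
        ]
        if label in bundle.atac_tables:
            jobs.append((circos_plot,
                         (circos_track_data(table, bundle.atac_tables[label]),
                          d / "circos.png", label)))
        for fn, args in jobs:
            try:
                fn(*args)
                written.append(args[1])
            except Exception:  # pragma: no cover - defensive
                log.exception("render failed: %s %s", fn.__name__, args[1])
    return written
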