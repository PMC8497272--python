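"""Render the cohort's standard figures under results/figures/.

Volcano and fingerprint per line, a Venn of the two co-expression lines'
protein-coding up signatures, and a circular per-chromosome track plot for
the first co-expression line.  Figures visualize module outputs only.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import RESULTS, load_cohort

from fusionsig import (Signature, circos_track_data, filter_down, filter_up,
                       fingerprint, venn, volcano_points)
from fusionsig.compare import _member_ids
from fusionsig.genetypes import DEFAULT_RULES
from fusionsig.plots import circos_plot, fingerprint_plot, venn_plot, volcano_plot


def main() -> None:
    figs = RESULTS / "figures"
    figs.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort()
    tables = {label: mace for label, (mace, _) in cohort.items()}

    for label, (mace, atac) in cohort.items():
        volcano_plot(volcano_points(mace), figs / f"volcano_{label}.png", label)
        up, down = filter_up(mace, label=label), filter_down(mace, label=label)
        combined = Signature(label, "up", pd.concat([up.frame, down.frame]))
        fingerprint_plot(fingerprint(combined, mace), figs / f"fingerprint_{label}.png", label)

    ids = {l: _member_ids(filter_up(tables[l], label=l), tables, "PCG", DEFAULT_RULES)
           for l in ("co_1", "co_2")}
    venn_plot(venn(ids), figs / "venn_co_lines_up_pcg.png", "co-expression up PCGs")

    mace, atac = cohort["co_1"]
    circos_plot(circos_track_data(mace, atac), figs / "circos_co_1.png", "co_1")
    print(f"wrote figures to {figs}")


if __name__ == "__main__":
    main()
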