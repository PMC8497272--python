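"""De novo induced and shut-down transcription per cell line.

Detects the zero-read transition sets, reports their read mass (induced
reads for de novo sets, mock reads for shut-down sets) and intersects the
de novo genes with each line's highly significant up signature, restricted
to protein-coding genes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import RESULTS, load_cohort

from fusionsig import detect_transitions, filter_up, intersect_significant


def main() -> None:
    rows = []
    for label, (mace, _) in load_cohort().items():
        dage = detect_transitions(mace)
        up = filter_up(mace, label=label)
        overlap = intersect_significant(dage, up, restrict_to="PCG")
        d = RESULTS / "cohort" / label
        dage.de_novo.to_csv(d / "de_novo.tsv", sep="\t", index=False)
        dage.shutdown.to_csv(d / "shutdown.tsv", sep="\t", index=False)
        rows.append({"cell_line": label,
                     "n_de_novo": len(dage.de_novo), "de_novo_reads": round(dage.de_novo_reads, 1),
                     "n_shutdown": len(dage.shutdown), "shutdown_reads": round(dage.shutdown_reads, 1),
                     "de_novo_in_up_pcg": len(overlap)})
        print(f"{label}: {len(dage.de_novo)} de novo ({dage.de_novo_reads:.0f} reads), "
              f"{len(dage.shutdown)} shut-down ({dage.shutdown_reads:.0f} reads); "
              f"{len(overlap)} de novo PCGs inside the significant up signature")
    pd.DataFrame(rows).to_csv(RESULTS / "transition_summary.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'transition_summary.tsv'}")


if __name__ == "__main__":
    main()
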