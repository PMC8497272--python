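"""Shared vs idiosyncratic signatures of the two co-expression lines, and
the protein-coding heatmap matrix across the cohort.

The overlap analysis uses protein-coding up/down signature members only;
the heatmap matrix collects each gene's log2FC in every line (fill 0 where
a line never saw the gene).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort import RESULTS, load_cohort

from fusionsig import filter_down, filter_up, heatmap_matrix, idiosyncratic, venn
from fusionsig.compare import _member_ids
from fusionsig.genetypes import DEFAULT_RULES


def main() -> None:
    cohort = load_cohort()
    tables = {label: mace for label, (mace, _) in cohort.items()}
    sigs = {label: {"up": filter_up(t, label=label), "down": filter_down(t, label=label)}
            for label, t in tables.items()}

    a, b = "co_1", "co_2"
    for direction in ("up", "down"):
        ia = _member_ids(sigs[a][direction], tables, "PCG", DEFAULT_RULES)
        ib = _member_ids(sigs[b][direction], tables, "PCG", DEFAULT_RULES)
        vc = venn({a: ia, b: ib})
        a_only, b_only, shared = idiosyncratic(ia, ib)
        print(f"{direction}: {len(shared)} shared PCGs, {len(a_only)} idiosyncratic to {a}, "
              f"{len(b_only)} idiosyncratic to {b}")

    for i, labels in enumerate((["direct_1", "reciprocal_1", "co_1"],
                                ["direct_2", "reciprocal_2", "co_2"])):
        members = [sigs[l][d] for l in labels for d in ("up", "down")]
        hm = heatmap_matrix(members, {l: tables[l] for l in labels}, restrict_to="PCG")
        out = RESULTS / f"heatmap_set_{i + 1}.tsv"
        hm.frame.reset_index(names="gene_id").to_csv(out, sep="\t", index=False)
        print(f"heatmap set {i + 1} ({'+'.join(labels)}): {hm.n_genes} protein-coding genes -> {out}")


if __name__ == "__main__":
    main()
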