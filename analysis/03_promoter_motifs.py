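#!/usr/bin/env python
"""Scan TSS-anchored promoter windows of every group member for the
consensus TATA box (TATA(T/A)ATA in -50..-1, sense strand), ABRE
(YACGTGKC) and DRE/CRT (RCCGAC) in -1000..+100 on both strands, and
tabulate per-group presence percentages.

Writes results/03_motif_frequency.tsv and per-gene hits.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_dataset, load_groups  # noqa: E402

from groupscan.motifs import group_motif_frequency, scan_gene  # noqa: E402


def main() -> None:
    genome, models, truth = load_dataset()
    groups = load_groups(truth)
    by_id = {m.gene_id: m for m in models}
    member_ids = sorted({g for ms in groups.values() for g in ms})
    presence, rows = {}, []
    for gid in member_ids:
        scans = scan_gene(by_id[gid], genome)
        presence[gid] = {m: r.present for m, r in scans.items()}
        for m, r in scans.items():
            rows.append({"gene_id": gid, "motif": m, "n_hits": len(r.matches)})
    pd.DataFrame(rows).to_csv(RESULTS / "03_motif_hits.tsv", sep="\t", index=False)
    freq = group_motif_frequency(groups, presence)
    freq.to_csv(RESULTS / "03_motif_frequency.tsv", sep="\t", index=False)
    print("promoter motif presence (% of genes):")
    print(
        freq.pivot_table(index="group", columns="motif", values="percent")
        .round(1)
        .to_string()
    )
    print(
        "\nexpected pattern: consensus TATA enriched in the DEG groups over the "
        "stable class; ABRE/DRE more frequent in up- than down-regulated groups."
    )


if __name__ == "__main__":
    main()
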