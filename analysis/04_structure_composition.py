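#!/usr/bin/env python
"""Structural features (gene/CDS length, intron and isoform counts) and
positional composition (binned G+C, CpG, C3pG1 profiles with 5'->3'
gradient slopes) per gene group.

Writes results/04_structural_features.tsv, 04_profiles.tsv and a profile
figure under results/figures/.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_dataset, load_groups  # noqa: E402

from groupscan.features import (  # noqa: E402
    gradient_slope,
    structural_features,
    window_composition,
)
from groupscan.io_formats import extract_cds, strip_stop, validate_cds  # noqa: E402
from groupscan.plotting import plot_profiles  # noqa: E402


def main() -> None:
    genome, models, truth = load_dataset()
    groups = load_groups(truth)
    feats = pd.DataFrame([asdict(structural_features(m)) for m in models])
    feats.to_csv(RESULTS / "04_structural_features.tsv", sep="\t", index=False)
    feats = feats.set_index("gene_id")

    print("structural medians per group:")
    for name, members in groups.items():
        sub = feats.loc[feats.index.intersection(members)]
        print(
            f"  {name:7s} n={len(sub):4d}  gene_length={sub.gene_length.median():7.0f}"
            f"  cds_length={sub.cds_length.median():6.0f}"
            f"  introns={sub.intron_count.median():4.1f}"
            f"  isoforms={sub.n_variants.median():3.1f}"
        )

    cds_by_gene = {}
    for m in models:
        cds = extract_cds(m, genome)
        if not validate_cds(cds):
            cds_by_gene[m.gene_id] = strip_stop(cds)

    rows = []
    print("\n5'->3' gradient slopes (per bin) of the mean profile:")
    for name, members in {**groups, "genome": list(cds_by_gene)}.items():
        per_metric = {"gc": [], "cpg": [], "c3pg1": []}
        for gid in members:
            cds = cds_by_gene.get(gid)
            if cds is None:
                continue
            prof = window_composition(cds)
            if prof and prof.full_bins is not None:
                per_metric["gc"].append(prof.full_bins.gc)
                per_metric["cpg"].append(prof.full_bins.cpg)
                per_metric["c3pg1"].append(prof.full_bins.c3pg1)
        slopes = {}
        for metric, vecs in per_metric.items():
            mean = np.nanmean(np.vstack(vecs), axis=0)
            slopes[metric] = gradient_slope(mean)
            for b, v in enumerate(mean):
                rows.append({"group": name, "metric": metric, "bin": b + 1,
                             "mean": v, "n": len(vecs)})
        print(f"  {name:7s} gc={slopes['gc']:+.5f}  cpg={slopes['cpg']:+.5f}"
              f"  c3pg1={slopes['c3pg1']:+.5f}")
    profiles = pd.DataFrame(rows)
    profiles.to_csv(RESULTS / "04_profiles.tsv", sep="\t", index=False)
    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    plot_profiles(profiles.assign(sd=np.nan), figdir / "04_gc_profile.png", "gc")
    print(
        "\nexpected pattern: the stable class shows the steep negative G+C "
        "gradient planted in its coding sequences; DEG groups are flatter."
    )


if __name__ == "__main__":
    main()
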