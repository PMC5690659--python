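#!/usr/bin/env python
"""Generate the study dataset: a synthetic genome + annotation + 12-library
count table emulating a two-cultivar (tolerant/sensitive) x two-condition
(control/stress) x three-timepoint (0.5, 4, 28 h) design with planted
up-/down-/stable-regulated gene classes.

Writes results/dataset/ (FASTA, GFF3, TSVs) and a short summary of the
planted truth.  All downstream drivers (02-06) read from here.
"""

from pathlib import Path

import pandas as pd

from groupscan.simulate import GeneratorConfig, write_dataset

SEED = 20170
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = GeneratorConfig()
    paths = write_dataset(cfg, SEED, OUT / "dataset")
    truth = pd.read_csv(paths["truth"], sep="\t")
    summary = truth["class"].value_counts().rename("n_genes")
    summary.to_csv(OUT / "01_planted_classes.tsv", sep="\t")
    print(f"wrote dataset for {cfg.n_genes} genes (seed {SEED}):")
    for name, p in paths.items():
        print(f"  {name}: {p}")
    print("\nplanted classes:")
    print(summary.to_string())
    print(
        f"\nplanted fold-changes: up x{cfg.fc_up:g}, down x{1 / abs(cfg.fc_down):g}; "
        f"NB dispersion {cfg.nb_dispersion}; {cfg.library_size:,}-read libraries"
    )


if __name__ == "__main__":
    main()
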