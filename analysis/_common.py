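"""Shared loading helpers for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from groupscan.io_formats import read_annotation, read_genome

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATASET = RESULTS / "dataset"


def load_dataset():
    genome = read_genome(DATASET / "genome.fa")
    models = read_annotation(DATASET / "annotation.gff3", genome)
    truth = pd.read_csv(DATASET / "truth.tsv", sep="\t").set_index("gene_id")
    return genome, models, truth


def load_groups(truth: pd.DataFrame) -> dict[str, list[str]]:
    """Built U/D groups from driver 02, plus the planted stable class as the
    SG side (the strict all-6-comparisons stable rule is noise-limited under
    the default dispersion; driver 02 prints the caveat)."""
    groups_df = pd.read_csv(RESULTS / "02_groups.tsv", sep="\t")
    out: dict[str, list[str]] = {}
    for name in ("U40", "D40", "U500", "D500"):
        members = groups_df.loc[groups_df.group == name, "gene_id"].tolist()
        if members:
            out[name] = members
    out["Sclass"] = truth.index[truth["class"] == "stable"].tolist()
    return out
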