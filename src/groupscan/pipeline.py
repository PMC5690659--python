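"""End-to-end orchestration: parse -> groups -> motifs -> features -> rscu
-> stats, with structured exclusion logging and a run manifest.

Every stage writes a tidy TSV under the output directory; the manifest
records the config hash, per-stage gene counts, and a checksum per output so
reruns with identical inputs are verifiable as identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import ExclusionLog
from .codons import group_rscu, join_trna_copies, rscu_long
from .expression import build_top_groups, classify_counts
from .features import (
    gradient_slope,
    structural_features,
    window_composition,
)
from .io_formats import (
    extract_cds,
    read_annotation,
    read_counts,
    read_genome,
    strip_stop,
    validate_cds,
)
from .motifs import group_motif_frequency, scan_gene
from .stats import pairwise_compare, results_frame

__all__ = ["RunConfig", "run_all"]

STAGES = ("parse", "groups", "motifs", "features", "rscu", "stats")


@dataclass
class RunConfig:
    genome: str
    annotation: str
    counts: str
    library_sizes: str
    outdir: str
    adjp: str | None = None
    trna: str | None = None
    fc_up: float = 2.0
    fc_down: float = -2.0
    alpha: float = 0.01
    stable_band: float = 1.1
    min_reads: int = 20
    top_ns: tuple[int, int] = (40, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_up <= 0 or self.stable_band <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "top_ns" in d:
            d["top_ns"] = tuple(d["top_ns"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Input paths are validated before any stage runs; a stage failure aborts
    with the stage name in the raised error.
    """
    missing = [
        p
        for p in (config.genome, config.annotation, config.counts, config.library_sizes,
                  config.adjp, config.trna)
        if p is not None and not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = ExclusionLog()
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
    }

    def finish_stage(stage: str, info: dict, outputs: dict[str, pd.DataFrame]) -> None:
        manifest["stages"][stage] = info
        for name, df in outputs.items():
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            manifest["outputs"][name] = _checksum(path)

    try:
        stage = "parse"
        genome = read_genome(config.genome)
        models = read_annotation(config.annotation, genome, log)
        cm = read_counts(config.counts, config.library_sizes)
        finish_stage(stage, {"n_genes": len(models), "n_libraries": len(cm.libraries)}, {})

        stage = "groups"
        adjp = pd.read_csv(config.adjp, sep="\t") if config.adjp else None
        records = classify_counts(
            cm, adjp, config.min_reads, config.fc_up, config.fc_down,
            config.alpha, config.stable_band,
        )
        groups = build_top_groups(records, config.top_ns, log)
        group_rows = [
            {"group": g.name, "rank": i + 1, "gene_id": gid,
             "score": g.rank_scores[gid]}
            for g in groups.values()
            for i, gid in enumerate(g.members)
        ]
        finish_stage(
            stage,
            {"n_comparisons": len(records),
             "group_sizes": {k: len(v) for k, v in groups.items()}},
            {"classification": records, "groups": pd.DataFrame(group_rows)},
        )

        stage = "motifs"
        by_id = {m.gene_id: m for m in models}
        member_ids = sorted({gid for g in groups.values() for gid in g.members})
        presence: dict[str, dict[str, bool]] = {}
        motif_rows = []
        for gid in member_ids:
            model = by_id.get(gid)
            if model is None:
                log.add("motifs", gid, "gene_not_in_annotation")
                continue
            scans = scan_gene(model, genome)
            presence[gid] = {m: r.present for m, r in scans.items()}
            for m, r in scans.items():
                motif_rows.append(
                    {"gene_id": gid, "motif": m, "n_hits": len(r.matches),
                     "positions": ";".join(str(x.position) for x in r.matches)}
                )
        members_map = {name: g.members for name, g in groups.items() if len(g)}
        freq = group_motif_frequency(members_map, presence)
        finish_stage(
            stage, {"n_genes_scanned": len(presence)},
            {"motifs_genes": pd.DataFrame(motif_rows), "motif_frequency": freq},
        )

        stage = "features"
        feat_rows = []
        cds_by_gene: dict[str, str] = {}
        for m in models:
            sf = structural_features(m)
            feat_rows.append(dataclasses.asdict(sf))
            cds = extract_cds(m, genome)
            reasons = validate_cds(cds)
            if reasons:
                log.add("features", m.gene_id, ",".join(reasons))
            else:
                cds_by_gene[m.gene_id] = strip_stop(cds)
        features = pd.DataFrame(feat_rows)
        profiles = _group_profiles(members_map, cds_by_gene, log)
        finish_stage(
            stage,
            {"n_genes": len(features), "n_codon_eligible": len(cds_by_gene)},
            {"features_genes": features, "profiles": profiles},
        )

        stage = "rscu"
        matrix = group_rscu(members_map, cds_by_gene, genome_column=True, log=log)
        long = rscu_long(matrix)
        if config.trna:
            trna = pd.read_csv(config.trna, sep="\t")
            long = join_trna_copies(matrix, trna)
        finish_stage(stage, {"n_columns": matrix.shape[1]}, {"rscu": long})

        stage = "stats"
        feat_table = features.set_index("gene_id")[
            ["gene_length", "cds_length", "intron_count", "n_variants"]
        ].astype(float)
        res = pairwise_compare(feat_table, members_map, "continuous", log)
        pres_table = pd.DataFrame.from_dict(presence, orient="index").astype(float)
        if not pres_table.empty:
            res += pairwise_compare(pres_table, members_map, "binary", log)
        finish_stage(stage, {"n_tests": len(res)}, {"stats": results_frame(res)})
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    exclusions = pd.DataFrame(log.to_rows(), columns=["stage", "gene_id", "reason"])
    exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    manifest["outputs"]["exclusions"] = _checksum(outdir / "exclusions.tsv")
    manifest["n_exclusions"] = len(log)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _group_profiles(
    members_map: dict[str, list[str]],
    cds_by_gene: dict[str, str],
    log: ExclusionLog,
) -> pd.DataFrame:
    """Per-group binned metagene profiles (mean, sd, n per bin) for G+C,
    CpG and C3pG1, over group members plus a whole-annotation column."""
    groups = dict(members_map)
    groups["genome"] = sorted(cds_by_gene)
    rows = []
    for group, members in groups.items():
        per_metric: dict[str, list[np.ndarray]] = {"gc": [], "cpg": [], "c3pg1": []}
        for gid in members:
            cds = cds_by_gene.get(gid)
            if cds is None:
                continue
            prof = window_composition(cds)
            if prof is None or prof.full_bins is None:
                log.add("features", gid, "cds_too_short_for_binned_profile")
                continue
            per_metric["gc"].append(prof.full_bins.gc)
            per_metric["cpg"].append(prof.full_bins.cpg)
            per_metric["c3pg1"].append(prof.full_bins.c3pg1)
        for metric, vecs in per_metric.items():
            if not vecs:
                continue
            mat = np.vstack(vecs)
            mean = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1) if len(vecs) > 1 else np.full(mat.shape[1], np.nan)
            slope = gradient_slope(mean)
            for b in range(mat.shape[1]):
                rows.append(
                    {"group": group, "metric": metric, "bin": b + 1,
                     "mean": mean[b], "sd": sd[b],
                     "n": int(np.sum(~np.isnan(mat[:, b]))),
                     "slope": slope if b == 0 else math.nan}
                )
    return pd.DataFrame(rows)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]
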