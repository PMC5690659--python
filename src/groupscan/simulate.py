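"""Seeded synthetic dataset generator: genome FASTA, GFF3 annotation,
12-library count table, and per-gene truth tables.

The generator emulates the study design every pipeline stage assumes: two
cultivars (tolerant / sensitive) x two oxygen conditions (control / stress)
x three sampling times (0.5, 4, 28 h), one library each.  Genes belong to
planted classes (up, down, stable, background, optionally cultivar-divergent)
that control

* the stress/control fold-change multiplier of negative-binomial counts,
* promoter motif presence (consensus TATA in -50..-1; ABRE and DRE/CRT in
  the extended promoter, random strand),
* structural distributions (exon number, CDS length, isoform count), and
* coding-sequence composition (a linear 5'->3' G+C gradient and a C-vs-T
  bias at the third position of the six two-fold pyrimidine-ending codon
  families: Phe, Tyr, His, Asn, Asp, Cys).

Unintended ABRE/DRE matches inside generated promoter windows are scrubbed
(single-base randomization, planted spans and CDS bases protected) so the
planted truth equals the realized motif presence up to the tiny residue the
protected CDS bases can harbor.

Determinism: one RNG stream per artifact component (truth, sequence,
counts), all spawned from the master seed, so identical seed + config yield
byte-identical artifacts, and adding sequence detail does not perturb count
noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._util import reverse_complement
from .io_formats import (
    CONDITIONS,
    CULTIVARS,
    TIMEPOINTS,
    CountMatrix,
    GeneModel,
    LibraryKey,
    write_annotation,
    write_counts,
)
from .motifs import IUPAC, scan_iupac

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_config",
    "assign_truth",
    "generate_annotation",
    "generate_counts",
    "generate_dataset",
    "write_dataset",
    "sample_cds",
    "expected_gc_profile",
    "expected_gc_bins",
]

GENE_CLASSES = ("up", "down", "stable", "background", "divergent")

# third-position C/T members of the six two-fold pyrimidine-ending families
_NNY_PREFIXES = ("TT", "TA", "CA", "AA", "GA", "TG")
_STOPS = ("TAA", "TAG", "TGA")

_BASE_ORDER = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class ClassParams:
    """Planted per-class distributions."""

    tata: float  # probability of a planted consensus TATA box
    abre: float
    dre: float
    exon_lambda: float  # exon count = 1 + Poisson(exon_lambda)
    cds_codons: tuple[int, int]  # uniform range, sense codons (>= 90)
    variants_lambda: float  # isoform count = 1 + Poisson(variants_lambda)
    gc_start: float  # expected G+C at the CDS 5' end
    gc_end: float  # ... and at the 3' end (linear in between)
    c_end_prob: float  # C-vs-T odds weight at NNY third positions
    c3pg1_odds: float = 1.0  # odds multiplier for G after a C3 junction


@dataclass(frozen=True)
class GeneratorConfig:
    seed_label: str = "default"
    n_genes: int = 2000
    group_fractions: dict = field(
        default_factory=lambda: {"up": 0.10, "down": 0.10, "stable": 0.25,
                                 "divergent": 0.0}
    )
    fc_up: float = 4.0
    fc_down: float = -4.0
    nb_dispersion: float = 0.05
    base_mean_reads: float = 200.0
    library_size: int = 2_000_000
    scale_to_library_size: bool = False
    genes_per_chromosome: int = 100
    intron_length: tuple[int, int] = (80, 400)
    utr5_length: tuple[int, int] = (60, 120)
    utr3_length: tuple[int, int] = (60, 200)
    class_params: dict = field(
        default_factory=lambda: {
            "up": ClassParams(0.40, 0.40, 0.35, 1.2, (100, 250), 0.3, 0.50, 0.47, 0.70),
            "down": ClassParams(0.40, 0.10, 0.10, 1.2, (100, 250), 0.3, 0.50, 0.47, 0.60),
            "stable": ClassParams(0.06, 0.10, 0.10, 5.0, (250, 450), 1.5, 0.60, 0.40, 0.50),
            "background": ClassParams(0.15, 0.15, 0.15, 3.0, (150, 350), 0.8, 0.55, 0.45, 0.55),
            "divergent": ClassParams(0.15, 0.15, 0.15, 1.2, (100, 250), 0.3, 0.50, 0.47, 0.55),
        }
    )

    def __post_init__(self) -> None:
        if sum(self.group_fractions.values()) > 1 + 1e-9:
            raise ValueError("group fractions must sum to <= 1")
        if self.fc_up < 2:
            raise ValueError("fc_up must be >= 2")
        if self.fc_down > -2:
            raise ValueError("fc_down must be <= -2")
        for name, cp in self.class_params.items():
            for p in (cp.tata, cp.abre, cp.dre, cp.c_end_prob):
                if not 0 <= p <= 1:
                    raise ValueError(f"probability out of [0,1] for class {name}")
            if cp.cds_codons[0] < 90:
                raise ValueError("CDS lengths must allow windowed analyses (>=90 codons)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["class_params"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in self.class_params.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        cp = {
            k: ClassParams(**{
                **v,
                "cds_codons": tuple(v["cds_codons"]),
            })
            for k, v in d.pop("class_params", {}).items()
        }
        for key in ("intron_length", "utr5_length", "utr3_length"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(class_params=cp or None, **d) if cp else cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    seed: int
    truth: pd.DataFrame
    genome: dict[str, str] | None = None
    models: list[GeneModel] | None = None
    counts: CountMatrix | None = None


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    truth_ss, seq_ss, counts_ss = ss.spawn(3)
    return (
        np.random.default_rng(truth_ss),
        np.random.default_rng(seq_ss),
        np.random.default_rng(counts_ss),
    )


# ---------------------------------------------------------------------------
# truth table


def assign_truth(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted class, fold-change multipliers, motif flags and structural
    values for every gene; exactly one record per gene."""
    n = config.n_genes
    counts = {}
    assigned = 0
    for cls in ("up", "down", "stable", "divergent"):
        k = int(round(config.group_fractions.get(cls, 0.0) * n))
        counts[cls] = k
        assigned += k
    counts["background"] = n - assigned
    classes = np.concatenate(
        [np.repeat(c, k) for c, k in counts.items() if k > 0]
    )
    rng.shuffle(classes)

    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n)])
    mult_up, mult_down = config.fc_up, 1.0 / abs(config.fc_down)
    mult_tol = np.ones(n)
    mult_sen = np.ones(n)
    mult_tol[classes == "up"] = mult_up
    mult_sen[classes == "up"] = mult_up
    mult_tol[classes == "down"] = mult_down
    mult_sen[classes == "down"] = mult_down
    mult_tol[classes == "divergent"] = mult_up
    mult_sen[classes == "divergent"] = mult_down

    rows = {
        "gene_id": gene_ids,
        "class": classes,
        "mult_tolerant": mult_tol,
        "mult_sensitive": mult_sen,
    }
    tata = np.zeros(n, dtype=bool)
    abre = np.zeros(n, dtype=bool)
    dre = np.zeros(n, dtype=bool)
    exon_count = np.zeros(n, dtype=int)
    cds_codons = np.zeros(n, dtype=int)
    n_variants = np.zeros(n, dtype=int)
    gc_start = np.zeros(n)
    gc_end = np.zeros(n)
    c_end = np.zeros(n)
    for cls, cp in config.class_params.items():
        m = classes == cls
        k = int(m.sum())
        if k == 0:
            continue
        tata[m] = rng.random(k) < cp.tata
        abre[m] = rng.random(k) < cp.abre
        dre[m] = rng.random(k) < cp.dre
        exon_count[m] = 1 + rng.poisson(cp.exon_lambda, k)
        cds_codons[m] = rng.integers(cp.cds_codons[0], cp.cds_codons[1] + 1, k)
        n_variants[m] = 1 + np.minimum(rng.poisson(cp.variants_lambda, k), 5)
        gc_start[m] = cp.gc_start
        gc_end[m] = cp.gc_end
        c_end[m] = cp.c_end_prob
    rows.update(
        tata=tata, abre=abre, dre=dre,
        exon_count=exon_count, cds_codons=cds_codons, n_variants=n_variants,
        gc_start=gc_start, gc_end=gc_end, c_end_prob=c_end,
        strand=np.where(rng.random(n) < 0.5, "+", "-"),
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coding-sequence engine


def _gc_levels(n_codons: int, gc_start: float, gc_end: float) -> np.ndarray:
    if n_codons == 1:
        return np.array([gc_start])
    t = np.arange(n_codons) / (n_codons - 1)
    return gc_start + (gc_end - gc_start) * t


def _draw_bases(g: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Base indices (A,C,G,T) with P(C)=P(G)=g/2 per row of u."""
    c_a = (1 - g)[:, None] / 2
    c_g = 0.5 + g[:, None] / 2
    return (u >= c_a).astype(np.int8) + (u >= 0.5) + (u >= c_g)


def _is_stop(b: np.ndarray) -> np.ndarray:
    t, a, g_ = 3, 0, 2
    return (b[:, 0] == t) & (
        ((b[:, 1] == a) & ((b[:, 2] == a) | (b[:, 2] == g_)))
        | ((b[:, 1] == g_) & (b[:, 2] == a))
    )


def sample_cds(
    n_codons: int,
    gc_start: float,
    gc_end: float,
    c_end_prob: float,
    rng: np.random.Generator,
    c3pg1_odds: float = 1.0,
) -> str:
    """Sense codons drawn base-by-base with a linear G+C gradient, stop
    codons rejected, and the NNY two-fold C/T choice reweighted by
    ``c_end_prob`` odds (GC-gradient preserving).  No terminal stop is
    appended here."""
    g = _gc_levels(n_codons, gc_start, gc_end)
    b = _draw_bases(g, rng.random((n_codons, 3)))
    # rejection-sample stop codons
    for _ in range(200):
        stops = _is_stop(b)
        if not stops.any():
            break
        idx = np.nonzero(stops)[0]
        b[idx] = _draw_bases(g[idx], rng.random((len(idx), 3)))
    # C-vs-T reweighting at third positions of the two-fold NNY families
    pref = {p: (("ACGT".index(p[0])), ("ACGT".index(p[1]))) for p in _NNY_PREFIXES}
    in_family = np.zeros(n_codons, dtype=bool)
    for b0, b1 in pref.values():
        in_family |= (b[:, 0] == b0) & (b[:, 1] == b1)
    in_family &= (b[:, 2] == 1) | (b[:, 2] == 3)  # C or T
    if in_family.any() and c_end_prob != 0.5:
        gi = g[in_family]
        beta = c_end_prob / (1 - c_end_prob)
        p_c = gi * beta / (gi * beta + (1 - gi))
        b[in_family, 2] = np.where(rng.random(in_family.sum()) < p_c, 1, 3)
    if c3pg1_odds != 1.0 and n_codons >= 2:
        _reweight_c3pg1(b, g, c3pg1_odds, rng)
    return "".join(_BASE_ORDER[b.ravel()])


def _reweight_c3pg1(
    b: np.ndarray, g: np.ndarray, odds: float, rng: np.random.Generator
) -> None:
    """Redraw first bases following a C3 with G-odds multiplied by ``odds``,
    avoiding the creation of stop codons."""
    after_c = np.nonzero(b[:-1, 2] == 1)[0] + 1
    for i in after_c:
        gi = g[i]
        w = np.array([(1 - gi) / 2, gi / 2, gi / 2 * odds, (1 - gi) / 2])
        w /= w.sum()
        for _ in range(50):
            new = rng.choice(4, p=w)
            b[i, 0] = new
            if not _is_stop(b[i : i + 1]):
                break


def _codon_distribution(
    g: float, c_end_prob: float
) -> np.ndarray:
    """Exact per-codon probability vector (64,) under the sampling scheme at
    G+C level ``g``: iid bases, stop rejection, NNY C/T reweighting."""
    base_p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    codes = np.array(
        [(i, j, k) for i in range(4) for j in range(4) for k in range(4)]
    )
    p = base_p[codes[:, 0]] * base_p[codes[:, 1]] * base_p[codes[:, 2]]
    stop_idx = [_codon_index(s) for s in _STOPS]
    p[stop_idx] = 0.0
    p /= p.sum()
    beta = c_end_prob / (1 - c_end_prob)
    p_c = g * beta / (g * beta + (1 - g))
    for prefix in _NNY_PREFIXES:
        ic = _codon_index(prefix + "C")
        it = _codon_index(prefix + "T")
        mass = p[ic] + p[it]
        p[ic] = mass * p_c
        p[it] = mass * (1 - p_c)
    return p


def _codon_index(codon: str) -> int:
    i = "ACGT"
    return 16 * i.index(codon[0]) + 4 * i.index(codon[1]) + i.index(codon[2])


def expected_gc_profile(
    n_codons: int, gc_start: float, gc_end: float, c_end_prob: float
) -> np.ndarray:
    """Analytic expected G+C per nucleotide position (length 3*n_codons)
    under the sampling scheme — the generator's planted truth."""
    codes = np.array(
        [(i, j, k) for i in range(4) for j in range(4) for k in range(4)]
    )
    is_gc = np.isin(codes, [1, 2]).astype(float)  # C=1, G=2
    out = np.empty(3 * n_codons)
    for t, g in enumerate(_gc_levels(n_codons, gc_start, gc_end)):
        p = _codon_distribution(g, c_end_prob)
        out[3 * t : 3 * t + 3] = p @ is_gc
    return out


def expected_gc_bins(
    n_codons: int, gc_start: float, gc_end: float, c_end_prob: float,
    n_bins: int = 90,
) -> np.ndarray:
    """Planted-truth expected per-bin G+C under the pipeline's binning rule."""
    per_nt = expected_gc_profile(n_codons, gc_start, gc_end, c_end_prob)
    L = len(per_nt)
    bins = (np.arange(L) * n_bins) // L
    num = np.bincount(bins, weights=per_nt, minlength=n_bins)
    den = np.bincount(bins, minlength=n_bins)
    return num / den


# ---------------------------------------------------------------------------
# annotation + genome


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.35) -> np.ndarray:
    return rng.choice(4, size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]).astype(
        np.int8
    )


_PROMOTER_UP = 1000
_PROMOTER_DOWN = 100
_FLANK = 1500
_GAP = 2600


def _concrete_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
                   for c in pattern)


def generate_annotation(
    config: GeneratorConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Materialize genome sequences and gene models for a truth table.

    Genes are placed non-overlapping with flanks large enough that the
    extended promoter window is always extractable and adjacent promoter
    windows never overlap.
    """
    gpc = config.genes_per_chromosome
    n = len(truth)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    n_chrom = (n + gpc - 1) // gpc
    for ci in range(n_chrom):
        sub = truth.iloc[ci * gpc : (ci + 1) * gpc]
        chrom_name = f"chr{ci + 1:02d}"
        layouts = []
        cursor = _FLANK
        for row in sub.itertuples():
            layout = _gene_layout(config, row, cursor, rng)
            layouts.append(layout)
            cursor = layout["end"] + _GAP + int(rng.integers(0, 400))
        length = cursor + _FLANK
        arr = _random_bases(rng, length)
        for row, layout in zip(sub.itertuples(), layouts):
            model = _write_gene(arr, config, row, layout, rng)
            model = dataclasses.replace(model, seq_id=chrom_name)
            _plant_promoter(arr, row, model, rng)
            models.append(model)
        genome[chrom_name] = "".join(_BASE_ORDER[arr])
    return genome, models


def _gene_layout(
    config: GeneratorConfig, row, start: int, rng: np.random.Generator
) -> dict:
    utr5 = int(rng.integers(*_hi(config.utr5_length)))
    utr3 = int(rng.integers(*_hi(config.utr3_length)))
    cds_nt = 3 * (row.cds_codons + 1)  # sense codons + terminal stop
    t_len = utr5 + cds_nt + utr3
    k = int(row.exon_count)
    min_exon = 30
    while k > 1 and t_len < min_exon * k:
        k -= 1
    if k == 1:
        exon_lens = [t_len]
    else:
        extra = rng.multinomial(t_len - min_exon * k, [1.0 / k] * k)
        exon_lens = [min_exon + int(e) for e in extra]
    intron_lens = [int(rng.integers(*_hi(config.intron_length))) for _ in range(k - 1)]
    span = t_len + sum(intron_lens)
    return {
        "start": start,
        "end": start + span,
        "utr5": utr5,
        "utr3": utr3,
        "cds_nt": cds_nt,
        "exon_lens": exon_lens,
        "intron_lens": intron_lens,
        "t_len": t_len,
    }


def _hi(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def _write_gene(
    arr: np.ndarray, config: GeneratorConfig, row, layout: dict,
    rng: np.random.Generator,
) -> GeneModel:
    sense = sample_cds(
        row.cds_codons, row.gc_start, row.gc_end, row.c_end_prob, rng
    )
    stop = _STOPS[rng.integers(3)]
    cds_seq = sense + stop
    utr5_seq = "".join(_BASE_ORDER[_random_bases(rng, layout["utr5"], gc=0.4)])
    utr3_seq = "".join(_BASE_ORDER[_random_bases(rng, layout["utr3"], gc=0.35)])
    transcript = utr5_seq + cds_seq + utr3_seq

    start, span = layout["start"], layout["end"] - layout["start"]
    minus = row.strand == "-"

    # local (gene-span, transcript-orientation) coordinates of each exon
    local_exons = []
    tpos = lpos = 0
    for i, le in enumerate(layout["exon_lens"]):
        local_exons.append((lpos, lpos + le, tpos))
        lpos += le
        if i < len(layout["intron_lens"]):
            lpos += layout["intron_lens"][i]
        tpos += le

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        if minus:
            return start + span - b, start + span - a
        return start + a, start + b

    base_idx = {b: i for i, b in enumerate("ACGT")}
    exon_ivs = []
    for la, lb, tp in local_exons:
        seg = transcript[tp : tp + (lb - la)]
        ga, gb = to_genomic(la, lb)
        gseg = reverse_complement(seg) if minus else seg
        arr[ga:gb] = np.fromiter((base_idx[c] for c in gseg), dtype=np.int8)
        exon_ivs.append((ga, gb))

    # CDS occupies transcript coords [utr5, utr5 + cds_nt)
    cds_ivs = _map_transcript_interval(
        layout["utr5"], layout["utr5"] + layout["cds_nt"], local_exons, to_genomic
    )
    exon_ivs_sorted = sorted(exon_ivs)
    cds_sorted = sorted(cds_ivs)
    if minus:
        exon_ivs_sorted = exon_ivs_sorted[::-1]
        cds_sorted = cds_sorted[::-1]
    tss = start + span - 1 if minus else start
    gid = row.gene_id
    tids = [f"{gid}.{i + 1}" for i in range(int(row.n_variants))]
    return GeneModel(
        gene_id=gid,
        seq_id="",
        strand=row.strand,
        transcript_ids=tids,
        representative_transcript=tids[0],
        tss=tss,
        exons={tid: list(exon_ivs_sorted) for tid in tids},
        cds_segments=cds_sorted,
    )


def _map_transcript_interval(ta: int, tb: int, local_exons, to_genomic) -> list:
    out = []
    for la, lb, tp in local_exons:
        le = lb - la
        s, e = max(ta, tp), min(tb, tp + le)
        if s < e:
            out.append(to_genomic(la + (s - tp), la + (e - tp)))
    return out


def _plant_promoter(
    arr: np.ndarray, row, model: GeneModel, rng: np.random.Generator
) -> None:
    """Plant configured motifs in the oriented promoter window and scrub
    unintended ABRE/DRE matches (CDS bases protected)."""
    up, down = _PROMOTER_UP, _PROMOTER_DOWN
    minus = model.strand == "-"
    if minus:
        glo, ghi = model.tss - down + 1, model.tss + up + 1
    else:
        glo, ghi = model.tss - up, model.tss + down
    window = _BASE_ORDER[arr[glo:ghi]]
    w = list("".join(window))
    if minus:
        w = list(reverse_complement("".join(w)))
    L = len(w)  # = up + down; flanks guarantee no truncation

    protected = np.zeros(L, dtype=bool)
    for s, e in model.cds_segments:  # genomic CDS intervals
        a, b = max(s, glo), min(e, ghi)
        if a < b:
            ia, ib = a - glo, b - glo
            if minus:
                ia, ib = L - ib, L - ia
            protected[ia:ib] = True

    def plant(seq: str, lo: int, hi: int) -> None:
        for _ in range(200):
            pos = int(rng.integers(lo, hi - len(seq) + 1))
            if not protected[pos : pos + len(seq)].any():
                w[pos : pos + len(seq)] = list(seq)
                protected[pos : pos + len(seq)] = True
                return
        raise RuntimeError("could not place planted motif")

    if row.tata:
        plant(_concrete_motif("TATAWATA", rng), up - 50, up)
    if row.abre:
        inst = _concrete_motif("YACGTGKC", rng)
        if rng.random() < 0.5:
            inst = reverse_complement(inst)
        plant(inst, 0, up - 60)
    if row.dre:
        inst = _concrete_motif("RCCGAC", rng)
        if rng.random() < 0.5:
            inst = reverse_complement(inst)
        plant(inst, 0, up - 60)

    for _ in range(100):
        seq = "".join(w)
        bad_spans = []
        for pat in ("YACGTGKC", "RCCGAC"):
            for m in scan_iupac(seq, pat, both_strands=True):
                span = (m.position, m.position + len(pat))
                if not protected[span[0] : span[1]].all():
                    bad_spans.append(span)
        if not bad_spans:
            break
        for s, e in bad_spans:
            free = [i for i in range(s, e) if not protected[i]]
            if free:
                i = free[int(rng.integers(len(free)))]
                w[i] = "ACGT"[rng.integers(4)]

    out = "".join(w)
    if minus:
        out = reverse_complement(out)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    arr[glo:ghi] = np.fromiter((base_idx[c] for c in out), dtype=np.int8)


# ---------------------------------------------------------------------------
# counts


def generate_counts(
    config: GeneratorConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> CountMatrix:
    """Negative-binomial counts for the 12-library design.

    Per gene and library, counts ~ NB(mean = base expression x planted
    stress multiplier, dispersion = nb_dispersion); stable/background genes
    keep identical means under control and stress.  ``library_size`` is the
    RPM denominator; with ``scale_to_library_size`` the expected column
    totals are rescaled to it (the default leaves planted fold-changes
    exactly realized, with library sizes exceeding annotated totals).
    """
    n = len(truth)
    libraries = [
        LibraryKey(cv, cond, tp)
        for cv in CULTIVARS for cond in CONDITIONS for tp in TIMEPOINTS
    ]
    mult = {
        ("tolerant", "stress"): truth.mult_tolerant.to_numpy(),
        ("sensitive", "stress"): truth.mult_sensitive.to_numpy(),
        ("tolerant", "control"): np.ones(n),
        ("sensitive", "control"): np.ones(n),
    }
    means = np.empty((n, len(libraries)))
    for j, lib in enumerate(libraries):
        means[:, j] = config.base_mean_reads * mult[(lib.cultivar, lib.condition)]
    if config.scale_to_library_size:
        means *= config.library_size / means.sum(axis=0, keepdims=True)
    phi = config.nb_dispersion
    if phi > 0:
        r = 1.0 / phi
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(means)
    return CountMatrix(
        gene_ids=list(truth.gene_id),
        libraries=libraries,
        counts=counts,
        library_sizes=np.full(len(libraries), float(config.library_size)),
    )


# ---------------------------------------------------------------------------
# top level


def generate_dataset(
    config: GeneratorConfig, seed: int, with_sequences: bool = True
) -> SyntheticDataset:
    rng_truth, rng_seq, rng_counts = _streams(seed)
    truth = assign_truth(config, rng_truth)
    genome = models = None
    if with_sequences:
        genome, models = generate_annotation(config, truth, rng_seq)
    counts = generate_counts(config, truth, rng_counts)
    return SyntheticDataset(config, seed, truth, genome, models, counts)


def write_dataset(config: GeneratorConfig, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.gff3, counts.tsv, library_sizes.tsv and
    truth.tsv; byte-identical across runs with the same seed and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config, seed, with_sequences=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "counts": outdir / "counts.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in ds.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_annotation(ds.models, paths["annotation"])
    write_counts(ds.counts, paths["counts"], paths["library_sizes"])
    truth = ds.truth.copy()
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    config.to_yaml(paths["config"])
    return paths
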