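"""Per-gene structural and compositional features.

Structural: gene span, concatenated CDS length, intron count of the
representative transcript, and number of splicing variants.

Compositional: G+C fraction, CpG dinucleotide rate, per-codon-position base
fractions (e.g. G1, C3), and the C3pG1 rate (codon ending in C followed by a
codon starting with G, per codon junction), each computed for four windows of
the stop-trimmed CDS:

* ``full``    — a metagene profile: the CDS divided into 90 equal
                relative-position bins with within-bin averaging;
* ``start90`` / ``middle90`` / ``end90`` — the first, centered, and last 90
                nucleotides (codon-aligned; defined only when the CDS has at
                least 90 codons).

5'->3' gradients are summarized by the ordinary least-squares slope of a
binned metric against bin index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel

__all__ = [
    "StructuralFeatures",
    "WindowMetrics",
    "CompositionProfile",
    "structural_features",
    "window_composition",
    "window_metrics",
    "gradient_slope",
    "N_BINS",
    "WINDOW_NT",
]

N_BINS = 90
WINDOW_NT = 90

BASES = "ACGT"


@dataclass
class StructuralFeatures:
    gene_id: str
    gene_length: int
    cds_length: int  # concatenated CDS, stop codon included
    intron_count: int
    n_variants: int


def structural_features(gene: GeneModel) -> StructuralFeatures:
    lo, hi = gene.gene_span
    cds_length = sum(e - s for s, e in gene.cds_segments)
    return StructuralFeatures(
        gene_id=gene.gene_id,
        gene_length=hi - lo,
        cds_length=cds_length,
        intron_count=len(gene.rep_exons) - 1,
        n_variants=gene.n_variants,
    )


@dataclass
class WindowMetrics:
    """Composition summary of one contiguous, frame-aligned window."""

    gc_fraction: float
    cpg_rate: float  # CG dinucleotides per junction (overlapping)
    base_at_position: dict[str, float]  # e.g. "G1", "C3" -> fraction
    c3pg1_rate: float  # per codon junction


@dataclass
class CompositionProfile:
    gene_id: str
    full_bins: "BinnedProfile | None"
    start90: WindowMetrics | None
    middle90: WindowMetrics | None
    end90: WindowMetrics | None


@dataclass
class BinnedProfile:
    """Per-bin metric vectors over the 90 relative-position bins."""

    gc: np.ndarray
    cpg: np.ndarray
    c3pg1: np.ndarray
    base_at_position: dict[str, np.ndarray] = field(default_factory=dict)


def _codon_aligned_middle_start(n_codons: int, window_codons: int = 30) -> int:
    # centered window, ties resolved toward the 5' end
    return (n_codons - window_codons) // 2


def middle_window(cds: str, window_nt: int = WINDOW_NT) -> str:
    n_codons = len(cds) // 3
    c0 = _codon_aligned_middle_start(n_codons, window_nt // 3)
    return cds[3 * c0 : 3 * c0 + window_nt]


def window_metrics(window: str) -> WindowMetrics:
    """Composition metrics of a frame-aligned window (frame starts at 0).

    N bases are excluded from every denominator; junctions involving N do
    not count as CpG or C3pG1.
    """
    if len(window) % 3 != 0:
        raise ValueError("window length must be a multiple of 3")
    arr = np.frombuffer(window.encode(), dtype="S1").astype("U1")
    defined = arr != "N"
    n_def = int(defined.sum())
    gc = float(np.isin(arr, ["G", "C"])[defined].sum() / n_def) if n_def else math.nan

    n_junc = len(arr) - 1
    if n_junc > 0:
        is_cg = (arr[:-1] == "C") & (arr[1:] == "G")
        cpg = float(is_cg.sum() / n_junc)
    else:
        cpg = math.nan

    base_at_position: dict[str, float] = {}
    for p in range(3):
        sub = arr[p::3]
        subdef = sub != "N"
        tot = int(subdef.sum())
        for b in BASES:
            base_at_position[f"{b}{p + 1}"] = (
                float((sub == b).sum() / tot) if tot else math.nan
            )

    n_codons = len(arr) // 3
    if n_codons >= 2:
        third = arr[2::3][: n_codons - 1]
        first_next = arr[0::3][1:n_codons]
        c3pg1 = float(((third == "C") & (first_next == "G")).sum() / (n_codons - 1))
    else:
        c3pg1 = math.nan
    return WindowMetrics(gc, cpg, base_at_position, c3pg1)


def _binned_profile(cds: str, n_bins: int = N_BINS) -> BinnedProfile:
    arr = np.frombuffer(cds.encode(), dtype="S1").astype("U1")
    L = len(arr)
    pos_bin = (np.arange(L) * n_bins) // L
    defined = arr != "N"
    is_gc = np.isin(arr, ["G", "C"]) & defined

    def bin_mean(values: np.ndarray, mask: np.ndarray, bins: np.ndarray) -> np.ndarray:
        num = np.bincount(bins[mask], weights=values[mask], minlength=n_bins)
        den = np.bincount(bins[mask], minlength=n_bins).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    gc = bin_mean(is_gc.astype(float), defined, pos_bin)

    junc_ok = defined[:-1] & defined[1:]
    is_cg = (arr[:-1] == "C") & (arr[1:] == "G")
    cpg = bin_mean(is_cg.astype(float), junc_ok, pos_bin[:-1])

    n_codons = L // 3
    if n_codons >= 2:
        third_idx = np.arange(n_codons - 1) * 3 + 2
        third = arr[third_idx]
        first_next = arr[third_idx + 1]
        cj_ok = (third != "N") & (first_next != "N")
        is_c3pg1 = (third == "C") & (first_next == "G")
        c3pg1 = bin_mean(is_c3pg1.astype(float), cj_ok, pos_bin[third_idx])
    else:
        c3pg1 = np.full(n_bins, np.nan)

    base_at_position: dict[str, np.ndarray] = {}
    for p in range(3):
        idx = np.arange(p, L, 3)
        sub, bins = arr[idx], pos_bin[idx]
        subdef = sub != "N"
        for b in BASES:
            base_at_position[f"{b}{p + 1}"] = bin_mean(
                (sub == b).astype(float), subdef, bins
            )
    return BinnedProfile(gc, cpg, c3pg1, base_at_position)


def window_composition(cds: str) -> CompositionProfile | None:
    """Composition profile of a stop-trimmed CDS (length divisible by 3).

    start/middle/end windows require >= 270 nt (90 codons); the binned full
    profile requires >= 90 nt.  Returns None when even that is unavailable.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3 (strip the stop first)")
    full = _binned_profile(cds) if len(cds) >= N_BINS else None
    if len(cds) >= 3 * WINDOW_NT:
        start = window_metrics(cds[:WINDOW_NT])
        middle = window_metrics(middle_window(cds))
        end = window_metrics(cds[-WINDOW_NT:])
    else:
        start = middle = end = None
    if full is None and start is None:
        return None
    return CompositionProfile("", full, start, middle, end)


def gradient_slope(binned_metric: np.ndarray) -> float:
    """OLS slope of a binned metric against bin index; NaN bins skipped.

    Returns NaN when fewer than two bins are defined.
    """
    y = np.asarray(binned_metric, dtype=float)
    x = np.arange(len(y))
    ok = ~np.isnan(y)
    if ok.sum() < 2:
        return math.nan
    return float(np.polyfit(x[ok], y[ok], 1)[0])
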