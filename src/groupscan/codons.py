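"""Relative synonymous codon usage (RSCU) over whole coding sequences and
positional 30-codon windows, pooled per gene group.

RSCU of codon c in synonymous family f (the codons sharing an amino acid) is
the observed count divided by the family mean: RSCU_c = x_c / (sum_f x / n_f).
Uniform usage gives 1 everywhere and within each observed family the RSCU
values sum to the family degeneracy.  The 59 RSCU-eligible codons are the 61
sense codons minus ATG (Met) and TGG (Trp), which have no synonyms; stop
codons are never counted.  Group-level RSCU pools (sums) codon counts across
member CDSs before normalization — the concatenated-usage convention —
rather than averaging per-gene RSCU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import ExclusionLog, reverse_complement

__all__ = [
    "SENSE_CODONS",
    "RSCU_CODONS",
    "CODON_TO_AA",
    "FAMILIES",
    "WINDOWS",
    "CodonCountTable",
    "count_codons",
    "count_all_windows",
    "rscu",
    "group_rscu",
    "rscu_long",
    "join_trna_copies",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
RSCU_CODONS: tuple[str, ...] = tuple(c for c in SENSE_CODONS if c not in ("ATG", "TGG"))

FAMILIES: dict[str, tuple[str, ...]] = {}
for _aa in sorted(set(CODON_TO_AA.values())):
    FAMILIES[_aa] = tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == _aa)

WINDOWS = ("full", "start30", "middle30", "end30")
WINDOW_CODONS = 30


@dataclass
class CodonCountTable:
    window: str
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0  # codons containing N

    def total(self) -> int:
        return sum(self.counts.values())


def _codon_slice(n_codons: int, window: str) -> tuple[int, int]:
    if window == "full":
        return 0, n_codons
    if window == "start30":
        return 0, WINDOW_CODONS
    if window == "end30":
        return n_codons - WINDOW_CODONS, n_codons
    if window == "middle30":
        c0 = (n_codons - WINDOW_CODONS) // 2  # ties toward the 5' end
        return c0, c0 + WINDOW_CODONS
    raise ValueError(f"unknown window {window!r}")


def count_codons(cds: str, window: str = "full") -> CodonCountTable | None:
    """Tally sense codons of a stop-trimmed CDS within one window.

    Positional windows require >= 90 codons and return None otherwise.
    Codons containing N are skipped and tallied separately.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3 (strip the stop first)")
    n_codons = len(cds) // 3
    if window != "full" and n_codons < 3 * WINDOW_CODONS:
        return None
    lo, hi = _codon_slice(n_codons, window)
    table = CodonCountTable(window=window, counts={c: 0 for c in SENSE_CODONS})
    for i in range(lo, hi):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            table.n_skipped += 1
        elif codon in CODON_TO_AA:
            table.counts[codon] += 1
        # stop codons inside the window would have been flagged upstream;
        # defensively they are simply not counted
    return table


def count_all_windows(cds: str) -> dict[str, CodonCountTable]:
    out = {}
    for w in WINDOWS:
        t = count_codons(cds, w)
        if t is not None:
            out[w] = t
    return out


def rscu(counts: CodonCountTable | Mapping[str, int]) -> dict[str, float | None]:
    """RSCU per eligible codon; None for codons of an unobserved family."""
    x = counts.counts if isinstance(counts, CodonCountTable) else dict(counts)
    out: dict[str, float | None] = {}
    for aa, codons in FAMILIES.items():
        if aa in ("M", "W"):
            continue
        fam_total = sum(x.get(c, 0) for c in codons)
        n_f = len(codons)
        for c in codons:
            out[c] = None if fam_total == 0 else x.get(c, 0) * n_f / fam_total
    return out


def _pool(tables: Iterable[CodonCountTable]) -> dict[str, int]:
    pooled = {c: 0 for c in SENSE_CODONS}
    for t in tables:
        for c, n in t.counts.items():
            pooled[c] += n
    return pooled


def group_rscu(
    group_members: Mapping[str, Iterable[str]],
    cds_by_gene: Mapping[str, str],
    genome_column: bool = True,
    log: ExclusionLog | None = None,
) -> pd.DataFrame:
    """Pooled RSCU matrix: 59 codons x (group x window).

    ``cds_by_gene`` holds stop-trimmed, validated CDSs for every eligible
    gene; group members without one are skipped with a log record.  When
    ``genome_column`` is set, a "genome" group pooled over every CDS in
    ``cds_by_gene`` is appended.  Groups with no eligible CDS produce no
    columns.  Values are NaN for unobserved families (distinct from RSCU 0,
    an unused codon in an observed family).
    """
    log = log if log is not None else ExclusionLog()
    groups = {k: list(v) for k, v in group_members.items()}
    if genome_column:
        groups["genome"] = sorted(cds_by_gene)
    columns: dict[tuple[str, str], dict[str, float | None]] = {}
    for group, members in groups.items():
        per_window: dict[str, list[CodonCountTable]] = {w: [] for w in WINDOWS}
        n_eligible = 0
        for g in members:
            cds = cds_by_gene.get(g)
            if cds is None:
                log.add("rscu", g, f"no_eligible_cds_for_group_{group}")
                continue
            n_eligible += 1
            for w, t in count_all_windows(cds).items():
                per_window[w].append(t)
        if n_eligible == 0:
            log.add("rscu", group, "group_without_eligible_cds")
            continue
        for w in WINDOWS:
            if per_window[w]:
                columns[(group, w)] = rscu(_pool(per_window[w]))
    df = pd.DataFrame(
        {col: pd.Series(vals, dtype=float) for col, vals in columns.items()},
        index=list(RSCU_CODONS),
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["group", "window"])
    df.index.name = "codon"
    return df


def rscu_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format view: group, window, codon, amino_acid, rscu."""
    long = (
        matrix.stack(["group", "window"], future_stack=True)
        .rename("rscu")
        .reset_index()
    )
    long["amino_acid"] = long["codon"].map(CODON_TO_AA)
    return long[["group", "window", "codon", "amino_acid", "rscu"]]


def _two_fold_pyrimidine_codons() -> set[str]:
    """Codons ending C/T whose codon box splits NNY vs NNR by amino acid."""
    out = set()
    for box in {c[:2] for c in SENSE_CODONS}:
        ys = [box + b for b in "CT" if box + b in CODON_TO_AA]
        if len(ys) == 2 and CODON_TO_AA[ys[0]] == CODON_TO_AA[ys[1]]:
            rs_aa = {CODON_TO_AA.get(box + b) for b in "AG"}
            if CODON_TO_AA[ys[0]] not in rs_aa:
                out.update(ys)
    return out


TWO_FOLD_NNY = frozenset(_two_fold_pyrimidine_codons())


def join_trna_copies(
    matrix: pd.DataFrame, trna_table: Mapping[str, int] | pd.DataFrame
) -> pd.DataFrame:
    """Annotate the RSCU matrix (long format) with tRNA gene-copy numbers.

    Each codon row gains the copy number of its Watson-Crick anticodon
    (reverse complement of the codon, DNA alphabet) and a wobble flag marking
    C/T-ending codons of two-fold pyrimidine families, which are decoded by
    a single G34 tRNA.  Unknown anticodon strings in the table are an error.
    """
    if isinstance(trna_table, pd.DataFrame):
        trna = dict(zip(trna_table.iloc[:, 0].astype(str), trna_table.iloc[:, 1]))
    else:
        trna = dict(trna_table)
    valid = {reverse_complement(c) for c in SENSE_CODONS}
    unknown = sorted(set(trna) - valid)
    if unknown:
        raise ValueError(f"unknown anticodons in tRNA table: {unknown}")
    long = rscu_long(matrix)
    long["anticodon"] = long["codon"].map(reverse_complement)
    if trna:
        long["trna_copies"] = long["anticodon"].map(lambda a: int(trna.get(a, 0)))
    long["wobble_G34"] = long["codon"].isin(TWO_FOLD_NNY)
    return long
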