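"""IUPAC consensus scanning of TSS-anchored promoter windows.

Three elements are scanned, each within the window the underlying biology
dictates:

* TATA-box — core ``TATA`` plus the 4 bases 3' of it, and the consensus
  ``TATAWATA`` (TATA(T/A)ATA), within the 50 bp immediately upstream of the
  TSS (-50..-1), sense strand only (the TATA-box is orientation-dependent
  relative to the TSS).
* ABRE (ABA-responsive element, ACGT-core G-box variant) — consensus
  ``YACGTGKC`` — and DRE/CRT (dehydration-responsive element / C-repeat) —
  core ``RCCGAC`` — within the extended promoter (1000 bp upstream to 100 bp
  downstream of the TSS), on both strands, as enhancer-like elements.

A match must lie fully inside the window; overlapping matches are all
reported, but presence is binary for the group frequency tables.  ``N`` in
the subject sequence matches no pattern symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._util import reverse_complement
from .io_formats import GeneModel, extract_window

__all__ = [
    "IUPAC",
    "MotifSpec",
    "MotifMatch",
    "MotifScanResult",
    "MOTIFS",
    "scan_iupac",
    "scan_tata",
    "scan_regulatory",
    "scan_gene",
    "group_motif_frequency",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifSpec:
    name: str
    pattern: str  # IUPAC consensus
    upstream: int
    downstream: int
    both_strands: bool

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols in pattern: {sorted(bad)}")
        if self.upstream + self.downstream < len(self.pattern):
            raise ValueError("window shorter than pattern")


MOTIFS: dict[str, MotifSpec] = {
    "TATA_core": MotifSpec("TATA_core", "TATANNNN", 50, 0, False),
    "TATA_consensus": MotifSpec("TATA_consensus", "TATAWATA", 50, 0, False),
    "ABRE": MotifSpec("ABRE", "YACGTGKC", 1000, 100, True),
    "DRE_CRT": MotifSpec("DRE_CRT", "RCCGAC", 1000, 100, True),
}


@dataclass(frozen=True)
class MotifMatch:
    position: int  # of the first matched base, window-relative here
    strand: str  # "+" sense, "-" reverse-complement match


@dataclass
class MotifScanResult:
    gene_id: str
    motif: str
    matches: list[MotifMatch] = field(default_factory=list)

    @property
    def present(self) -> bool:
        return bool(self.matches)

    def tss_relative(self, upstream: int) -> "MotifScanResult":
        """Shift window-relative positions so that the TSS base is 0."""
        return MotifScanResult(
            self.gene_id,
            self.motif,
            [MotifMatch(m.position - upstream, m.strand) for m in self.matches],
        )


def _pattern_regex(pattern: str) -> re.Pattern:
    # N in the subject matches nothing, so character classes never include N
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in pattern.upper()
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def scan_iupac(
    sequence: str, pattern: str, both_strands: bool = False
) -> list[MotifMatch]:
    """All (possibly overlapping) full matches of an IUPAC consensus.

    Minus-strand hits are matches of the reverse-complemented pattern; their
    reported position is still that of the 5'-most base on the given
    sequence.
    """
    if not pattern:
        raise ValueError("empty pattern")
    bad = set(pattern.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols: {sorted(bad)}")
    seq = sequence.upper()
    hits = [MotifMatch(m.start(), "+") for m in _pattern_regex(pattern).finditer(seq)]
    if both_strands:
        rc_pat = _iupac_revcomp(pattern)
        hits += [
            MotifMatch(m.start(), "-") for m in _pattern_regex(rc_pat).finditer(seq)
        ]
    return sorted(hits, key=lambda h: (h.position, h.strand))


_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def _iupac_revcomp(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


def scan_tata(
    gene: GeneModel, genome: Mapping[str, str]
) -> tuple[MotifScanResult, MotifScanResult]:
    """Scan -50..-1 (sense strand) for the TATA core and consensus."""
    core = _scan_window(gene, genome, MOTIFS["TATA_core"])
    consensus = _scan_window(gene, genome, MOTIFS["TATA_consensus"])
    return core, consensus


def scan_regulatory(
    gene: GeneModel, genome: Mapping[str, str]
) -> tuple[MotifScanResult, MotifScanResult]:
    """Scan the extended promoter (both strands) for ABRE and DRE/CRT."""
    abre = _scan_window(gene, genome, MOTIFS["ABRE"])
    dre = _scan_window(gene, genome, MOTIFS["DRE_CRT"])
    return abre, dre


def _scan_window(
    gene: GeneModel, genome: Mapping[str, str], spec: MotifSpec
) -> MotifScanResult:
    window = extract_window(gene, genome, spec.upstream, spec.downstream)
    matches = scan_iupac(window.seq, spec.pattern, spec.both_strands)
    res = MotifScanResult(gene.gene_id, spec.name, matches)
    return res.tss_relative(spec.upstream - window.clip_start)


def scan_gene(gene: GeneModel, genome: Mapping[str, str]) -> dict[str, MotifScanResult]:
    core, consensus = scan_tata(gene, genome)
    abre, dre = scan_regulatory(gene, genome)
    return {r.motif: r for r in (core, consensus, abre, dre)}


def group_motif_frequency(
    group_members: Mapping[str, Iterable[str]],
    presence: Mapping[str, Mapping[str, bool]],
) -> pd.DataFrame:
    """Tabulate per-group motif presence percentages.

    ``presence`` maps gene_id -> {motif name -> present}; genes without a
    scan record (no extractable promoter) are excluded from n_total.
    Returns a tidy frame (group, motif, n_present, n_total, percent); empty
    groups are omitted.
    """
    rows = []
    motif_names = sorted({m for per_gene in presence.values() for m in per_gene})
    for group, members in group_members.items():
        members = list(members)
        if not members:
            continue
        for motif in motif_names:
            scanned = [g for g in members if g in presence and motif in presence[g]]
            n_present = sum(1 for g in scanned if presence[g][motif])
            n_total = len(scanned)
            rows.append(
                {
                    "group": group,
                    "motif": motif,
                    "n_present": n_present,
                    "n_total": n_total,
                    "percent": 100.0 * n_present / n_total if n_total else float("nan"),
                }
            )
    return pd.DataFrame(rows)
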