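"""Reading/writing of genome FASTA, GFF3 annotation, and count tables,
plus strand-aware extraction of TSS-anchored windows and coding sequences.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open; GFF3 I/O converts from/to the
standard 1-based inclusive coordinates.  The TSS of a gene is the 5'-most base
of its *representative* transcript (the transcript whose identifier sorts
first lexicographically, matching the ".1" model convention of Phytozome-style
gene sets), and window positions are expressed relative to it: position 0 is
the TSS base itself, negative positions run upstream on the coding strand.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import ExclusionLog, reverse_complement

__all__ = [
    "GenomeFormatError",
    "AnnotationError",
    "GeneModel",
    "LibraryKey",
    "CountMatrix",
    "SequenceWindow",
    "read_genome",
    "read_annotation",
    "write_annotation",
    "extract_window",
    "extract_cds",
    "validate_cds",
    "read_counts",
    "write_counts",
]

_VALID_BASES = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, bad alphabet, ...)."""


class AnnotationError(ValueError):
    """Raised for structurally invalid GFF3 input."""


@dataclass(frozen=True)
class SequenceWindow:
    """A strand-oriented sequence window with boundary-truncation records.

    ``clip_start``/``clip_end`` count bases lost to sequence boundaries at
    the 5' and 3' ends of the *oriented* window.
    """

    seq: str
    truncated: bool
    clip_start: int = 0
    clip_end: int = 0

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


@dataclass
class GeneModel:
    """One gene locus with its transcripts, representative model and TSS.

    ``exons`` maps transcript id to its exon intervals and ``cds_segments``
    holds the representative transcript's CDS intervals; both are 0-based
    half-open genomic intervals ordered 5'->3' in transcript orientation
    (descending genomic start on the minus strand).
    """

    gene_id: str
    seq_id: str
    strand: str
    transcript_ids: list[str]
    representative_transcript: str
    tss: int
    exons: dict[str, list[tuple[int, int]]]
    cds_segments: list[tuple[int, int]]

    @property
    def n_variants(self) -> int:
        return len(self.transcript_ids)

    @property
    def rep_exons(self) -> list[tuple[int, int]]:
        return self.exons[self.representative_transcript]

    @property
    def gene_span(self) -> tuple[int, int]:
        """Outermost exon boundaries of the representative transcript."""
        ivs = self.rep_exons
        lo = min(s for s, _ in ivs)
        hi = max(e for _, e in ivs)
        return lo, hi


@dataclass(frozen=True, order=True)
class LibraryKey:
    cultivar: str  # "tolerant" | "sensitive"
    condition: str  # "control" | "stress"
    timepoint: float  # hours

    def __str__(self) -> str:
        tp = f"{self.timepoint:g}"
        return f"{self.cultivar}:{self.condition}:{tp}"

    @classmethod
    def parse(cls, key: str) -> "LibraryKey":
        try:
            cultivar, condition, tp = key.split(":")
            return cls(cultivar, condition, float(tp))
        except ValueError as exc:
            raise ValueError(f"malformed library key {key!r}") from exc


CULTIVARS = ("tolerant", "sensitive")
CONDITIONS = ("control", "stress")
TIMEPOINTS = (0.5, 4.0, 28.0)


@dataclass
class CountMatrix:
    """Raw read counts per gene per library plus library sizes.

    ``library_sizes`` are total mapped reads per library (the RPM
    denominator); they may exceed the annotated-gene column sums, since the
    annotated genes need not exhaust the mapped reads.
    """

    gene_ids: list[str]
    libraries: list[LibraryKey]
    counts: np.ndarray  # shape (n_genes, n_libraries), integer
    library_sizes: np.ndarray  # shape (n_libraries,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.libraries)):
            raise ValueError("counts shape does not match gene/library lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.all(np.equal(np.mod(self.counts, 1), 0)):
            raise ValueError("non-integral counts")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")

    def library_index(self, key: LibraryKey) -> int:
        return self.libraries.index(key)

    def column(self, key: LibraryKey) -> np.ndarray:
        return self.counts[:, self.library_index(key)]


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a multi-record FASTA into {seq_id: upper-case sequence}.

    Rejects duplicate ids, empty sequences, and any character outside
    A/C/G/T/N (other IUPAC ambiguity codes are not accepted; N is retained
    and treated downstream as matching no motif symbol).
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise GenomeFormatError(f"duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise GenomeFormatError(f"empty sequence for record {record.id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise GenomeFormatError(
                f"record {record.id!r} contains invalid character "
                f"{seq[pos]!r} at position {pos}"
            )
        genome[record.id] = seq
    if not genome:
        raise GenomeFormatError(f"no FASTA records found in {path}")
    return genome


_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attrs(field9: str) -> dict[str, str]:
    return {m.group(1).strip(): m.group(2).strip() for m in _ATTR_RE.finditer(field9)}


def read_annotation(
    path: str | Path,
    genome: Mapping[str, str],
    log: ExclusionLog | None = None,
) -> list[GeneModel]:
    """Parse a gene -> mRNA -> exon/CDS GFF3 hierarchy into GeneModels.

    Genes whose representative-transcript CDS length is not divisible by 3
    are excluded with a log record; dangling Parent attributes, CDS segments
    outside exons, and genes on sequences absent from the genome are hard
    errors.
    """
    log = log if log is not None else ExclusionLog()
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"line {lineno}: expected 9 columns")
            seq_id, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            if start0 < 0 or end0 <= start0:
                raise AnnotationError(f"line {lineno}: invalid coordinates")
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise AnnotationError(f"line {lineno}: gene without ID")
                if seq_id not in genome:
                    raise AnnotationError(
                        f"gene {gid!r} on sequence {seq_id!r} absent from genome"
                    )
                genes[gid] = {"seq_id": seq_id, "strand": strand, "transcripts": []}
                gene_order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = a.get("ID"), a.get("Parent")
                if tid is None or parent is None:
                    raise AnnotationError(f"line {lineno}: mRNA needs ID and Parent")
                if parent not in genes:
                    raise AnnotationError(
                        f"line {lineno}: dangling Parent {parent!r} for mRNA {tid!r}"
                    )
                transcripts[tid] = {
                    "gene": parent,
                    "strand": strand,
                    "seq_id": seq_id,
                    "exons": [],
                    "cds": [],
                }
                genes[parent]["transcripts"].append(tid)
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                if parent is None or parent not in transcripts:
                    raise AnnotationError(
                        f"line {lineno}: dangling Parent {parent!r} for {ftype}"
                    )
                key = "exons" if ftype == "exon" else "cds"
                transcripts[parent][key].append((start0, end0))
            # other feature types are ignored

    models: list[GeneModel] = []
    for gid in gene_order:
        g = genes[gid]
        if not g["transcripts"]:
            log.add("parse", gid, "no_transcripts")
            continue
        strand = g["strand"]
        minus = strand == "-"
        exons: dict[str, list[tuple[int, int]]] = {}
        for tid in g["transcripts"]:
            ivs = sorted(transcripts[tid]["exons"])
            _check_disjoint(ivs, gid, tid, "exon")
            exons[tid] = ivs[::-1] if minus else ivs
        rep = min(g["transcripts"])
        cds = sorted(transcripts[rep]["cds"])
        _check_disjoint(cds, gid, rep, "CDS")
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in sorted(exons[rep])):
                raise AnnotationError(
                    f"gene {gid!r}: CDS segment [{cs},{ce}) outside exons of {rep!r}"
                )
        cds_len = sum(e - s for s, e in cds)
        if cds and cds_len % 3 != 0:
            log.add("parse", gid, "cds_length_not_multiple_of_3")
            continue
        rep_exons = exons[rep]
        if not rep_exons:
            log.add("parse", gid, "representative_transcript_without_exons")
            continue
        tss = (
            max(e for _, e in rep_exons) - 1 if minus else min(s for s, _ in rep_exons)
        )
        models.append(
            GeneModel(
                gene_id=gid,
                seq_id=g["seq_id"],
                strand=strand,
                transcript_ids=list(g["transcripts"]),
                representative_transcript=rep,
                tss=tss,
                exons=exons,
                cds_segments=cds[::-1] if minus else cds,
            )
        )
    return models


def _check_disjoint(
    sorted_ivs: list[tuple[int, int]], gid: str, tid: str, kind: str
) -> None:
    for (s1, e1), (s2, _e2) in zip(sorted_ivs, sorted_ivs[1:]):
        if s2 < e1:
            raise AnnotationError(
                f"gene {gid!r}: overlapping {kind} intervals in transcript {tid!r}"
            )


def write_annotation(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels back to GFF3 (1-based inclusive) for round-tripping."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span_lo = min(s for ivs in m.exons.values() for s, _ in ivs)
            span_hi = max(e for ivs in m.exons.values() for _, e in ivs)
            fh.write(
                _gff_line(m.seq_id, "gene", span_lo, span_hi, m.strand, f"ID={m.gene_id}")
            )
            for tid in m.transcript_ids:
                ivs = sorted(m.exons[tid])
                fh.write(
                    _gff_line(
                        m.seq_id, "mRNA", ivs[0][0], ivs[-1][1], m.strand,
                        f"ID={tid};Parent={m.gene_id}",
                    )
                )
                for s, e in ivs:
                    fh.write(
                        _gff_line(m.seq_id, "exon", s, e, m.strand, f"Parent={tid}")
                    )
                if tid == m.representative_transcript:
                    for s, e in sorted(m.cds_segments):
                        fh.write(
                            _gff_line(m.seq_id, "CDS", s, e, m.strand, f"Parent={tid}")
                        )


def _gff_line(seq_id: str, ftype: str, s0: int, e0: int, strand: str, attrs: str) -> str:
    return f"{seq_id}\tgroupscan\t{ftype}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}\n"


def extract_window(
    gene: GeneModel,
    genome: Mapping[str, str],
    upstream: int,
    downstream: int,
) -> SequenceWindow:
    """Strand-oriented sequence covering TSS-relative positions
    [-upstream, +downstream), where position 0 is the TSS base.

    The window is truncated at sequence boundaries (flag set); a window
    entirely off-sequence yields an empty string.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be non-negative")
    chrom = genome[gene.seq_id]
    n = len(chrom)
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream + 1, gene.tss + upstream + 1
    clo, chi = max(lo, 0), min(hi, n)
    if clo >= chi:
        return SequenceWindow("", True, upstream + downstream, 0)
    seq = chrom[clo:chi]
    if gene.strand == "-":
        seq = reverse_complement(seq)
        clip_start, clip_end = hi - chi, clo - lo
    else:
        clip_start, clip_end = clo - lo, hi - chi
    return SequenceWindow(
        seq, truncated=(clo != lo or chi != hi),
        clip_start=clip_start, clip_end=clip_end,
    )


def extract_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenated representative-transcript CDS, 5'->3' (reverse-complemented
    on the minus strand).  The terminal stop codon, when present, is retained
    here; downstream codon statistics strip it."""
    chrom = genome[gene.seq_id]
    parts = []
    for s, e in gene.cds_segments:
        seg = chrom[s:e]
        if gene.strand == "-":
            seg = reverse_complement(seg)
        parts.append(seg)
    return "".join(parts)


def validate_cds(cds: str) -> list[str]:
    """Reason codes making a CDS ineligible for codon/composition analyses."""
    reasons = []
    if len(cds) == 0:
        reasons.append("empty_cds")
        return reasons
    if len(cds) % 3 != 0:
        reasons.append("length_not_multiple_of_3")
        return reasons
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        reasons.append("internal_stop_codon")
    return reasons


def strip_stop(cds: str) -> str:
    """Drop a terminal stop codon if present (no-op otherwise)."""
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def read_counts(
    counts_path: str | Path, sizes_path: str | Path
) -> CountMatrix:
    """Read the counts TSV (first column gene_id, header of library keys
    "cultivar:condition:timepoint") and the library-sizes TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    libraries = [LibraryKey.parse(c) for c in df.columns]
    sizes_df = pd.read_csv(sizes_path, sep="\t", index_col=0, header=None)
    sizes = np.array([float(sizes_df.loc[str(k)].iloc[0]) for k in libraries])
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        libraries=libraries,
        counts=df.to_numpy(),
        library_sizes=sizes,
    )


def write_counts(cm: CountMatrix, counts_path: str | Path, sizes_path: str | Path) -> None:
    df = pd.DataFrame(
        cm.counts, index=pd.Index(cm.gene_ids, name="gene_id"),
        columns=[str(k) for k in cm.libraries],
    )
    df.to_csv(counts_path, sep="\t")
    buf = io.StringIO()
    for k, s in zip(cm.libraries, cm.library_sizes):
        buf.write(f"{k}\t{s:g}\n")
    Path(sizes_path).write_text(buf.getvalue())
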