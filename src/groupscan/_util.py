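"""Small shared helpers: reverse complement, exclusion logging."""

from __future__ import annotations

from dataclasses import dataclass, field

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ExclusionRecord:
    stage: str
    gene_id: str
    reason: str


@dataclass
class ExclusionLog:
    """Structured per-gene exclusion records (reason codes, not free text).

    Every stage that drops a gene appends a record here so per-analysis
    sample sizes can be reconstructed afterwards.
    """

    records: list[ExclusionRecord] = field(default_factory=list)

    def add(self, stage: str, gene_id: str, reason: str) -> None:
        self.records.append(ExclusionRecord(stage, gene_id, reason))

    def for_stage(self, stage: str) -> list[ExclusionRecord]:
        return [r for r in self.records if r.stage == stage]

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self) -> list[dict]:
        return [
            {"stage": r.stage, "gene_id": r.gene_id, "reason": r.reason}
            for r in self.records
        ]
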