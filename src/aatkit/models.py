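"""Shared gene-model container used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    Coordinates are 0-based half-open on the chromosome; ``exons`` are sorted,
    non-overlapping genomic intervals. For minus-strand genes the CDS is the
    reverse complement of the concatenated exon sequence (standard GFF3
    semantics: exons stored in ascending genomic order, transcription runs
    right to left).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # '+' | '-'
    exons: tuple[tuple[int, int], ...]
    cds: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end: int | None = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def extract_cds(self, chromosome_sequence: str) -> str:
        parts = [chromosome_sequence[s:e] for s, e in self.exons]
        joined = "".join(parts)
        return joined if self.strand == "+" else reverse_complement(joined)
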