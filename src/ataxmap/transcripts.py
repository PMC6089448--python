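"""Minimal transcript models and coding-coordinate arithmetic.

A transcript is an ordered set of exons on one strand with a CDS span.
For reverse-strand transcripts all coding arithmetic happens in
transcription sense: exon order reversed, bases complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import InputDataError, ModelError
from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSlice:
    """A window of genome sequence anchored at an absolute 1-based position."""

    chrom: str
    start: int  # 1-based position of seq[0]
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise InputDataError(
                f"position {self.chrom}:{pos} outside genome slice "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        return self.seq[pos - self.start].upper()

    def fetch(self, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive span [start, end]."""
        if start > end:
            raise InputDataError("fetch start exceeds end")
        if not (self.start <= start and end <= self.end):
            raise InputDataError(
                f"span {self.chrom}:{start}-{end} outside genome slice"
            )
        return self.seq[start - self.start : end - self.start + 1].upper()


@dataclass
class TranscriptModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[GenomicInterval]  # ordered by genomic position, non-overlapping
    cds_start: int  # genomic, 1-based inclusive
    cds_end: int
    frame_offset: int = 0
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.transcript_id:
            self.transcript_id = f"{self.gene_id}.t1"
        prev_end = 0
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ModelError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start <= prev_end:
                raise ModelError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = ex.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription order."""
        pos: list[int] = []
        for ex in self.exons:
            lo = max(ex.start, self.cds_start)
            hi = min(ex.end, self.cds_end)
            if lo <= hi:
                pos.extend(range(lo, hi + 1))
        if not pos:
            raise ModelError(f"{self.gene_id}: CDS does not intersect any exon")
        if self.strand == "-":
            pos.reverse()
        pos = pos[self.frame_offset :]
        if len(pos) % 3 != 0:
            raise ModelError(
                f"{self.gene_id}: CDS length {len(pos)} not divisible by 3 "
                f"after frame offset {self.frame_offset}"
            )
        return pos

    def coding_sequence(self, genome: GenomeSlice) -> str:
        """CDS in transcription sense (reverse-strand bases complemented)."""
        bases = [genome.base(p) for p in self.cds_genomic_positions()]
        seq = "".join(bases)
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)
        return seq

    def protein(self, genome: GenomeSlice) -> str:
        return str(Seq(self.coding_sequence(genome)).translate())

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        return list(reversed(self.exons)) if self.strand == "-" else list(self.exons)

    def exon_index_of(self, pos: int) -> int | None:
        """1-based exon number in transcription order containing pos, else None."""
        for i, ex in enumerate(self.exons_in_transcription_order(), start=1):
            if ex.start <= pos <= ex.end:
                return i
        return None
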