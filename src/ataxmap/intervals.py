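"""1-based inclusive genomic intervals.

All coordinates in this package are 1-based inclusive (VCF-native).
BED (0-based half-open) exists only at export boundaries; see
:meth:`GenomicInterval.to_bed` and :meth:`GenomicInterval.from_bed`.

The reported length is ``end - start`` (not ``end - start + 1``): the
convention under which printed marker-bounded interval bounds subtract
to a round kb figure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InputDataError

_INTERVAL_RE = re.compile(r"^([^:]+):([\d,_ ]+)-([\d,_ ]+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InputDataError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise InputDataError(
                f"interval start {self.start} exceeds end {self.end} on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def to_bed(self) -> tuple[str, int, int]:
        """Convert to BED convention: 0-based half-open (start-1, end)."""
        return (self.chrom, self.start - 1, self.end)

    @classmethod
    def from_bed(cls, chrom: str, bed_start: int, bed_end: int) -> "GenomicInterval":
        return cls(chrom, bed_start + 1, bed_end)

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (1-based inclusive); separators in digits allowed."""
        m = _INTERVAL_RE.match(text.strip())
        if not m:
            raise InputDataError(f"cannot parse interval {text!r}; expected chrom:start-end")
        clean = lambda s: int(re.sub(r"[,_ ]", "", s))  # noqa: E731
        return cls(m.group(1), clean(m.group(2)), clean(m.group(3)))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"
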