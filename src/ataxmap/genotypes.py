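"""Sample-by-marker genotype matrices with per-marker genomic positions.

Genotype codes count copies of the alternate allele: 0, 1, 2; missing
calls are stored as -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputDataError, SampleLookupError

MISSING = -1


@dataclass
class MarkerMap:
    """Ordered marker metadata: ids, chromosome labels and bp positions.

    Positions must be strictly increasing within each chromosome and
    chromosomes must form contiguous blocks.
    """

    ids: list[str]
    chroms: np.ndarray   # dtype object/str, one per marker
    positions: np.ndarray  # int64, 1-based bp

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = len(self.ids)
        if self.chroms.shape != (n,) or self.positions.shape != (n,):
            raise InputDataError("marker map fields have inconsistent lengths")
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for c, p in zip(self.chroms, self.positions):
            if c != prev_chrom:
                if c in seen:
                    raise InputDataError(f"markers for chromosome {c} are not contiguous")
                seen.add(c)
                prev_chrom, prev_pos = c, -1
            if p <= prev_pos:
                raise InputDataError(
                    f"marker positions not strictly increasing on {c} at {p}"
                )
            prev_pos = p

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chroms:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            raise InputDataError(f"no markers on chromosome {chrom}")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class GenotypeMatrix:
    """Samples x markers alternate-allele dosage matrix."""

    samples: list[str]
    markers: MarkerMap
    codes: np.ndarray = field(repr=False)  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.markers)):
            raise InputDataError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputDataError(
                f"invalid genotype code {self.codes[i, j]} for sample "
                f"{self.samples[i]} marker {self.markers.ids[j]}"
            )
        self._index = {s: i for i, s in enumerate(self.samples)}
        if len(self._index) != len(self.samples):
            raise InputDataError("duplicate sample ids in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self._index[sample]
        except KeyError:
            raise SampleLookupError(f"unknown sample id {sample!r}") from None

    def row(self, sample: str) -> np.ndarray:
        return self.codes[self.sample_index(sample)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.markers, self.codes[rows].copy())
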