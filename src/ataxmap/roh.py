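"""Runs of homozygosity and shared-homozygosity interval mapping.

A run is a maximal stretch of consecutive markers on one chromosome in
which an individual shows at most ``max_het_calls`` heterozygous and at
most ``max_missing_calls`` missing calls. Case-shared intervals are
regions covered by a qualifying run in at least ``min_case_fraction`` of
the cases, optionally requiring all supporting cases to be homozygous
for the same allele at every informative marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .genotypes import MISSING, GenotypeMatrix
from .intervals import GenomicInterval


@dataclass(frozen=True)
class RohParams:
    # Defaults sized for a ~50k genome-wide SNP array (one marker per
    # tens of kb): tolerate a single miscalled het and a couple of
    # missing calls per segment.
    min_markers: int = 20
    min_length_bp: int = 500_000
    max_het_calls: int = 1
    max_missing_calls: int = 2

    def __post_init__(self) -> None:
        if self.min_markers < 1:
            raise ConfigurationError("min_markers must be >= 1")
        if self.min_length_bp < 0:
            raise ConfigurationError("min_length_bp must be >= 0")
        if self.max_het_calls < 0 or self.max_missing_calls < 0:
            raise ConfigurationError("max_het_calls/max_missing_calls must be >= 0")


@dataclass
class RohSegment:
    sample: str
    interval: GenomicInterval
    n_markers: int
    n_het_used: int
    n_missing_used: int
    marker_start: int  # index into the full marker map
    marker_end: int    # inclusive
    homozygous_codes: np.ndarray = field(repr=False)  # per-marker codes in the run


def _maximal_runs(het: np.ndarray, miss: np.ndarray, max_het: int, max_miss: int):
    """All maximal windows [i, j] with at most max_het hets and max_miss missing.

    Two-pointer sweep: for each left edge the right edge is pushed as far
    as feasible; a window is maximal iff its right edge advanced past the
    previous window's.
    """
    n = het.size
    out = []
    j = 0
    h = m = 0
    prev_j = -1
    for i in range(n):
        if j < i:
            j, h, m = i, 0, 0
        while j < n:
            nh = h + int(het[j])
            nm = m + int(miss[j])
            if nh > max_het or nm > max_miss:
                break
            h, m = nh, nm
            j += 1
        if j > i and j - 1 > prev_j:
            out.append((i, j - 1, h, m))
            prev_j = j - 1
        if j > i:
            h -= int(het[i])
            m -= int(miss[i])
    return out


def detect_roh(
    genotypes: GenotypeMatrix, sample: str, params: RohParams | None = None
) -> list[RohSegment]:
    """Detect runs of homozygosity for one sample, per chromosome."""
    params = params or RohParams()
    codes = genotypes.row(sample)
    segments: list[RohSegment] = []
    for chrom in genotypes.markers.chromosomes:
        sl = genotypes.markers.chrom_slice(chrom)
        c = codes[sl]
        pos = genotypes.markers.positions[sl]
        het = c == 1
        miss = c == MISSING
        for i, j, h, m in _maximal_runs(het, miss, params.max_het_calls, params.max_missing_calls):
            n_markers = j - i + 1
            length = int(pos[j] - pos[i])
            if n_markers < params.min_markers or length < params.min_length_bp:
                continue
            segments.append(
                RohSegment(
                    sample=sample,
                    interval=GenomicInterval(chrom, int(pos[i]), int(pos[j])),
                    n_markers=n_markers,
                    n_het_used=h,
                    n_missing_used=m,
                    marker_start=sl.start + i,
                    marker_end=sl.start + j,
                    homozygous_codes=c[i : j + 1].copy(),
                )
            )
    return segments


@dataclass(frozen=True)
class SharedIntervalParams:
    min_case_fraction: float = 0.85
    require_shared_allele: bool = True
    # Bridge per-case coverage gaps up to this many markers before
    # computing cross-case support: isolated error clusters split a
    # genuine autozygous run but should not break interval sharing.
    fill_gap_markers: int = 5
    roh: RohParams = field(default_factory=RohParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.min_case_fraction <= 1.0:
            raise ConfigurationError("min_case_fraction must be in (0, 1]")
        if self.fill_gap_markers < 0:
            raise ConfigurationError("fill_gap_markers must be >= 0")


@dataclass
class SharedInterval:
    interval: GenomicInterval
    supporting_cases: list[str]
    discordant_cases: list[str]
    shared_allele_consistent: bool
    n_markers: int


@dataclass
class SharedIntervalResult:
    intervals: list[SharedInterval]
    diagnostics: str = ""

    @property
    def top(self) -> SharedInterval | None:
        return self.intervals[0] if self.intervals else None


def map_shared_interval(
    genotypes: GenotypeMatrix,
    case_ids: list[str],
    params: SharedIntervalParams | None = None,
) -> SharedIntervalResult:
    """Find genomic intervals shared as same-allele homozygous runs across cases.

    Returns intervals ranked by supporting-case count, then marker count,
    then bp length. An empty result (with a diagnostic message) is
    returned when no region satisfies the criterion; this is not an
    error.
    """
    params = params or SharedIntervalParams()
    if len(case_ids) < 2:
        raise ConfigurationError("map_shared_interval requires at least two cases")
    n_cases = len(case_ids)
    k_required = int(np.ceil(params.min_case_fraction * n_cases))

    segments = {s: detect_roh(genotypes, s, params.roh) for s in case_ids}
    n_markers_total = genotypes.n_markers
    coverage = np.zeros((n_cases, n_markers_total), dtype=bool)
    for ci, s in enumerate(case_ids):
        for seg in segments[s]:
            coverage[ci, seg.marker_start : seg.marker_end + 1] = True
    if params.fill_gap_markers > 0:
        for chrom in genotypes.markers.chromosomes:
            sl = genotypes.markers.chrom_slice(chrom)
            for ci in range(n_cases):
                row = coverage[ci, sl]
                covered = np.flatnonzero(row)
                if covered.size < 2:
                    continue
                gaps = np.diff(covered)
                for gi in np.flatnonzero((gaps > 1) & (gaps <= params.fill_gap_markers + 1)):
                    row[covered[gi] : covered[gi + 1]] = True

    found: list[SharedInterval] = []
    support_count = coverage.sum(axis=0)
    case_rows = np.array([genotypes.sample_index(c) for c in case_ids])

    def coverage_run(ci: int, peak: int, lo_bound: int, hi_bound: int) -> tuple[int, int]:
        """Contiguous covered marker run of one case around ``peak``."""
        row = coverage[ci]
        lo = peak
        while lo > lo_bound and row[lo - 1]:
            lo -= 1
        hi = peak
        while hi < hi_bound and row[hi + 1]:
            hi += 1
        return lo, hi

    def widest_supported_run(covering: list[int], runs: dict[int, tuple[int, int]]):
        """Widest marker run fully covered by >= k_required of the cases.

        Exact scan: for each candidate left edge A (a case's run start),
        take among cases starting at or before A the k-th largest run
        end; maximize width. All runs contain the peak, so the result
        does too.
        """
        best = None
        for A in sorted({runs[ci][0] for ci in covering}):
            ends = sorted(
                (runs[ci][1] for ci in covering if runs[ci][0] <= A), reverse=True
            )
            if len(ends) < k_required:
                continue
            B = ends[k_required - 1]
            if B >= A and (best is None or B - A > best[1] - best[0]):
                best = (A, B)
        return best

    for chrom in genotypes.markers.chromosomes:
        sl = genotypes.markers.chrom_slice(chrom)
        ok = support_count[sl] >= k_required
        if not ok.any():
            continue
        # maximal runs of markers meeting the support threshold
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(starts, ends):
            m0, m1 = sl.start + idx[a], sl.start + idx[b]
            # peak: centre of the longest plateau of maximal support (an
            # edge marker would sit next to unshared sequence)
            region_support = support_count[m0 : m1 + 1]
            mx = region_support.max()
            at_max = np.flatnonzero(region_support == mx)
            splits = np.flatnonzero(np.diff(at_max) > 1)
            seg_starts = np.concatenate(([0], splits + 1))
            seg_ends = np.concatenate((splits, [at_max.size - 1]))
            widths = seg_ends - seg_starts
            w = int(np.argmax(widths))
            peak = m0 + int(at_max[(seg_starts[w] + seg_ends[w]) // 2])
            covering = [ci for ci in range(n_cases) if coverage[ci, peak]]
            # clip each case's run to the support region: beyond it, runs
            # extend into sequence not shared across cases
            runs = {ci: coverage_run(ci, peak, m0, m1) for ci in covering}

            if params.require_shared_allele:
                # the shared haplotype's allele at each marker: majority of
                # homozygous calls among covering cases; each case's run is
                # truncated at its nearest informative mismatch, so every
                # surviving run is same-allele consistent by construction
                codes_r = genotypes.codes[case_rows][:, m0 : m1 + 1]
                cov_r = coverage[:, m0 : m1 + 1]
                hom0 = ((codes_r == 0) & cov_r).sum(axis=0)
                hom2 = ((codes_r == 2) & cov_r).sum(axis=0)
                majority = np.where(hom2 >= hom0, 2, 0)
                informative = (codes_r == 0) | (codes_r == 2)
                mismatch = cov_r & informative & (codes_r != majority[None, :])
                truncated: dict[int, tuple[int, int]] = {}
                for ci in covering:
                    mm_rel = np.flatnonzero(mismatch[ci])
                    lo_ci, hi_ci = runs[ci]
                    p_rel = peak - m0
                    left = mm_rel[mm_rel < p_rel]
                    right = mm_rel[mm_rel > p_rel]
                    if mismatch[ci, p_rel]:
                        continue  # case contradicts the shared allele at the peak
                    if left.size:
                        lo_ci = max(lo_ci, m0 + int(left.max()) + 1)
                    if right.size:
                        hi_ci = min(hi_ci, m0 + int(right.min()) - 1)
                    truncated[ci] = (lo_ci, hi_ci)
                covering = list(truncated)
                runs = truncated

            run = widest_supported_run(covering, runs)
            if run is None:
                continue
            lo, hi = run
            supporting = [ci for ci in covering if runs[ci][0] <= lo and runs[ci][1] >= hi]
            consistent = bool(params.require_shared_allele)
            if len(supporting) < k_required or lo > hi:
                continue
            supp_ids = [case_ids[ci] for ci in supporting]
            disc_ids = [c for c in case_ids if c not in supp_ids]
            pos = genotypes.markers.positions
            found.append(
                SharedInterval(
                    interval=GenomicInterval(chrom, int(pos[lo]), int(pos[hi])),
                    supporting_cases=supp_ids,
                    discordant_cases=disc_ids,
                    shared_allele_consistent=consistent,
                    n_markers=hi - lo + 1,
                )
            )
    # rank by supported marker mass (supporting cases x markers), breaking
    # ties by support then length: robust when an adjacent region is
    # coincidentally covered by one extra case over a short stretch
    found.sort(
        key=lambda si: (
            -len(si.supporting_cases) * si.n_markers,
            -len(si.supporting_cases),
            -si.interval.length_bp,
        )
    )
    if not found:
        return SharedIntervalResult(
            intervals=[],
            diagnostics=(
                f"no interval supported by >= {k_required}/{n_cases} cases "
                f"(min_case_fraction={params.min_case_fraction})"
            ),
        )
    return SharedIntervalResult(intervals=found)
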