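"""Gene-dropping down a pedigree on a genetic map, with a planted
recessive disease haplotype.

Founder chromosomes get unique identity-by-descent labels; a designated
founder carries the disease allele on one chromosome copy. Transmission
to each offspring recombines the parent's two haplotypes as a Poisson
crossover process on the genetic map. Alternate-homozygotes at the
causal locus are therefore homozygous by descent for the planted
haplotype across the surrounding interval, shortened only by
recombination. A symmetric allele-miscall and missingness layer is
applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, InputDataError
from ..genotypes import MISSING, GenotypeMatrix, MarkerMap
from ..intervals import GenomicInterval
from ..pedigree import Pedigree
from .config import SimConfig

CAUSAL_INTERVAL_HALF_WIDTH = 340_500  # default planted interval span: 681 kb


@dataclass
class SimTruth:
    """Ground-truth ledger for one simulated cohort."""

    causal_chrom: str
    causal_interval: GenomicInterval
    causal_variant_position: int
    carrier_status: dict[str, str]          # animal -> GG | AG | AA
    case_ids: list[str]
    phenocopy_ids: list[str]
    aa_case_ids: list[str]
    planted_haplotype_label: int
    founder_freqs: np.ndarray = field(repr=False, default=None)
    clean_codes: np.ndarray = field(repr=False, default=None)  # pre-error genotypes
    ibd_labels: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    seed: int | None = None
    # filled by downstream simulators
    background_counts: dict[str, int] = field(default_factory=dict)
    true_sigma_a2: float | None = None
    true_sigma_e2: float | None = None
    true_contrasts: dict[str, float] = field(default_factory=dict)
    paranodal_groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.causal_interval.contains(self.causal_chrom, self.causal_variant_position):
            raise ConfigurationError(
                "causal_variant_position must lie inside causal_interval"
            )


def make_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced markers on chr1..chrN (a stand-in for an SNP array)."""
    ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    spacing = config.chromosome_length_bp // (config.markers_per_chromosome + 1)
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for m in range(config.markers_per_chromosome):
            ids.append(f"{chrom}_m{m:05d}")
            chroms.append(chrom)
            positions.append((m + 1) * spacing)
    return MarkerMap(
        ids=ids, chroms=np.array(chroms, dtype=object), positions=np.array(positions)
    )


def _gamete(
    hap_pair: np.ndarray, cm: np.ndarray, length_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """One recombined gamete from a (2, n_loci) haplotype pair."""
    n_cross = rng.poisson(length_cm / 100.0)
    phase = int(rng.integers(2))
    if n_cross == 0:
        return hap_pair[phase].copy()
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_cross))
    active = (phase + np.searchsorted(cuts, cm, side="right")) % 2
    return np.where(active == 0, hap_pair[0], hap_pair[1])


def drop_transmissions(
    pedigree: Pedigree,
    loci_cm: dict[str, np.ndarray],
    chrom_lengths_cm: dict[str, float],
    founder_haps: dict[str, dict[str, np.ndarray]],
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Drop founder haplotypes down the pedigree.

    ``founder_haps[chrom][founder]`` is a (2, n_loci) array (any integer
    dtype: alleles, IBD labels, or both packed). Returns the same
    structure covering every animal; each non-founder receives one
    recombined gamete per parent.
    """
    out: dict[str, dict[str, np.ndarray]] = {c: dict(founder_haps[c]) for c in loci_cm}
    for animal in pedigree.topological_order():
        sire, dam = pedigree.parents(animal)
        if sire is None and dam is None:
            for c in loci_cm:
                if animal not in out[c]:
                    raise InputDataError(f"founder {animal} has no assigned haplotypes")
            continue
        for c, cm in loci_cm.items():
            length = chrom_lengths_cm[c]
            g_s = _gamete(out[c][sire], cm, length, rng)
            g_d = _gamete(out[c][dam], cm, length, rng)
            out[c][animal] = np.stack([g_s, g_d])
    return out


def _apply_error_layer(
    codes: np.ndarray, error_rate: float, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric per-allele miscall at ``error_rate`` plus missingness."""
    noisy = codes.copy()
    if error_rate > 0:
        a = (codes >= 1).astype(np.int8)
        b = (codes == 2).astype(np.int8)
        f1 = rng.random(codes.shape) < error_rate
        f2 = rng.random(codes.shape) < error_rate
        noisy = ((a ^ f1) + (b ^ f2)).astype(np.int8)
    if missing_rate > 0:
        noisy[rng.random(codes.shape) < missing_rate] = MISSING
    return noisy


def drop_causal_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Single-locus Mendelian drop: founder alleles at the configured
    disease-allele frequency, one random allele inherited per parent.

    A light-weight companion to :func:`gene_drop` for phenotype/association
    simulations that need genotype classes but no marker data.
    """
    rng = rng or np.random.default_rng(config.seed)
    alleles: dict[str, np.ndarray] = {}
    for animal in pedigree.topological_order():
        sire, dam = pedigree.parents(animal)
        pair = np.empty(2, dtype=np.int8)
        for k, parent in enumerate((sire, dam)):
            if parent is None:
                pair[k] = rng.random() < config.disease_allele_freq
            else:
                pair[k] = alleles[parent][rng.integers(2)]
        alleles[animal] = pair
    return {a: {0: "GG", 1: "AG", 2: "AA"}[int(p.sum())] for a, p in alleles.items()}


def gene_drop(
    pedigree: Pedigree,
    marker_map: MarkerMap,
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate array genotypes and causal-locus descent for a pedigree.

    The disease haplotype is planted on one chromosome copy of the focal
    founder (the first founder unless ``config.linebreeding_founder``
    names another). When a drop yields fewer alternate homozygotes in
    the terminal cohort than the configured case count requires, the
    whole drop is redrawn (up to ``config.min_aa_attempts`` times) —
    conditioning on ascertainment of a disease cohort, never on
    individual transmissions, so Mendelian consistency holds within the
    accepted drop.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_needed = config.n_cases - config.n_phenocopies

    chroms = marker_map.chromosomes
    causal_chrom = chroms[min(config.causal_chrom_index, len(chroms) - 1)]
    causal_pos = int(config.chromosome_length_bp * config.causal_fraction_along)

    founders = pedigree.founders()
    disease_founder = config.linebreeding_founder or founders[0]
    if disease_founder not in founders:
        raise ConfigurationError(
            f"linebreeding_founder: {disease_founder!r} is not a founder"
        )

    # loci per chromosome: marker positions plus (off-grid) causal locus
    loci_bp: dict[str, np.ndarray] = {}
    causal_slot = -1
    for c in chroms:
        sl = marker_map.chrom_slice(c)
        pos = marker_map.positions[sl].astype(np.int64)
        if c == causal_chrom:
            if causal_pos in pos:
                causal_pos += 1
            causal_slot = int(np.searchsorted(pos, causal_pos))
            pos = np.insert(pos, causal_slot, causal_pos)
        loci_bp[c] = pos
    loci_cm = {c: p * (config.cm_per_mb / 1e6) for c, p in loci_bp.items()}
    lengths_cm = {c: config.chromosome_length_bp * config.cm_per_mb / 1e6 for c in chroms}

    lo, hi = config.allele_freq_range
    freqs = {c: rng.uniform(lo, hi, size=loci_bp[c].size) for c in chroms}
    founder_freqs = np.concatenate(
        [np.delete(freqs[c], causal_slot) if c == causal_chrom else freqs[c] for c in chroms]
    )

    hap_label = {f: (2 * i, 2 * i + 1) for i, f in enumerate(founders)}
    planted_label = hap_label[disease_founder][0]

    def packed_founder_haps(local_rng: np.random.Generator):
        """Alleles and IBD labels packed into one int32 per locus copy."""
        packed: dict[str, dict[str, np.ndarray]] = {c: {} for c in chroms}
        for f in founders:
            for c in chroms:
                alleles = (local_rng.random((2, loci_bp[c].size)) < freqs[c]).astype(np.int32)
                if c == causal_chrom:
                    alleles[:, causal_slot] = 0
                    if f == disease_founder:
                        alleles[0, causal_slot] = 1
                labels = np.empty((2, loci_bp[c].size), dtype=np.int32)
                labels[0], labels[1] = hap_label[f]
                packed[c][f] = (alleles << 16) | labels
        return packed

    ids = pedigree.ids()
    terminal_cohort = max(e.birth_cohort for e in pedigree)
    cohort_ids = [e.animal_id for e in pedigree if e.birth_cohort == terminal_cohort]

    attempts = max(1, config.min_aa_attempts)
    for attempt in range(attempts):
        dropped = drop_transmissions(
            pedigree, loci_cm, lengths_cm, packed_founder_haps(rng), rng
        )
        alleles = {c: {a: (dropped[c][a] >> 16).astype(np.int8) for a in ids} for c in chroms}
        causal_geno = {
            a: int(alleles[causal_chrom][a][:, causal_slot].sum()) for a in ids
        }
        n_aa_cohort = sum(1 for a in cohort_ids if causal_geno[a] == 2)
        if n_aa_cohort >= n_needed:
            break
    labels = {
        causal_chrom: np.stack(
            [(dropped[causal_chrom][a] & 0xFFFF).astype(np.int16) for a in ids]
        )
    }
    status = {a: {0: "GG", 1: "AG", 2: "AA"}[causal_geno[a]] for a in ids}

    # genotype matrix over array markers (causal slot excluded)
    clean = np.empty((len(ids), len(marker_map)), dtype=np.int8)
    col = 0
    for c in chroms:
        n_loci = loci_bp[c].size
        block = np.empty((len(ids), n_loci), dtype=np.int8)
        for i, a in enumerate(ids):
            block[i] = alleles[c][a].sum(axis=0)
        if c == causal_chrom:
            block = np.delete(block, causal_slot, axis=1)
            n_loci -= 1
        clean[:, col : col + n_loci] = block
        col += n_loci

    noisy = _apply_error_layer(clean, config.genotype_error_rate, config.missing_rate, rng)
    genotypes = GenotypeMatrix(samples=list(ids), markers=marker_map, codes=noisy)

    aa_pool = [a for a in cohort_ids if causal_geno[a] == 2]
    non_aa_pool = [a for a in cohort_ids if causal_geno[a] != 2]
    n_aa_cases = min(len(aa_pool), config.n_cases - config.n_phenocopies)
    aa_cases = [str(a) for a in rng.choice(aa_pool, size=n_aa_cases, replace=False)] if n_aa_cases else []
    n_pc = min(config.n_phenocopies, len(non_aa_pool))
    phenocopies = [str(a) for a in rng.choice(non_aa_pool, size=n_pc, replace=False)] if n_pc else []
    case_ids = aa_cases + phenocopies

    interval_start = max(1, causal_pos - CAUSAL_INTERVAL_HALF_WIDTH)
    interval_end = min(config.chromosome_length_bp, causal_pos + CAUSAL_INTERVAL_HALF_WIDTH)

    truth = SimTruth(
        causal_chrom=causal_chrom,
        causal_interval=GenomicInterval(causal_chrom, interval_start, interval_end),
        causal_variant_position=causal_pos,
        carrier_status=status,
        case_ids=case_ids,
        phenocopy_ids=phenocopies,
        aa_case_ids=aa_cases,
        planted_haplotype_label=planted_label,
        founder_freqs=founder_freqs,
        clean_codes=clean,
        ibd_labels=labels,
        seed=config.seed,
    )
    return genotypes, truth
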