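"""Variant-table simulation for a sequenced case/control trio, plus a
packaged toy transcript.

The toy transcript is a six-exon reverse-strand gene whose coding
sequence places an arginine codon (CGA) so that the codon's middle base
is the last nucleotide of exon 5; the planted causal substitution is
G>A in transcription sense (C/T on the forward genome strand), i.e. a
simultaneous missense and donor-site change. Background variants each
violate exactly one (first-failing) cascade criterion, with counts
recorded in the truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InputDataError
from ..filtering import VariantRecord, annotate_consequence
from ..intervals import GenomicInterval
from ..transcripts import GenomeSlice, TranscriptModel, revcomp
from .config import SimConfig
from .genedrop import SimTruth

# deterministic non-stop codon pool for filler positions
_FILLER_CODONS = ["GCT", "GAA", "CTG", "AAA", "GGC", "TCT", "GAT", "CCA", "GTT", "ATC"]

EXON_CDS_LENGTHS = (120, 120, 120, 120, 128, 25)  # sums to 633 = 211 codons
CAUSAL_CDS_POSITION = 608  # middle base of codon 203, last base of exon 5
INTRON_LEN = 200


@dataclass
class ToyGene:
    transcript: TranscriptModel
    genome: GenomeSlice
    causal_chrom: str
    causal_pos: int           # genomic, 1-based
    causal_ref: str           # forward-strand alleles (C/T)
    causal_alt: str
    cds_to_genomic: dict[int, int] = field(repr=False, default_factory=dict)


def _build_coding_sequence() -> str:
    n_codons = sum(EXON_CDS_LENGTHS) // 3
    codons = [_FILLER_CODONS[i % len(_FILLER_CODONS)] for i in range(n_codons)]
    codons[0] = "ATG"
    codons[201] = "ACC"   # Thr202; its third base is the -3 donor position
    codons[202] = "CGA"   # Arg203; middle base = exon 5's last nucleotide
    codons[-1] = "TAA"
    return "".join(codons)


def _intron(rng: np.random.Generator) -> str:
    filler = "".join(rng.choice(list("ACGT"), size=INTRON_LEN - 8))
    return "GTAAGT" + filler + "AG"


def make_toy_transcript(
    chrom: str = "chr19",
    causal_genomic_pos: int = 27_041_449,
    seed: int = 0,
    flank: int = 60,
) -> ToyGene:
    """Build the packaged reverse-strand toy transcript and its genome slice."""
    rng = np.random.default_rng(seed)
    cds = _build_coding_sequence()
    assert cds[CAUSAL_CDS_POSITION - 1] == "G"

    exon_seqs = []
    off = 0
    for n in EXON_CDS_LENGTHS:
        exon_seqs.append(cds[off : off + n])
        off += n
    introns = [_intron(rng) for _ in range(len(exon_seqs) - 1)]

    # transcript-with-introns in transcription sense
    parts = []
    exon_t_ranges = []  # 1-based [a, b] in T coordinates, transcription order
    t = 0
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        exon_t_ranges.append((t + 1, t + len(ex)))
        t += len(ex)
        if i < len(introns):
            parts.append(introns[i])
            t += len(introns[i])
    big = "".join(parts)
    length = len(big)

    # genome: reverse strand, so the slice holds revcomp(T) with flanks
    flank_l = "".join(rng.choice(list("ACGT"), size=flank))
    flank_r = "".join(rng.choice(list("ACGT"), size=flank))
    seq = flank_l + revcomp(big) + flank_r

    # T coordinate of the causal base (CDS 608, exon 5, 4 introns upstream)
    t_causal = CAUSAL_CDS_POSITION + 4 * INTRON_LEN
    # genomic position of T coordinate t: g(t) = S + flank + (L - t)
    start = causal_genomic_pos - flank - (length - t_causal)
    if start < 1:
        raise InputDataError("causal_genomic_pos too small for the toy gene span")

    def g(t_coord: int) -> int:
        return start + flank + (length - t_coord)

    exons_genomic = sorted(
        GenomicInterval(chrom, g(b), g(a)) for a, b in exon_t_ranges
    )
    transcript = TranscriptModel(
        gene_id="toygene",
        chrom=chrom,
        strand="-",
        exons=exons_genomic,
        cds_start=exons_genomic[0].start,
        cds_end=exons_genomic[-1].end,
    )
    genome = GenomeSlice(chrom=chrom, start=start, seq=seq)

    cds_map = {i + 1: p for i, p in enumerate(transcript.cds_genomic_positions())}
    gene = ToyGene(
        transcript=transcript,
        genome=genome,
        causal_chrom=chrom,
        causal_pos=causal_genomic_pos,
        causal_ref=genome.base(causal_genomic_pos),
        causal_alt=revcomp("A"),  # G>A in transcript sense -> C>T forward
        cds_to_genomic=cds_map,
    )
    assert gene.causal_ref == "C" and gene.causal_alt == "T"
    assert cds_map[CAUSAL_CDS_POSITION] == causal_genomic_pos
    return gene


def synonymous_snvs(
    gene: ToyGene, *, min_boundary_distance: int = 4
) -> list[tuple[int, str, str]]:
    """Forward-strand (pos, ref, alt) SNVs annotated synonymous on the toy gene.

    Sites within ``min_boundary_distance`` of an exon edge are skipped so
    the calls carry no splice_region label.
    """
    tx, genome = gene.transcript, gene.genome
    out = []
    for cds_i, pos in gene.cds_to_genomic.items():
        ex = next(e for e in tx.exons if e.start <= pos <= e.end)
        if min(pos - ex.start, ex.end - pos) < min_boundary_distance:
            continue
        ref = genome.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            v = VariantRecord(tx.chrom, pos, ref, alt, genotypes={})
            call = annotate_consequence(v, tx, genome)
            if call.classes == {"synonymous"}:
                out.append((pos, ref, alt))
    return out


@dataclass
class VariantTableSim:
    variants: list[VariantRecord]
    causal: VariantRecord
    transcript: TranscriptModel
    genome: GenomeSlice
    case_samples: list[str]
    control_samples: list[str]
    interval: GenomicInterval


_SEGREGATING = "segregating"  # cases hom-alt, control hom-ref


def simulate_variant_table(
    truth: SimTruth,
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
) -> VariantTableSim:
    """Emit a causal variant plus background variants, one cascade
    violation each, for two affected and one unaffected sequenced animal.
    """
    rng = rng or np.random.default_rng(config.seed)
    if not truth.aa_case_ids:
        raise InputDataError("simulate_variant_table requires at least one affected animal")
    cases = truth.aa_case_ids[:2]
    controls = [
        a for a, s in truth.carrier_status.items() if s == "GG" and a not in cases
    ]
    if not controls:
        controls = [a for a, s in truth.carrier_status.items() if s == "AG"]
    if not controls:
        raise InputDataError("no unaffected animal available as sequencing control")
    control = [controls[0]]

    interval = truth.causal_interval
    gene = make_toy_transcript(
        chrom=truth.causal_chrom,
        causal_genomic_pos=truth.causal_variant_position,
        seed=config.seed,
    )

    def genotypes(kind: str) -> dict[str, int]:
        if kind == _SEGREGATING:
            g = {c: 2 for c in cases}
            g[control[0]] = 0
            return g
        if kind == "case_het":
            g = {c: 2 for c in cases}
            g[cases[0]] = 1
            g[control[0]] = 0
            return g
        raise ValueError(kind)

    used = {truth.causal_variant_position}
    used.update(range(gene.genome.start, gene.genome.end + 1))

    def fresh_positions(n: int, inside: bool) -> list[int]:
        out: list[int] = []
        step = 977  # co-prime spacing keeps positions distinct and sorted-ish
        if inside:
            p = interval.start + 11
            while len(out) < n:
                if p not in used and p <= interval.end:
                    out.append(p)
                    used.add(p)
                p += step
            return out
        p = interval.end + 1000
        while len(out) < n:
            if p not in used:
                out.append(p)
                used.add(p)
            p += step
        return out

    variants: list[VariantRecord] = []

    causal = VariantRecord(
        chrom=truth.causal_chrom,
        pos=truth.causal_variant_position,
        ref=gene.causal_ref,
        alt=gene.causal_alt,
        genotypes=genotypes(_SEGREGATING),
        known_in_catalogue=False,
        on_array_other_breeds=False,
        variant_id="planted_causal",
    )
    variants.append(causal)

    for pos in fresh_positions(config.n_outside_interval, inside=False):
        variants.append(
            VariantRecord(truth.causal_chrom, pos, "A", "C", genotypes(_SEGREGATING))
        )
    for pos in fresh_positions(config.n_fail_genotype, inside=True):
        variants.append(
            VariantRecord(truth.causal_chrom, pos, "G", "T", genotypes("case_het"))
        )
    for pos in fresh_positions(config.n_known, inside=True):
        variants.append(
            VariantRecord(
                truth.causal_chrom, pos, "T", "G", genotypes(_SEGREGATING),
                known_in_catalogue=True,
            )
        )
    for pos in fresh_positions(config.n_on_array, inside=True):
        variants.append(
            VariantRecord(
                truth.causal_chrom, pos, "C", "A", genotypes(_SEGREGATING),
                on_array_other_breeds=True,
            )
        )
    syn_sites = synonymous_snvs(gene)
    if len(syn_sites) < config.n_synonymous:
        raise InputDataError(
            f"toy transcript offers only {len(syn_sites)} synonymous sites, "
            f"{config.n_synonymous} requested"
        )
    picks = rng.choice(len(syn_sites), size=config.n_synonymous, replace=False)
    for k in sorted(int(i) for i in picks):
        pos, ref, alt = syn_sites[k]
        variants.append(
            VariantRecord(truth.causal_chrom, pos, ref, alt, genotypes(_SEGREGATING))
        )

    variants.sort(key=lambda v: (v.chrom, v.pos))
    truth.background_counts = {
        "outside_interval": config.n_outside_interval,
        "fail_genotype": config.n_fail_genotype,
        "known_in_catalogue": config.n_known,
        "on_array": config.n_on_array,
        "synonymous": config.n_synonymous,
    }
    return VariantTableSim(
        variants=variants,
        causal=causal,
        transcript=gene.transcript,
        genome=gene.genome,
        case_samples=list(cases),
        control_samples=control,
        interval=interval,
    )
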