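"""Case/control variant filter cascade with coding-consequence annotation.

The cascade reproduces a five-step recessive-candidate workflow over a
variant table restricted to a mapped interval:

1. keep variants inside the interval;
2. keep variants homozygous-alternate in every case and carrying at
   least one reference allele in the control(s);
3. drop variants present in a known-variant catalogue;
4. drop variants already present on genotyping arrays in other
   populations;
5. keep protein-affecting consequences.

Counts are monotone non-increasing; each dropped variant is attributed
to the first step it fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, InputDataError
from .intervals import GenomicInterval
from .splice import SplicePwm, default_donor_pwm, donor_score_delta
from .transcripts import GenomeSlice, TranscriptModel, revcomp

HOM_REF, HET, HOM_ALT, GT_MISSING = 0, 1, 2, -1

_VALID_BASES = set("ACGT")

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}

PROTEIN_AFFECTING = frozenset(
    {"missense", "stop_gain", "stop_loss", "start_loss", "frameshift"}
)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, int]  # sample -> {0,1,2,-1}
    known_in_catalogue: bool = False
    on_array_other_breeds: bool = False
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InputDataError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele.upper()) <= _VALID_BASES:
                raise InputDataError(
                    f"{self.chrom}:{self.pos}: invalid allele {allele!r}"
                )
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.variant_id:
            self.variant_id = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class ConsequenceCall:
    classes: set[str]
    protein_change: str | None = None
    exon_index: int | None = None
    distance_to_exon_boundary: int | None = None
    codon_number: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    donor_ref_window: str | None = None
    donor_alt_window: str | None = None


# splice window sizes (donor side): last N exonic / first M intronic bases
SPLICE_EXONIC = 3
SPLICE_INTRONIC = 6


def _donor_windows(
    variant: VariantRecord, transcript: TranscriptModel, genome: GenomeSlice, exon_t_index: int
) -> tuple[str, str]:
    """Reference and alternate 9-base donor windows in transcription sense."""
    exons = transcript.exons_in_transcription_order()
    ex = exons[exon_t_index - 1]
    if transcript.strand == "+":
        g_positions = list(range(ex.end - 2, ex.end + 7))
        bases = [genome.base(p) for p in g_positions]
        ref_win = "".join(bases)
        alt_bases = list(bases)
        if variant.pos in g_positions:
            alt_bases[g_positions.index(variant.pos)] = variant.alt
        alt_win = "".join(alt_bases)
    else:
        g_positions = list(range(ex.start - 6, ex.start + 3))
        bases = [genome.base(p) for p in g_positions]
        alt_bases = list(bases)
        if variant.pos in g_positions:
            alt_bases[g_positions.index(variant.pos)] = variant.alt
        ref_win = revcomp("".join(bases))
        alt_win = revcomp("".join(alt_bases))
    return ref_win, alt_win


def annotate_consequence(
    variant: VariantRecord, transcript: TranscriptModel, genome: GenomeSlice
) -> ConsequenceCall:
    """Predict the coding/splice consequence of a variant on one transcript.

    A variant outside the transcript span is ``intergenic``; one inside
    the span but not exonic is ``intronic`` (plus ``splice_region`` when
    within the donor window). Never raises for position alone.
    """
    if variant.chrom != transcript.chrom or not transcript.span.contains(
        variant.chrom, variant.pos
    ):
        return ConsequenceCall(classes={"intergenic"})

    exons_t = transcript.exons_in_transcription_order()
    exon_idx = transcript.exon_index_of(variant.pos)

    call = ConsequenceCall(classes=set())

    # --- splice-region assessment against the donor side of each junction
    donor_exon_idx: int | None = None
    if exon_idx is not None and exon_idx < len(exons_t):
        ex = exons_t[exon_idx - 1]
        dist = (ex.end - variant.pos) if transcript.strand == "+" else (variant.pos - ex.start)
        call.distance_to_exon_boundary = int(dist)
        if dist < SPLICE_EXONIC:
            call.classes.add("splice_region")
            donor_exon_idx = exon_idx
    elif exon_idx is None:
        # intronic: distance to the donor (upstream-in-transcription) exon
        for k in range(1, len(exons_t)):
            ex = exons_t[k - 1]
            if transcript.strand == "+":
                dist = variant.pos - ex.end
            else:
                dist = ex.start - variant.pos
            if 1 <= dist <= SPLICE_INTRONIC:
                call.classes.add("splice_region")
                call.distance_to_exon_boundary = int(dist)
                donor_exon_idx = k
                break

    if donor_exon_idx is not None:
        try:
            ref_win, alt_win = _donor_windows(variant, transcript, genome, donor_exon_idx)
            call.donor_ref_window = ref_win
            call.donor_alt_window = alt_win
        except InputDataError:
            pass  # window runs off the supplied genome slice

    if exon_idx is None:
        call.classes.add("intronic")
        return call

    call.exon_index = exon_idx

    cds_positions = transcript.cds_genomic_positions()
    try:
        cds_idx = cds_positions.index(variant.pos)
    except ValueError:
        # exonic but outside CDS (UTR); treated as non-coding
        call.classes.add("intronic")
        return call

    if not variant.is_snv:
        shift = abs(len(variant.ref) - len(variant.alt))
        call.classes.add("frameshift" if shift % 3 else "inframe_indel")
        call.codon_number = cds_idx // 3 + 1
        call.protein_change = f"p.{call.codon_number}{'fs' if shift % 3 else 'del/ins'}"
        return call

    genome_ref = genome.base(variant.pos)
    if genome_ref != variant.ref:
        raise InputDataError(
            f"{variant.chrom}:{variant.pos}: VCF ref {variant.ref} does not match "
            f"genome base {genome_ref}"
        )

    coding = transcript.coding_sequence(genome)
    codon_number = cds_idx // 3 + 1
    offset = cds_idx % 3
    codon_start = cds_idx - offset
    ref_codon = coding[codon_start : codon_start + 3]
    alt_base_tx = variant.alt if transcript.strand == "+" else revcomp(variant.alt)
    alt_codon = ref_codon[:offset] + alt_base_tx + ref_codon[offset + 1 :]

    from Bio.Seq import Seq

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    call.codon_number = codon_number
    call.ref_aa, call.alt_aa = ref_aa, alt_aa

    if ref_aa == alt_aa:
        call.classes.add("synonymous")
        call.protein_change = f"p.{AA3[ref_aa]}{codon_number}="
    elif codon_number == 1 and ref_aa == "M":
        call.classes.add("start_loss")
        call.protein_change = f"p.{AA3[ref_aa]}1{AA3[alt_aa]}"
    elif alt_aa == "*":
        call.classes.add("stop_gain")
        call.protein_change = f"p.{AA3[ref_aa]}{codon_number}{AA3[alt_aa]}"
    elif ref_aa == "*":
        call.classes.add("stop_loss")
        call.protein_change = f"p.{AA3[ref_aa]}{codon_number}{AA3[alt_aa]}"
    else:
        call.classes.add("missense")
        call.protein_change = f"p.{AA3[ref_aa]}{codon_number}{AA3[alt_aa]}"
    return call


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_out: int


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)
    survivor_ids: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": s.name, "n_in": s.n_in, "n_out": s.n_out} for s in self.steps]
        )

    def counts(self) -> list[int]:
        return [s.n_out for s in self.steps]


STEP_NAMES = [
    "in_interval",
    "hom_alt_cases_ref_allele_in_controls",
    "absent_from_catalogue",
    "absent_from_array",
    "protein_affecting",
]


def _genotype_pass(
    v: VariantRecord, case_ids: list[str], control_ids: list[str], control_rule: str
) -> bool:
    for c in case_ids:
        if v.genotypes.get(c, GT_MISSING) != HOM_ALT:
            return False  # a missing case call fails the homozygosity requirement
    control_ok = [
        v.genotypes.get(c, GT_MISSING) in (HOM_REF, HET) for c in control_ids
    ]
    if not control_ok:
        return True
    return all(control_ok) if control_rule == "all" else any(control_ok)


def apply_filter_cascade(
    variants: list[VariantRecord],
    case_ids: list[str],
    control_ids: list[str],
    interval: GenomicInterval,
    transcripts: list[TranscriptModel],
    genome: GenomeSlice,
    *,
    keep_splice_synonymous: bool = False,
    splice_delta_cutoff: float = -2.0,
    control_rule: str = "all",
    pwm: SplicePwm | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the five-step cascade; returns survivors and the per-step report."""
    if not case_ids:
        raise ConfigurationError("apply_filter_cascade: case_ids must not be empty")
    if control_rule not in ("all", "any"):
        raise ConfigurationError("control_rule must be 'all' or 'any'")

    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    if [id(v) for v in ordered] != [id(v) for v in variants]:
        if [(v.chrom, v.pos) for v in ordered] != [(v.chrom, v.pos) for v in variants]:
            warnings.warn("variant table was unsorted; sorted by (chrom, pos)", stacklevel=2)
    variants = ordered

    report = FilterReport()
    current = [v for v in variants if interval.contains(v.chrom, v.pos)]
    report.steps.append(FilterStep(STEP_NAMES[0], len(variants), len(current)))

    n_in = len(current)
    current = [v for v in current if _genotype_pass(v, case_ids, control_ids, control_rule)]
    report.steps.append(FilterStep(STEP_NAMES[1], n_in, len(current)))

    n_in = len(current)
    current = [v for v in current if not v.known_in_catalogue]
    report.steps.append(FilterStep(STEP_NAMES[2], n_in, len(current)))

    n_in = len(current)
    current = [v for v in current if not v.on_array_other_breeds]
    report.steps.append(FilterStep(STEP_NAMES[3], n_in, len(current)))

    n_in = len(current)
    pwm = pwm or default_donor_pwm()
    survivors: list[VariantRecord] = []
    for v in current:
        tx = next(
            (t for t in transcripts if t.chrom == v.chrom and t.span.contains(v.chrom, v.pos)),
            None,
        )
        if tx is None:
            continue
        call = annotate_consequence(v, tx, genome)
        if call.classes & PROTEIN_AFFECTING:
            survivors.append(v)
        elif (
            keep_splice_synonymous
            and "synonymous" in call.classes
            and "splice_region" in call.classes
            and call.donor_ref_window
            and call.donor_alt_window
            and donor_score_delta(call.donor_ref_window, call.donor_alt_window, pwm)
            <= splice_delta_cutoff
        ):
            survivors.append(v)
    report.steps.append(FilterStep(STEP_NAMES[4], n_in, len(survivors)))
    report.survivor_ids = [v.variant_id for v in survivors]
    return survivors, report
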