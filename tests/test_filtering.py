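import numpy as np
import pytest

from ataxmap.errors import ConfigurationError, InputDataError, ModelError
from ataxmap.filtering import (
    GT_MISSING,
    HET,
    HOM_ALT,
    HOM_REF,
    ConsequenceCall,
    VariantRecord,
    annotate_consequence,
    apply_filter_cascade,
)
from ataxmap.intervals import GenomicInterval
from ataxmap.transcripts import GenomeSlice, TranscriptModel, revcomp

# independent codon table for the oracle (standard genetic code)
CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate((a, b, c) for a in _bases for b in _bases for c in _bases):
    CODON_TABLE[_a + _b + _c] = _aas[_i]


def oracle_class(ref_codon, alt_codon, codon_number):
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        return "synonymous"
    if codon_number == 1 and ref_aa == "M":
        return "start_loss"
    if alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*":
        return "stop_loss"
    return "missense"


def single_exon_transcript(cds, chrom="chrT", start=101, strand="+"):
    """Toy transcript whose single exon is exactly the CDS."""
    n = len(cds)
    if strand == "+":
        seq = "A" * (start - 1) + cds + "A" * 50
        genome = GenomeSlice(chrom, 1, seq)
    else:
        seq = "A" * (start - 1) + revcomp(cds) + "A" * 50
        genome = GenomeSlice(chrom, 1, seq)
    tx = TranscriptModel(
        gene_id="toy30",
        chrom=chrom,
        strand=strand,
        exons=[GenomicInterval(chrom, start, start + n - 1)],
        cds_start=start,
        cds_end=start + n - 1,
    )
    return tx, genome


def make_cds_30_codons():
    rng = np.random.default_rng(42)
    safe = ["GCT", "GAA", "CTG", "AAA", "GGC", "TCT", "GAT", "CCA", "GTT", "ATC",
            "TGG", "TAC", "CAC", "CGA", "AGC", "TTT", "ATG", "CAA", "GGG", "CTC"]
    codons = ["ATG"] + [safe[int(rng.integers(len(safe)))] for _ in range(28)] + ["TAA"]
    return "".join(codons)


class TestAnnotatorOracle:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_substitution_matches_translation_oracle(self, strand):
        cds = make_cds_30_codons()
        tx, genome = single_exon_transcript(cds, strand=strand)
        start = tx.exons[0].start
        n = len(cds)
        for cds_i in range(n):  # 90 coding bases
            codon_number = cds_i // 3 + 1
            offset = cds_i % 3
            ref_codon = cds[cds_i - offset : cds_i - offset + 3]
            for alt_tx in "ACGT":
                if alt_tx == cds[cds_i]:
                    continue
                alt_codon = ref_codon[:offset] + alt_tx + ref_codon[offset + 1 :]
                expected = oracle_class(ref_codon, alt_codon, codon_number)
                if strand == "+":
                    pos = start + cds_i
                    ref_g, alt_g = cds[cds_i], alt_tx
                else:
                    pos = start + (n - 1 - cds_i)
                    ref_g, alt_g = revcomp(cds[cds_i]), revcomp(alt_tx)
                v = VariantRecord(tx.chrom, pos, ref_g, alt_g, genotypes={})
                call = annotate_consequence(v, tx, genome)
                coding = call.classes - {"splice_region"}
                assert coding == {expected}, (cds_i, alt_tx, strand)
                assert call.codon_number == codon_number

    def test_strand_involution(self, toy_gene):
        """Annotation is invariant under re-encoding the gene on the
        opposite strand of the reverse-complemented genome slice."""
        tx, genome = toy_gene.transcript, toy_gene.genome
        L = len(genome.seq)
        flipped_genome = GenomeSlice(genome.chrom, genome.start, revcomp(genome.seq))

        def flip(pos):
            return genome.start + (genome.end - pos)

        flipped_exons = sorted(
            GenomicInterval(tx.chrom, flip(e.end), flip(e.start)) for e in tx.exons
        )
        flipped_tx = TranscriptModel(
            gene_id=tx.gene_id,
            chrom=tx.chrom,
            strand="+",
            exons=flipped_exons,
            cds_start=flip(tx.cds_end),
            cds_end=flip(tx.cds_start),
        )
        v = VariantRecord(
            toy_gene.causal_chrom, toy_gene.causal_pos,
            toy_gene.causal_ref, toy_gene.causal_alt, genotypes={},
        )
        v_flipped = VariantRecord(
            toy_gene.causal_chrom, flip(toy_gene.causal_pos),
            revcomp(toy_gene.causal_ref), revcomp(toy_gene.causal_alt), genotypes={},
        )
        call = annotate_consequence(v, tx, genome)
        call_f = annotate_consequence(v_flipped, flipped_tx, flipped_genome)
        assert call.protein_change == call_f.protein_change
        assert call.classes == call_f.classes
        assert call.exon_index == call_f.exon_index


class TestToyGeneAnnotation:
    def test_causal_variant_call(self, toy_gene):
        v = VariantRecord(
            toy_gene.causal_chrom, toy_gene.causal_pos,
            toy_gene.causal_ref, toy_gene.causal_alt, genotypes={},
        )
        call = annotate_consequence(v, toy_gene.transcript, toy_gene.genome)
        assert call.classes == {"missense", "splice_region"}
        assert call.protein_change == "p.Arg203Gln"
        assert call.exon_index == 5
        assert call.distance_to_exon_boundary == 0

    def test_synonymous_site(self, toy_gene):
        tx, genome = toy_gene.transcript, toy_gene.genome
        # codon 10 is ATC (Ile); ATC -> ATA keeps isoleucine
        pos = toy_gene.cds_to_genomic[30]
        ref = genome.base(pos)
        alt = revcomp("A")  # transcript-sense C>A at the third codon base
        call = annotate_consequence(
            VariantRecord(tx.chrom, pos, ref, alt, genotypes={}), tx, genome
        )
        assert "synonymous" in call.classes
        assert call.protein_change == "p.Ile10="

    def test_intronic_and_intergenic(self, toy_gene):
        tx, genome = toy_gene.transcript, toy_gene.genome
        intron_pos = tx.exons[0].end + 50  # between exon structures
        call = annotate_consequence(
            VariantRecord(tx.chrom, intron_pos, genome.base(intron_pos), "A"
                          if genome.base(intron_pos) != "A" else "C", genotypes={}),
            tx, genome,
        )
        assert "intronic" in call.classes
        out_call = annotate_consequence(
            VariantRecord(tx.chrom, 1_000, "A", "C", genotypes={}), tx, genome
        )
        assert out_call.classes == {"intergenic"}

    def test_donor_intronic_positions_flag_splice_region(self, toy_gene):
        tx, genome = toy_gene.transcript, toy_gene.genome
        # minus strand: intron bases just below an exon start are donor-side
        ex5 = tx.exons_in_transcription_order()[4]
        for offset in (1, 6):
            pos = ex5.start - offset
            ref = genome.base(pos)
            alt = "A" if ref != "A" else "C"
            call = annotate_consequence(
                VariantRecord(tx.chrom, pos, ref, alt, genotypes={}), tx, genome
            )
            assert "splice_region" in call.classes
            assert "intronic" in call.classes
        pos = ex5.start - 7  # beyond the donor window
        ref = genome.base(pos)
        call = annotate_consequence(
            VariantRecord(tx.chrom, pos, ref, "A" if ref != "A" else "C", genotypes={}),
            tx, genome,
        )
        assert "splice_region" not in call.classes

    def test_ref_mismatch_raises(self, toy_gene):
        tx, genome = toy_gene.transcript, toy_gene.genome
        pos = toy_gene.causal_pos
        wrong_ref = "G" if genome.base(pos) != "G" else "T"
        with pytest.raises(InputDataError):
            annotate_consequence(
                VariantRecord(tx.chrom, pos, wrong_ref, "A", genotypes={}), tx, genome
            )

    def test_frameshift_vs_inframe_indel(self, toy_gene):
        tx, genome = toy_gene.transcript, toy_gene.genome
        pos = toy_gene.cds_to_genomic[33]
        ref = genome.base(pos)
        fs = annotate_consequence(
            VariantRecord(tx.chrom, pos, ref, ref + "AT", genotypes={}), tx, genome
        )
        assert "frameshift" in fs.classes
        inframe = annotate_consequence(
            VariantRecord(tx.chrom, pos, ref, ref + "ATG", genotypes={}), tx, genome
        )
        assert "inframe_indel" in inframe.classes


class TestVariantRecordValidation:
    def test_ref_equals_alt_raises(self):
        with pytest.raises(InputDataError):
            VariantRecord("chr1", 10, "A", "A", genotypes={})

    def test_invalid_allele_raises(self):
        with pytest.raises(InputDataError):
            VariantRecord("chr1", 10, "A", "N", genotypes={})


def _v(pos, genotypes, known=False, on_array=False, ref="A", alt="C"):
    return VariantRecord(
        "chr19", pos, ref, alt, genotypes=dict(genotypes),
        known_in_catalogue=known, on_array_other_breeds=on_array,
    )


INTERVAL = GenomicInterval("chr19", 26_848_700, 27_529_700)
SEG = {"case1": HOM_ALT, "case2": HOM_ALT, "ctrl": HOM_REF}


class TestFilterCascade:
    def test_empty_input_gives_all_zero_counts(self, toy_gene):
        _, report = apply_filter_cascade(
            [], ["case1"], ["ctrl"], INTERVAL, [toy_gene.transcript], toy_gene.genome
        )
        assert report.counts() == [0, 0, 0, 0, 0]
        assert len(report.steps) == 5

    def test_empty_cases_raise(self, toy_gene):
        with pytest.raises(ConfigurationError):
            apply_filter_cascade(
                [], [], ["ctrl"], INTERVAL, [toy_gene.transcript], toy_gene.genome
            )

    def test_first_failing_step_attribution(self, toy_gene):
        causal = _v(
            toy_gene.causal_pos, SEG, ref=toy_gene.causal_ref, alt=toy_gene.causal_alt
        )
        variants = [
            _v(26_000_000, SEG),                                  # outside interval
            _v(26_900_000, {**SEG, "case1": HET}),                # fails genotype
            _v(26_910_000, SEG, known=True),                      # in catalogue
            _v(26_920_000, SEG, on_array=True),                   # on array
            causal,
        ]
        survivors, report = apply_filter_cascade(
            variants, ["case1", "case2"], ["ctrl"], INTERVAL,
            [toy_gene.transcript], toy_gene.genome,
        )
        assert report.counts() == [4, 3, 2, 1, 1]
        assert [v.variant_id for v in survivors] == [causal.variant_id]
        # monotone non-increasing and survivors subset of input
        counts = [report.steps[0].n_in] + report.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_case_genotype_fails_filter(self, toy_gene):
        v = _v(26_900_000, {"case1": HOM_ALT, "case2": GT_MISSING, "ctrl": HOM_REF})
        survivors, report = apply_filter_cascade(
            [v], ["case1", "case2"], ["ctrl"], INTERVAL,
            [toy_gene.transcript], toy_gene.genome,
        )
        assert report.counts()[1] == 0

    def test_control_rule_all_vs_any(self, toy_gene):
        v = _v(
            toy_gene.causal_pos,
            {"case1": HOM_ALT, "ctrl1": HOM_REF, "ctrl2": HOM_ALT},
            ref=toy_gene.causal_ref, alt=toy_gene.causal_alt,
        )
        kw = dict(
            interval=INTERVAL, transcripts=[toy_gene.transcript], genome=toy_gene.genome
        )
        _, rep_all = apply_filter_cascade([v], ["case1"], ["ctrl1", "ctrl2"], **kw)
        assert rep_all.counts()[1] == 0
        surv, rep_any = apply_filter_cascade(
            [v], ["case1"], ["ctrl1", "ctrl2"], control_rule="any", **kw
        )
        assert rep_any.counts()[1] == 1 and len(surv) == 1

    def test_unsorted_input_warns_and_sorts(self, toy_gene):
        v1 = _v(27_000_000, SEG)
        v2 = _v(26_900_000, SEG)
        with pytest.warns(UserWarning, match="unsorted"):
            apply_filter_cascade(
                [v1, v2], ["case1", "case2"], ["ctrl"], INTERVAL,
                [toy_gene.transcript], toy_gene.genome,
            )

    def test_synonymous_dropped_by_default(self, toy_gene):
        from ataxmap.sim.variants import synonymous_snvs

        pos, ref, alt = synonymous_snvs(toy_gene)[0]
        v = _v(pos, SEG, ref=ref, alt=alt)
        survivors, report = apply_filter_cascade(
            [v], ["case1", "case2"], ["ctrl"], INTERVAL,
            [toy_gene.transcript], toy_gene.genome,
        )
        assert survivors == []
        assert report.counts() == [1, 1, 1, 1, 0]

    def test_keep_splice_synonymous_flag(self):
        # plus-strand gene whose exon-1 terminal base is a third codon
        # position: CTG -> CTA is synonymous but weakens the donor site
        exon1 = "ATGGCTCTG"
        exon2 = "GCTGAAGATTAA"
        intron = "GTAAGT" + "C" * 20 + "AG"
        seq = "CCC" + exon1 + intron + exon2 + "CCC"
        genome = GenomeSlice("chrS", 1, seq)
        e1_start = 4
        e1_end = e1_start + len(exon1) - 1
        e2_start = e1_end + len(intron) + 1
        tx = TranscriptModel(
            gene_id="splicegene",
            chrom="chrS",
            strand="+",
            exons=[
                GenomicInterval("chrS", e1_start, e1_end),
                GenomicInterval("chrS", e2_start, e2_start + len(exon2) - 1),
            ],
            cds_start=e1_start,
            cds_end=e2_start + len(exon2) - 1,
        )
        assert tx.protein(genome) == "MALAED*"
        iv = GenomicInterval("chrS", 1, len(seq))
        v = VariantRecord("chrS", e1_end, "G", "A", genotypes=dict(SEG))
        call = annotate_consequence(v, tx, genome)
        assert call.classes == {"synonymous", "splice_region"}

        kw = dict(interval=iv, transcripts=[tx], genome=genome)
        dropped, _ = apply_filter_cascade([v], ["case1", "case2"], ["ctrl"], **kw)
        assert dropped == []
        kept, _ = apply_filter_cascade(
            [v], ["case1", "case2"], ["ctrl"], keep_splice_synonymous=True, **kw
        )
        assert len(kept) == 1


def test_transcript_model_validation():
    with pytest.raises(ModelError):
        TranscriptModel(
            gene_id="bad", chrom="chr1", strand="+",
            exons=[GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 15, 30)],
            cds_start=10, cds_end=30,
        )
    tx = TranscriptModel(
        gene_id="frame", chrom="chr1", strand="+",
        exons=[GenomicInterval("chr1", 10, 20)], cds_start=10, cds_end=20,
    )
    with pytest.raises(ModelError, match="divisible by 3"):
        tx.cds_genomic_positions()
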