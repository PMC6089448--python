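# ataxmap

A toolkit for mapping a recessive Mendelian disease in a livestock
population and characterizing the candidate variant:

- **`ataxmap.roh`** — runs-of-homozygosity detection on SNP-array
  genotypes and shared-homozygosity (autozygosity) interval mapping
  across affected animals, tolerant of phenocopies and genotyping error.
- **`ataxmap.filtering`** — a five-step case/control variant filter
  cascade (interval → segregation → known-variant catalogue → array
  content → protein-affecting consequence) with a reverse-strand-aware
  coding-consequence annotator and splice-region flagging.
- **`ataxmap.splice`** — generic position-weight-matrix scoring of
  9-base splice donor windows (log2 odds against a uniform background).
- **`ataxmap.popgen`** — cohort genotype counting, allele frequencies
  under both table (one-decimal) and prose (integer percent) rounding,
  homozygote fractions, effect-size ratios, and a conditional-exact
  test for homozygote deficit.
- **`ataxmap.association`** — pedigree numerator relationship matrix
  (tabular method, with a Henderson-rules sparse inverse), REML fitting
  of the single-locus animal model `y = 1μ + Xβ + u + e`, and genotype
  contrast tables with significance markers.
- **`ataxmap.morphometry`** — group summaries and one-way ANOVA for
  paranodal-length measurements.
- **`ataxmap.sim`** — synthetic-data generators with full ground-truth
  ledgers: linebred pedigrees, gene-dropping with a planted recessive
  disease haplotype, variant tables with by-construction filter-cascade
  categories, phenotypes under the animal model, and log-normal
  morphometry groups.

All genomic coordinates are 1-based inclusive (VCF-native); BED output
is converted explicitly at export. Interval length is reported as
`end − start` (in kb as `length/1000`).

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` carries the acceptance criteria: the
desk-scale figures plus property-based checks (planted-interval recovery
over 50 seeded simulations, filter-cascade exactness over 100 seeds,
annotator agreement with a brute-force translation oracle, relationship
matrix vs. gene-dropping Monte Carlo, REML contrast recovery and null
calibration, ANOVA power). The full suite takes a few minutes on one
CPU.

## CLI

One executable with six subcommands, each accepting `--out` (and
`--seed`/`--config` where stochastic):

```sh
ataxmap simulate --config sim.yaml --seed 1 --out cohort/
ataxmap roh      --genotypes cohort/genotypes --cases cases.txt --out roh/
ataxmap filter   --vcf cohort/variants.vcf --interval chr19:26848700-27529700 \
                 --cases aff1,aff2 --controls wt1 \
                 --transcripts cohort/transcripts.gff3 \
                 --genome cohort/genome_slice.fasta --out filtered/
ataxmap freq     --counts cohort_counts.tsv --out freq/
ataxmap assoc    --pedigree cohort/pedigree.csv --phenotypes cohort/phenotypes.tsv --out assoc/
ataxmap morpho   --measures lengths.tsv --out morpho/
```

Every run writes a `provenance.json` (package version, config hash,
seed) next to its outputs. `ataxmap simulate` emits a full synthetic
cohort: pedigree CSV, genotypes (TSV + PLINK-style .ped/.map), a VCF
with the planted causal variant and categorized background variants, a
GFF3 toy transcript with its FASTA genome slice, phenotypes, paranodal
lengths, and a `truth.json` ground-truth ledger.

## File formats

| object | format |
| --- | --- |
| genotypes | TSV matrix + marker TSV, or PLINK-style text .ped/.map |
| variants | VCF v4.2 (uncompressed; INFO flags KNOWN, ONARRAY) |
| pedigree | CSV: animal_id, sire_id, dam_id, sex, birth_cohort ("0" = unknown parent) |
| transcripts | minimal GFF3 (gene/mRNA/exon/CDS) |
| genome | FASTA slice with `start=` anchor in the description |
| phenotypes / reports | TSV |
| intervals | BED (0-based half-open) on export only |
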