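"""Readers and writers for the on-disk formats the toolkit owns.

Internal coordinates are 1-based inclusive everywhere; BED output is the
only 0-based half-open surface and is produced by explicit conversion.
All write/read pairs round-trip their in-memory objects.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputDataError
from .filtering import VariantRecord
from .genotypes import MISSING, GenotypeMatrix, MarkerMap
from .intervals import GenomicInterval
from .pedigree import Pedigree, PedigreeEntry
from .transcripts import GenomeSlice, TranscriptModel

# ---------------------------------------------------------------- genotypes


def write_genotypes_tsv(gm: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a genotype matrix as <prefix>.tsv plus <prefix>.markers.tsv."""
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".tsv")
    marker_path = prefix.with_suffix(".markers.tsv")
    df = pd.DataFrame(gm.codes, index=gm.samples, columns=gm.markers.ids)
    df.index.name = "sample_id"
    df.to_csv(geno_path, sep="\t")
    pd.DataFrame(
        {
            "marker_id": gm.markers.ids,
            "chrom": gm.markers.chroms,
            "pos": gm.markers.positions,
        }
    ).to_csv(marker_path, sep="\t", index=False)
    return geno_path, marker_path


def read_genotypes_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".tsv")
    marker_path = prefix.with_suffix(".markers.tsv")
    for p in (geno_path, marker_path):
        if not p.exists():
            raise InputDataError(f"missing genotype file {p}")
    df = pd.read_csv(geno_path, sep="\t", index_col="sample_id")
    mk = pd.read_csv(marker_path, sep="\t")
    markers = MarkerMap(
        ids=list(mk["marker_id"].astype(str)),
        chroms=mk["chrom"].astype(str).to_numpy(dtype=object),
        positions=mk["pos"].to_numpy(dtype=np.int64),
    )
    if list(df.columns) != markers.ids:
        raise InputDataError(f"{geno_path}: marker columns do not match {marker_path}")
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        markers=markers,
        codes=df.to_numpy(dtype=np.int8),
    )


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """PLINK-style text .ped/.map; codes map to alleles A (ref) and B (alt)."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    allele = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            genos = " ".join(allele[int(c)] for c in gm.codes[i])
            fh.write(f"FAM {sample} 0 0 0 -9 {genos}\n")
    with open(map_path, "w") as fh:
        for mid, chrom, pos in zip(gm.markers.ids, gm.markers.chroms, gm.markers.positions):
            fh.write(f"{chrom} {mid} 0 {pos}\n")
    return ped_path, map_path


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    ids, chroms, positions = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise InputDataError(f"{map_path}:{lineno}: expected 4 fields")
            chroms.append(parts[0])
            ids.append(parts[1])
            positions.append(int(parts[3]))
    markers = MarkerMap(
        ids=ids, chroms=np.array(chroms, dtype=object), positions=np.array(positions)
    )
    samples, rows = [], []
    code_of = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2, ("0", "0"): MISSING}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(markers):
                raise InputDataError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(markers)} fields, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            pairs = zip(parts[6::2], parts[7::2])
            try:
                rows.append([code_of[p] for p in pairs])
            except KeyError as exc:
                raise InputDataError(
                    f"{ped_path}:{lineno}: invalid allele pair {exc.args[0]}"
                ) from None
    return GenotypeMatrix(samples=samples, markers=markers, codes=np.array(rows, dtype=np.int8))


def read_genotypes(path: str | Path, fmt: str = "tsv") -> GenotypeMatrix:
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    if fmt == "plink":
        return read_plink(path)
    raise InputDataError(f"unknown genotype format {fmt!r} (use 'tsv' or 'plink')")


# ---------------------------------------------------------------- VCF

_GT_TO_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
_CODE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(variants: list[VariantRecord], samples: list[str], path: str | Path) -> Path:
    """Write an uncompressed VCF v4.2 (1-based positions)."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=KNOWN,Number=0,Type=Flag,Description="Present in known-variant catalogue">')
    header.add_line('##INFO=<ID=ONARRAY,Number=0,Type=Flag,Description="Present on genotyping arrays in other populations">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in variants):
        max_pos = max(v.pos for v in variants if v.chrom == chrom)
        header.contigs.add(chrom, length=max_pos + 10_000)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos - 1,  # pysam is 0-based internally
                alleles=(v.ref, v.alt),
                id=v.variant_id,
            )
            if v.known_in_catalogue:
                rec.info["KNOWN"] = True
            if v.on_array_other_breeds:
                rec.info["ONARRAY"] = True
            for s in samples:
                rec.samples[s]["GT"] = _CODE_TO_GT[v.genotypes.get(s, MISSING)]
            vf.write(rec)
    return path


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"no such VCF {path}")
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise InputDataError(
                    f"{path}: record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            genotypes = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                genotypes[s] = _GT_TO_CODE.get(gt, MISSING) if gt else MISSING
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,  # pysam exposes the 1-based POS here
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotypes=genotypes,
                    known_in_catalogue="KNOWN" in rec.info,
                    on_array_other_breeds="ONARRAY" in rec.info,
                    variant_id=rec.id or "",
                )
            )
    return out, samples


# ---------------------------------------------------------------- pedigree

_PED_COLUMNS = ["animal_id", "sire_id", "dam_id", "sex", "birth_cohort"]


def write_pedigree(pedigree: Pedigree, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "animal_id": e.animal_id,
            "sire_id": e.sire_id or "0",
            "dam_id": e.dam_id or "0",
            "sex": e.sex,
            "birth_cohort": e.birth_cohort,
        }
        for e in pedigree
    ]
    pd.DataFrame(rows, columns=_PED_COLUMNS).to_csv(path, index=False)
    return path


def read_pedigree(path: str | Path) -> Pedigree:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(_PED_COLUMNS) - set(df.columns)
    if missing:
        raise InputDataError(f"{path}: missing pedigree columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                PedigreeEntry(
                    animal_id=row["animal_id"],
                    sire_id=None if row["sire_id"] in ("0", "", None) else row["sire_id"],
                    dam_id=None if row["dam_id"] in ("0", "", None) else row["dam_id"],
                    sex=row["sex"],
                    birth_cohort=int(row["birth_cohort"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise InputDataError(f"{path}:{i + 2}: {exc}") from None
    return Pedigree(entries)


# ---------------------------------------------------------------- transcripts

def write_transcripts(transcripts: list[TranscriptModel], path: str | Path) -> Path:
    """Minimal GFF3: gene / mRNA / exon / CDS features, 1-based inclusive."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            span = t.span
            attrs = f"ID={t.gene_id}"
            fh.write(
                f"{t.chrom}\tataxmap\tgene\t{span.start}\t{span.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{t.chrom}\tataxmap\tmRNA\t{span.start}\t{span.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for i, ex in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chrom}\tataxmap\texon\t{ex.start}\t{ex.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                )
            lo = max(t.cds_start, span.start)
            hi = min(t.cds_end, span.end)
            fh.write(
                f"{t.chrom}\tataxmap\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t{t.frame_offset}\t"
                f"ID={t.transcript_id}.cds;Parent={t.transcript_id}\n"
            )
    return path


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"no such GFF3 {path}")
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise InputDataError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                mrnas[attr["ID"]] = {
                    "chrom": chrom,
                    "strand": strand,
                    "gene": attr.get("Parent", attr["ID"]),
                    "exons": [],
                    "cds": None,
                    "phase": 0,
                }
            elif ftype == "exon":
                parent = attr["Parent"]
                mrnas.setdefault(parent, {"chrom": chrom, "strand": strand,
                                          "gene": parent, "exons": [], "cds": None, "phase": 0})
                mrnas[parent]["exons"].append(GenomicInterval(chrom, int(start), int(end)))
            elif ftype == "CDS":
                parent = attr["Parent"]
                mrnas[parent]["cds"] = (int(start), int(end))
                mrnas[parent]["phase"] = 0 if phase == "." else int(phase)
    out = []
    for tid, info in mrnas.items():
        if not info["exons"]:
            continue
        exons = sorted(info["exons"], key=lambda e: e.start)
        cds = info["cds"] or (exons[0].start, exons[-1].end)
        out.append(
            TranscriptModel(
                gene_id=info["gene"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons,
                cds_start=cds[0],
                cds_end=cds[1],
                frame_offset=info["phase"],
                transcript_id=tid,
            )
        )
    return out


# ---------------------------------------------------------------- sequence

def write_genome_slice(genome: GenomeSlice, path: str | Path) -> Path:
    path = Path(path)
    rec = SeqRecord(
        Seq(genome.seq),
        id=genome.chrom,
        description=f"start={genome.start}",
    )
    SeqIO.write([rec], str(path), "fasta")
    return path


def read_genome_slice(path: str | Path) -> GenomeSlice:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"no such FASTA {path}")
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise InputDataError(f"{path}: expected exactly one sequence record")
    rec = recs[0]
    start = 1
    for token in rec.description.split():
        if token.startswith("start="):
            start = int(token.split("=", 1)[1])
    return GenomeSlice(chrom=rec.id, start=start, seq=str(rec.seq).upper())


# ---------------------------------------------------------------- misc

def write_bed(intervals: list[GenomicInterval], path: str | Path, names: list[str] | None = None) -> Path:
    """Export intervals as BED (0-based half-open, converted explicitly)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, bed_start, bed_end = iv.to_bed()
            name = names[i] if names else f"interval_{i + 1}"
            fh.write(f"{chrom}\t{bed_start}\t{bed_end}\t{name}\n")
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    required = {"animal_id", "trait", "value"}
    if not required <= set(df.columns):
        raise InputDataError(f"{path}: phenotype table needs columns {sorted(required)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_report(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_provenance(path: str | Path, *, config: dict, seed: int | None, version: str) -> Path:
    """Machine-readable provenance block emitted by every CLI run."""
    path = Path(path)
    canonical = json.dumps(config, sort_keys=True, default=str)
    block = {
        "version": version,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config,
    }
    path.write_text(json.dumps(block, indent=2, default=str) + "\n")
    return path
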