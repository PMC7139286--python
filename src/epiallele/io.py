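"""Readers and writers for the text formats the pipeline exchanges.

Cytosine reports, sample sheets, BED6, simple VCF 4.2 (allelic-depth and
genotype flavours), GFF3 and FASTA.  Coordinates follow each format's
native convention: BED is 0-based half-open, VCF/GFF3/cytosine reports
are 1-based.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

CYTOSINE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "count_methylated",
    "count_unmethylated",
    "sample_id",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences."""
    import pyfaidx

    with pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ----------------------------------------------------- cytosine reports

def write_cytosine_report(records: pd.DataFrame, path: str) -> None:
    records[CYTOSINE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cytosine_report(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CYTOSINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine report {path} lacks columns {sorted(missing)}")
    return df


def read_bismark_report(path: str, sample_id: str) -> pd.DataFrame:
    """Read a headerless Bismark-style cytosine report.

    Columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"],
    )
    df["sample_id"] = sample_id
    return df[CYTOSINE_COLUMNS]


def read_sample_sheet(path: str) -> pd.DataFrame:
    """TSV with columns sample_id, group (group in {ctrl, treat})."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"sample sheet {path} lacks column {col!r}")
    return df


# -------------------------------------------------------------- BED/GFF

def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    gr = pr.read_bed(path)
    df = gr.df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                 "Name": "name", "Score": "score", "Strand": "strand"}
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_gff3(path: str) -> pd.DataFrame:
    """GFF3 features as a frame with 0-based half-open start/end."""
    gr = pr.read_gff3(path)
    df = gr.df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                 "Feature": "feature", "Strand": "strand"}
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_gff3(df: pd.DataFrame, path: str, source: str = "epiallele") -> None:
    """Write features (0-based half-open in memory) as 1-based GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            attrs = getattr(row, "attributes", None) or f"ID={getattr(row, 'name', '.')}"
            fh.write(
                f"{row.chrom}\t{source}\t{getattr(row, 'feature', 'region')}\t"
                f"{row.start + 1}\t{row.end}\t.\t{getattr(row, 'strand', '+')}\t.\t{attrs}\n"
            )


# ------------------------------------------------------------------ VCF

def write_allelic_vcf(loci: pd.DataFrame, sample_names: Iterable[str], path: str) -> None:
    """Write biallelic SNVs with per-sample AD (ref,alt depths).

    ``loci`` needs columns chrom, pos (1-based), ref, alt, qual and, per
    sample name S, columns ``S_ref`` and ``S_alt``.
    """
    sample_names = list(sample_names)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in loci["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for row in loci.itertuples(index=False):
            fields = [row.chrom, str(int(row.pos)), ".", row.ref, row.alt,
                      f"{row.qual:.1f}", "PASS", ".", "GT:AD"]
            for s in sample_names:
                ref_n = int(getattr(row, f"{s}_ref"))
                alt_n = int(getattr(row, f"{s}_alt"))
                gt = "0/1" if (ref_n > 0 and alt_n > 0) else ("1/1" if alt_n > 0 else "0/0")
                fields.append(f"{gt}:{ref_n},{alt_n}")
            fh.write("\t".join(fields) + "\n")


def read_allelic_vcf(path: str) -> pd.DataFrame:
    """Read a VCF with AD fields into a long frame (one row per locus)."""
    import pysam

    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "qual": rec.qual if rec.qual is not None else 0.0,
            }
            ok = True
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    ok = False
                    break
                row[f"{s}_ref"] = int(ad[0])
                row[f"{s}_alt"] = int(ad[1])
            if ok:
                rows.append(row)
    return pd.DataFrame(rows)


def write_genotype_vcf(genotypes: pd.DataFrame, loci: pd.DataFrame, path: str) -> None:
    """Write a population genotype matrix (individuals x SNPs, 0/1/2/NaN).

    ``loci`` gives chrom, pos, ref, alt per SNP (columns of ``genotypes``).
    """
    inds = list(genotypes.index)
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in loci["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, inds)) + "\n"
        )
        for snp_id, locus in zip(genotypes.columns, loci.itertuples(index=False)):
            fields = [locus.chrom, str(int(locus.pos)), str(snp_id), locus.ref,
                      locus.alt, ".", "PASS", ".", "GT"]
            for g in genotypes[snp_id].to_numpy():
                fields.append("./." if np.isnan(g) else code_to_gt[int(g)])
            fh.write("\t".join(fields) + "\n")


def read_genotype_matrix(path: str) -> pd.DataFrame:
    """Genotypes from a VCF (GT field) or a 0/1/2 TSV, as individuals x SNPs."""
    if path.endswith((".tsv", ".txt")):
        return pd.read_csv(path, sep="\t", index_col=0)
    import pysam

    data: dict[str, list[float]] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            calls = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or gt[0] is None:
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(1 for a in gt if a)))
            data[rec.id or f"{rec.chrom}:{rec.pos}"] = calls
    return pd.DataFrame(data, index=samples)


def sha256_file(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
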