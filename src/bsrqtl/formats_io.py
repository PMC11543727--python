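"""Genomic coordinate types and readers/writers for the standard formats the
pipeline touches.

Coordinate convention
---------------------
All in-memory coordinates are **1-based inclusive** base-pair positions, so
positions printed in QTL tables map verbatim onto :class:`GenomicInterval`
fields.  Only BED output/input converts to/from the half-open 0-based BED
convention.

Bulk allele counts are carried as a plain :class:`pandas.DataFrame` with the
column schema :data:`COUNT_COLUMNS` — one row per biallelic SNP with REF/ALT
read depths for the high-frequency (MUL) and low-frequency (TRI) bulks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column schema of a bulk allele-count table.
COUNT_COLUMNS = ("chrom", "pos", "mul_ref", "mul_alt", "tri_ref", "tri_alt")


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval of 1-based base-pair positions on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start must be <= end, got [{self.start}, {self.end}]"
            )

    @property
    def width_mb(self) -> float:
        """Interval width in Mb, computed as (end - start) / 1e6."""
        return (self.end - self.start) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        """Intersection interval ([max starts, min ends]) or None if disjoint."""
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with strand-aware transcription start/termination sites."""

    gene_id: str
    interval: GenomicInterval
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: left bound on '+', right bound on '-'."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        """Transcription termination site (opposite end from the TSS)."""
        return self.interval.end if self.strand == "+" else self.interval.start


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_bulk_vcf(
    path: str | Path,
    mul_sample: str = "MUL",
    tri_sample: str = "TRI",
) -> pd.DataFrame:
    """Read a two-bulk VCF with FORMAT/AD into a bulk allele-count table.

    Only biallelic SNP records are kept; multiallelic sites and indels are
    skipped (the ΔSNP index is defined for exactly two alleles).  The number
    of skipped records is logged and stored in ``df.attrs["n_skipped"]``.

    Raises
    ------
    ValueError
        If either sample is absent, a kept record lacks the AD field, or
        positions are not sorted within a chromosome.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (mul_sample, tri_sample):
        if name not in samples:
            raise ValueError(
                f"sample {name!r} not found in {path} (samples: {samples})"
            )
    i_mul = samples.index(mul_sample)
    i_tri = samples.index(tri_sample)

    rows: list[tuple] = []
    n_skipped = 0
    last_pos: dict[str, int] = {}
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        if rec.POS < last_pos.get(rec.CHROM, 0):
            raise ValueError(
                f"VCF not sorted: {rec.CHROM}:{rec.POS} after "
                f"{rec.CHROM}:{last_pos[rec.CHROM]}"
            )
        last_pos[rec.CHROM] = rec.POS
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"missing FORMAT/AD at {rec.CHROM}:{rec.POS}")
        ad = np.asarray(ad)
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                int(ad[i_mul, 0]),
                int(ad[i_mul, 1]),
                int(ad[i_tri, 0]),
                int(ad[i_tri, 1]),
            )
        )
    df = pd.DataFrame(rows, columns=list(COUNT_COLUMNS))
    # AD of '.' comes back as negative sentinels; treat as zero depth
    for col in COUNT_COLUMNS[2:]:
        if len(df):
            df[col] = df[col].clip(lower=0)
    df.attrs["n_skipped"] = n_skipped
    if n_skipped:
        logger.info("read_bulk_vcf: skipped %d multiallelic/indel records", n_skipped)
    return df


def write_bulk_vcf(
    counts: pd.DataFrame,
    path: str | Path,
    mul_sample: str = "MUL",
    tri_sample: str = "TRI",
    ref_allele: str = "A",
    alt_allele: str = "T",
) -> None:
    """Write a bulk allele-count table as a minimal two-sample VCF 4.2 file.

    Each row becomes one biallelic SNP record with GT:AD genotypes (GT is
    emitted as missing; only the allele depths carry information).
    """
    path = Path(path)
    chroms = list(dict.fromkeys(counts["chrom"]))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsrqtl\n")
        for chrom in chroms:
            sub = counts.loc[counts["chrom"] == chrom, "pos"]
            length = int(sub.max()) + 1000 if len(sub) else 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{mul_sample}\t{tri_sample}\n"
        )
        for row in counts.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{ref_allele}\t{alt_allele}"
                f"\t.\t.\t.\tGT:AD\t"
                f"./.:{int(row.mul_ref)},{int(row.mul_alt)}\t"
                f"./.:{int(row.tri_ref)},{int(row.tri_alt)}\n"
            )


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns: {sorted(missing)}")
    return df[list(COUNT_COLUMNS)]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneRecord]:
    """Load gene features from a GFF3 file as :class:`GeneRecord` objects.

    Uses an in-memory gffutils database; only features of type ``gene`` are
    returned. A malformed line raises ``ValueError`` naming the line number.
    """
    import gffutils

    path = Path(path)
    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                interval=GenomicInterval(feat.seqid, feat.start, feat.end),
                strand=strand,
            )
        )
    return genes


def _validate_gff_lines(path: Path) -> None:
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line "
                    f"({len(fields)} fields, expected 9)"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open: start-1, end)."""
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must match intervals in length")
    with Path(path).open("w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file back into 1-based inclusive intervals."""
    intervals = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]) + 1, int(fields[2]))
            )
    return intervals


# ---------------------------------------------------------------------------
# TSV tables (genetic map, genotypes, phenotypes, expression)
# ---------------------------------------------------------------------------

def read_map_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"marker", "chrom", "cm", "bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"genetic map {path} must have columns {sorted(required)}")
    return df


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Line × marker genotype matrix (codes 0/1/2, index = line ids)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"line", "replicate", "affected", "n_seedlings"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"phenotype table {path} must have columns {sorted(required)}"
        )
    return df


def read_fpkm_tsv(path: str | Path) -> pd.DataFrame:
    """Gene × sample FPKM matrix; first column = gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError(f"FPKM matrix {path} contains negative values")
    return df
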