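"""Integration of linkage QTL regions with BSA significant regions, gene
membership, variant location classes and expression filtering.

The joint-analysis logic: a QTL is upheld only where a linkage-mapping
confidence interval and a bulked-segregant region overlap; genes inside the
intersection become candidates, are annotated with the location of nearby
variants relative to the gene model (1-kb upstream of the TSS / genic /
1-kb downstream of the TTS, strand-aware), and are kept when expressed
(FPKM strictly > 1) in both bulks of the stage under study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GeneRecord, GenomicInterval, write_bed

__all__ = [
    "OverlapRecord",
    "CandidateGene",
    "intersect_regions",
    "genes_in",
    "classify_variant",
    "expression_filter",
    "candidate_report",
]


@dataclass(frozen=True)
class OverlapRecord:
    """A nonempty intersection between a linkage QTL and a BSA region."""

    qtl_name: str
    bsa_name: str
    linkage: GenomicInterval
    bsa: GenomicInterval
    intersection: GenomicInterval
    gene_ids: tuple[str, ...] = ()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class CandidateGene:
    """A gene inside a joint region, with expression and variant context."""

    gene_id: str
    interval: GenomicInterval
    source: str  # e.g. "qMF-6/V0"
    expressed: bool
    variant_classes: tuple[str, ...] = ()


def intersect_regions(
    qtl_regions: Mapping[str, GenomicInterval],
    bsa_regions: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[GeneRecord] | None = None,
) -> list[OverlapRecord]:
    """All pairwise nonempty intersections of linkage and BSA regions.

    ``bsa_regions`` carries a label per region (e.g. the stage it came
    from).  When ``genes`` is given, each record lists the gene ids that
    overlap the intersection.
    """
    records = []
    for qtl_name, linkage in qtl_regions.items():
        for bsa_name, bsa in bsa_regions:
            inter = linkage.intersect(bsa)
            if inter is None:
                continue
            ids: tuple[str, ...] = ()
            if genes is not None:
                ids = tuple(g.gene_id for g in genes_in(inter, genes))
            records.append(
                OverlapRecord(qtl_name, bsa_name, linkage, bsa, inter, ids)
            )
    return records


def genes_in(
    interval: GenomicInterval,
    genes: Iterable[GeneRecord],
    rule: str = "any-overlap",
) -> list[GeneRecord]:
    """Genes residing in an interval.

    ``rule="any-overlap"`` (default) keeps genes overlapping the query by at
    least one base under the 1-based inclusive convention — a gene ending
    exactly at the interval start is included.  ``rule="contained"`` requires
    the whole gene inside the interval.
    """
    if rule == "any-overlap":
        return [g for g in genes if g.interval.overlaps(interval)]
    if rule == "contained":
        return [
            g
            for g in genes
            if g.interval.chrom == interval.chrom
            and g.interval.start >= interval.start
            and g.interval.end <= interval.end
        ]
    raise ValueError(f"unknown rule {rule!r}")


def classify_variant(
    chrom: str, pos: int, gene: GeneRecord, flank: int = 1000
) -> str:
    """Classify a variant position relative to one gene, strand-aware.

    Returns ``"genic"`` inside the gene interval, ``"upstream"`` within
    ``flank`` bp beyond the TSS, ``"downstream"`` within ``flank`` bp beyond
    the TTS, else ``"intergenic"``.  The three gene-relative classes
    partition the positions near a gene: each position maps to exactly one
    class for a given gene.
    """
    iv = gene.interval
    if chrom != iv.chrom:
        return "intergenic"
    if iv.start <= pos <= iv.end:
        return "genic"
    if gene.strand == "+":
        before, after = "upstream", "downstream"
    else:
        before, after = "downstream", "upstream"
    if iv.start - flank <= pos < iv.start:
        return before
    if iv.end < pos <= iv.end + flank:
        return after
    return "intergenic"


def expression_filter(
    genes: Sequence[GeneRecord],
    fpkm: pd.DataFrame,
    bulk_samples: Sequence[str],
    threshold: float = 1.0,
    source: str = "",
    variant_classes: Mapping[str, Sequence[str]] | None = None,
) -> list[CandidateGene]:
    """Flag genes expressed (FPKM > threshold, strict) in every bulk sample.

    ``fpkm`` is a gene × sample matrix.  A gene absent from the matrix is
    flagged unexpressed with a warning.  ``variant_classes`` optionally maps
    gene ids to the variant location classes observed near them.
    """
    missing = [s for s in bulk_samples if s not in fpkm.columns]
    if missing:
        raise ValueError(f"FPKM matrix lacks bulk samples: {missing}")
    out = []
    for gene in genes:
        if gene.gene_id in fpkm.index:
            values = fpkm.loc[gene.gene_id, list(bulk_samples)]
            expressed = bool((values > threshold).all())
        else:
            warnings.warn(
                f"gene {gene.gene_id} missing from FPKM matrix; "
                "flagged unexpressed",
                stacklevel=2,
            )
            expressed = False
        classes: tuple[str, ...] = ()
        if variant_classes is not None:
            classes = tuple(sorted(set(variant_classes.get(gene.gene_id, ()))))
        out.append(
            CandidateGene(
                gene_id=gene.gene_id,
                interval=gene.interval,
                source=source,
                expressed=expressed,
                variant_classes=classes,
            )
        )
    return out


def candidate_report(
    overlaps: Sequence[OverlapRecord],
    candidates: Sequence[CandidateGene],
    out_tsv: str | Path,
    out_bed: str | Path | None = None,
) -> pd.DataFrame:
    """Write the candidate-gene report (TSV, optionally BED of candidates).

    One row per candidate gene with provenance: source region, gene
    coordinates, expression flag and variant classes.  Rows are ordered
    deterministically by (chromosome, start, gene id), so identical inputs
    yield byte-identical files.
    """
    region_by_source = {
        f"{o.qtl_name}/{o.bsa_name}": o.intersection for o in overlaps
    }
    rows = []
    for cand in candidates:
        region = region_by_source.get(cand.source)
        rows.append(
            {
                "gene_id": cand.gene_id,
                "chrom": cand.interval.chrom,
                "start": cand.interval.start,
                "end": cand.interval.end,
                "source": cand.source,
                "region_start": region.start if region else "",
                "region_end": region.end if region else "",
                "expressed": cand.expressed,
                "variant_classes": ",".join(cand.variant_classes),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "source",
            "region_start", "region_end", "expressed", "variant_classes",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["chrom", "start", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
    df.to_csv(out_tsv, sep="\t", index=False)
    if out_bed is not None:
        write_bed(
            [GenomicInterval(r.chrom, r.start, r.end) for r in df.itertuples()],
            out_bed,
            names=df["gene_id"].tolist(),
        )
    return df
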