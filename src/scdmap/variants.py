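"""Variant and gene-model containers with VCF/BED IO.

Variants follow VCF conventions: 1-based left-anchored positions, indels
carry the anchor base in both alleles.  Per-sample evidence is the pair of
quality-passing read counts supporting (ref, alt); a sample with zero
reads on both alleles has an unknown genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pysam

__all__ = [
    "VariantRecord",
    "GeneModel",
    "GENOTYPE_UNKNOWN",
    "read_vcf",
    "write_vcf",
    "write_exons_bed",
]

#: per-sample genotype codes: alt-allele count 0/1/2, or unknown
GENOTYPE_UNKNOWN = "unknown"


@dataclass
class VariantRecord:
    """One biallelic variant site with per-sample genotypes and read support.

    ``genotypes`` maps sample id -> 0/1/2 or :data:`GENOTYPE_UNKNOWN`;
    ``read_counts`` maps sample id -> (ref_reads, alt_reads), both already
    thresholded for base/mapping quality upstream.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, object] = field(default_factory=dict)
    read_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for sample, (r, a) in self.read_counts.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative read count for {sample!r}")

    @property
    def variant_class(self) -> str:
        return "SNP" if len(self.ref) == len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def affected_span(self) -> tuple[int, int]:
        """1-based inclusive genomic span of the altered reference bases.

        For SNPs this is the site itself; for indels the anchor base is
        excluded and the span covers the deleted bases (deletion) or the
        insertion point's following base (insertion, zero-length event on
        the reference, represented by the base right of the anchor).
        """
        if self.variant_class == "SNP":
            return (self.pos, self.pos)
        if len(self.ref) > len(self.alt):  # deletion
            return (self.pos + len(self.alt), self.pos + len(self.ref) - 1)
        return (self.pos + 1, self.pos + 1)  # insertion point

    def genotype_of(self, sample: str):
        """Genotype honouring the zero-evidence convention: a sample whose
        quality-passing read counts are (0, 0) is unknown regardless of the
        nominal call."""
        counts = self.read_counts.get(sample)
        if counts is not None and counts == (0, 0):
            return GENOTYPE_UNKNOWN
        return self.genotypes.get(sample, GENOTYPE_UNKNOWN)

    def with_genotype(self, sample: str, genotype) -> "VariantRecord":
        new = dict(self.genotypes)
        new[sample] = genotype
        return replace(self, genotypes=new, read_counts=dict(self.read_counts))


@dataclass
class GeneModel:
    """A gene with exon structure on the genome (1-based inclusive intervals)."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c <= b:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        if any(a > b for a, b in exons):
            raise ValueError("exon start exceeds end")
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        if chrom != self.chrom:
            return False
        return any(a <= end and start <= b for a, b in self.exons)


# ---------------------------------------------------------------------------
# VCF IO (uncompressed VCF v4.2 with GT and AD, via pysam)


def _vcf_header(samples: Sequence[str], contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "AD", "R", "Integer", "Quality-passing read depths for the ref and alt alleles"
    )
    for sample in samples:
        header.add_sample(sample)
    return header


def write_vcf(
    variants: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> None:
    contigs = sorted({v.chrom for v in variants}) or ["chr1"]
    header = _vcf_header(samples, contigs)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), GENOTYPE_UNKNOWN: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for sample in samples:
                rec.samples[sample]["GT"] = gt_map[v.genotype_of(sample)]
                rec.samples[sample]["AD"] = v.read_counts.get(sample, (0, 0))
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError("only biallelic records are supported")
            genotypes: dict[str, object] = {}
            read_counts: dict[str, tuple[int, int]] = {}
            for sample in samples:
                data = rec.samples[sample]
                gt = data.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotypes[sample] = GENOTYPE_UNKNOWN
                else:
                    genotypes[sample] = int(sum(gt))
                ad = data.get("AD")
                read_counts[sample] = (
                    (int(ad[0]), int(ad[1])) if ad and ad[0] is not None else (0, 0)
                )
            variants.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotypes=genotypes,
                    read_counts=read_counts,
                )
            )
    return variants, samples


def write_exons_bed(gene_models: Sequence[GeneModel], path: str | Path) -> None:
    """Exon BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for gm in gene_models:
            for i, (start, end) in enumerate(gm.exons, start=1):
                fh.write(
                    f"{gm.chrom}\t{start - 1}\t{end}\t{gm.gene_id}_exon{i}\t0\t{gm.strand}\n"
                )
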