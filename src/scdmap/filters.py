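"""Candidate-variant filtering: quality, zygosity, exonic location,
cross-species synteny, phenotype annotation, and cross-cohort exclusion.

The cascade mirrors how a candidate region from family mapping is whittled
down to a short list: keep variants with read evidence, homozygous
non-reference in every genotyped affected, inside exons, within genes
whose model-organism orthologs show a relevant phenotype, and absent (as
homozygotes) from unrelated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .gwas import CandidateRegion
from .variants import GENOTYPE_UNKNOWN, GeneModel, VariantRecord

__all__ = [
    "SyntenyBlock",
    "PhenotypeAnnotation",
    "FilterAudit",
    "filter_by_quality",
    "homozygous_alt_in_affecteds",
    "intersect_exons",
    "map_synteny",
    "phenotype_restrict",
    "exclude_cross_cohort",
    "run_filter_cascade",
    "read_synteny_tsv",
    "write_synteny_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
]


@dataclass(frozen=True)
class SyntenyBlock:
    """A conserved-order interval pair between two genomes (1-based inclusive)."""

    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.source_start > self.source_end or self.target_start > self.target_end:
            raise ValueError("malformed synteny block interval")
        if self.source_end == self.source_start and self.target_end == self.target_start:
            pass  # single-base block is degenerate but tolerated
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if self.source_end - self.source_start == 0 and self.target_end - self.target_start > 0:
            raise ValueError("zero-length source interval cannot be interpolated")


@dataclass(frozen=True)
class PhenotypeAnnotation:
    gene_id: str
    term: str


@dataclass
class FilterAudit:
    """Per-stage bookkeeping: input = retained + removed."""

    stage: str
    n_input: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def filter_by_quality(
    variants: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], FilterAudit]:
    """Drop records with no quality-passing read support in any sample.

    Read counts are assumed already thresholded (base/mapping quality >= 20)
    by the upstream caller; here a sample with (0, 0) support has an
    unknown genotype, and a record unknown in every sample carries no
    evidence and is removed.
    """
    kept = []
    for v in variants:
        evidence = [
            s for s in v.read_counts if v.read_counts[s] != (0, 0)
        ]
        if evidence:
            # mark evidence-free samples unknown (genotype_of already
            # enforces this view; materialise it for downstream writers)
            genotypes = {s: v.genotype_of(s) for s in v.genotypes}
            kept.append(
                VariantRecord(
                    v.chrom, v.pos, v.ref, v.alt, genotypes, dict(v.read_counts), v.gene_id
                )
            )
    return kept, FilterAudit("quality", len(variants), len(kept))


def homozygous_alt_in_affecteds(
    variants: Sequence[VariantRecord], affected_ids: Sequence[str]
) -> tuple[list[VariantRecord], FilterAudit]:
    """Keep variants homozygous-alt in every genotyped affected sample.

    Affecteds with unknown genotype (zero read evidence) do not veto a
    variant, but at least one affected must be genotyped.
    """
    if not affected_ids:
        raise ValueError("no affected sample ids supplied")
    kept = []
    for v in variants:
        calls = [v.genotype_of(s) for s in affected_ids]
        known = [c for c in calls if c != GENOTYPE_UNKNOWN]
        if known and all(c == 2 for c in known):
            kept.append(v)
    return kept, FilterAudit("hom_alt_in_affecteds", len(variants), len(kept))


def intersect_exons(
    variants: Sequence[VariantRecord], gene_models: Sequence[GeneModel]
) -> tuple[list[VariantRecord], FilterAudit]:
    """Keep variants whose affected bases overlap an exon; annotate gene id.

    SNPs are tested at their site; indels on their affected reference
    bases excluding the VCF anchor.  Interval arithmetic is 1-based
    inclusive, so a variant on an exon's terminal base is retained.
    """
    kept = []
    for v in variants:
        start, end = v.affected_span()
        hit = next(
            (gm for gm in gene_models if gm.overlaps_exon(v.chrom, start, end)), None
        )
        if hit is not None:
            kept.append(
                VariantRecord(
                    v.chrom, v.pos, v.ref, v.alt,
                    dict(v.genotypes), dict(v.read_counts), hit.gene_id,
                )
            )
    return kept, FilterAudit("exonic", len(variants), len(kept))


def map_synteny(
    region: CandidateRegion, blocks: Sequence[SyntenyBlock]
) -> list[tuple[str, int, int]]:
    """Project a genomic interval through synteny blocks onto a target genome.

    Every block overlapping the region contributes one target interval;
    partial overlaps are linearly interpolated within the block, and '-'
    orientation reverses the mapping.  Returns (chrom, start, end) tuples,
    1-based inclusive.
    """
    out = []
    for b in blocks:
        if b.source_chrom != region.chrom:
            continue
        lo = max(region.start, b.source_start)
        hi = min(region.end, b.source_end)
        if lo > hi:
            continue
        src_len = b.source_end - b.source_start
        tgt_len = b.target_end - b.target_start
        if src_len == 0:
            out.append((b.target_chrom, b.target_start, b.target_end))
            continue
        f_lo = (lo - b.source_start) / src_len
        f_hi = (hi - b.source_start) / src_len
        if b.orientation == "+":
            t_lo = b.target_start + round(f_lo * tgt_len)
            t_hi = b.target_start + round(f_hi * tgt_len)
        else:
            t_lo = b.target_end - round(f_hi * tgt_len)
            t_hi = b.target_end - round(f_lo * tgt_len)
        out.append((b.target_chrom, int(t_lo), int(t_hi)))
    return out


def phenotype_restrict(
    gene_ids: Iterable[str],
    annotations: Sequence[PhenotypeAnnotation],
    terms: Sequence[str],
) -> list[str]:
    """Genes with at least one annotation matching any query term
    (case-insensitive substring)."""
    if not terms:
        raise ValueError("empty phenotype term set")
    queries = [t.lower() for t in terms]
    by_gene: dict[str, list[str]] = {}
    for ann in annotations:
        by_gene.setdefault(ann.gene_id, []).append(ann.term.lower())
    return [
        g
        for g in gene_ids
        if any(q in term for term in by_gene.get(g, []) for q in queries)
    ]


def exclude_cross_cohort(
    variants: Sequence[VariantRecord],
    exclusion_genotypes: Mapping[tuple[str, int, str, str], Mapping[str, object]],
) -> tuple[list[VariantRecord], FilterAudit]:
    """Drop candidates homozygous-alt in any sample of an unrelated cohort.

    ``exclusion_genotypes`` maps variant keys (chrom, pos, ref, alt) to
    per-sample genotypes observed in other cohorts (e.g. whole-genome data
    from unaffected dogs of other breeds).
    """
    kept = []
    for v in variants:
        other = exclusion_genotypes.get(v.key, {})
        if any(g == 2 for g in other.values()):
            continue
        kept.append(v)
    return kept, FilterAudit("cross_cohort", len(variants), len(kept))


def run_filter_cascade(
    variants: Sequence[VariantRecord],
    affected_ids: Sequence[str],
    gene_models: Sequence[GeneModel],
    candidate_genes: Optional[Iterable[str]] = None,
    exclusion_genotypes: Optional[Mapping] = None,
) -> tuple[list[VariantRecord], list[FilterAudit]]:
    """Quality -> zygosity -> exonic -> phenotype-gene -> cross-cohort cascade.

    ``candidate_genes``, when given, restricts exonic hits to that gene
    set (the phenotype-annotated genes from the synteny/annotation step).
    """
    audits = []
    vs, audit = filter_by_quality(variants)
    audits.append(audit)
    vs, audit = homozygous_alt_in_affecteds(vs, affected_ids)
    audits.append(audit)
    vs, audit = intersect_exons(vs, gene_models)
    audits.append(audit)
    if candidate_genes is not None:
        gene_set = set(candidate_genes)
        n_in = len(vs)
        vs = [v for v in vs if v.gene_id in gene_set]
        audits.append(FilterAudit("phenotype_genes", n_in, len(vs)))
    if exclusion_genotypes is not None:
        vs, audit = exclude_cross_cohort(vs, exclusion_genotypes)
        audits.append(audit)
    return vs, audits


# ---------------------------------------------------------------------------
# TSV IO for synteny blocks and phenotype annotations

_SYNTENY_COLS = [
    "source_chrom", "source_start", "source_end",
    "target_chrom", "target_start", "target_end", "orientation",
]


def write_synteny_tsv(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source_chrom": b.source_chrom,
                "source_start": b.source_start,
                "source_end": b.source_end,
                "target_chrom": b.target_chrom,
                "target_start": b.target_start,
                "target_end": b.target_end,
                "orientation": b.orientation,
            }
            for b in blocks
        ],
        columns=_SYNTENY_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_synteny_tsv(path: str | Path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"source_chrom": str, "target_chrom": str})
    return [
        SyntenyBlock(
            str(r.source_chrom), int(r.source_start), int(r.source_end),
            str(r.target_chrom), int(r.target_start), int(r.target_end),
            str(r.orientation),
        )
        for r in df.itertuples()
    ]


def write_phenotype_tsv(annotations: Sequence[PhenotypeAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": a.gene_id, "phenotype_term": a.term} for a in annotations]
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | Path) -> list[PhenotypeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [PhenotypeAnnotation(str(r.gene_id), str(r.phenotype_term)) for r in df.itertuples()]
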