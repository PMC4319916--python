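"""Synthetic cohorts for a fully penetrant recessive lethal disorder.

The generator emulates the data a mapping study of a small outbred dog
family actually sees: a three-generation pedigree in which two carrier
parents produce a litter with affected pups, SNP-array genotypes with
linkage disequilibrium around an embedded causal locus, a candidate-region
variant table containing a homozygous exonic 1-bp deletion in the causal
gene, and the accompanying gene-model / synteny / phenotype annotation
tables.  A truth record ties everything together for parameter-recovery
testing.

LD is modelled by founder-haplotype block copying: each pedigree founder's
chromosomes are mosaics of a small pool of breed haplotypes, copied in
blocks of geometric length, and one designated pool haplotype carries the
causal allele.  Non-founders inherit parental haplotypes with Poisson
recombination (1 cM/Mb).  This produces the tag-SNP structure the mapping
method exploits without simulating ancestral recombination graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gwas import MISSING, CandidateRegion, GenotypeMatrix, write_ped_map
from .pedigree import (
    AFFECTED,
    UNAFFECTED,
    Individual,
    Pedigree,
    write_ped,
)
from .filters import PhenotypeAnnotation, SyntenyBlock, write_phenotype_tsv, write_synteny_tsv
from .variants import GeneModel, VariantRecord, write_exons_bed, write_vcf

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedPedigree",
    "Cohort",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_gene_models",
    "simulate_synteny_blocks",
    "simulate_phenotype_annotations",
    "simulate_region_variants",
    "simulate_cohort",
    "default_region",
    "write_cohort",
    "simulate_founder_pool",
    "pool_copy_weights",
    "SKELETAL_QUERY_TERMS",
]

#: substring queries that cover the skeletal annotation vocabulary below,
#: the way a curator would search a model-organism phenotype browser
SKELETAL_QUERY_TERMS = ("skeletal", "rib", "vertebra", "kyphosis")

#: skeletal phenotype vocabulary used for annotation tables
SKELETAL_TERMS = (
    "abnormal rib and vertebrae morphology",
    "decreased rib number",
    "rib fusion",
    "hemivertebrae",
    "abnormal vertebral column morphology",
    "kyphosis",
)
NON_SKELETAL_TERMS = (
    "abnormal retina morphology",
    "decreased body weight",
    "abnormal coat pigmentation",
    "increased heart rate",
    "abnormal kidney morphology",
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the scaled-down desk conditions: ten 60-Mb chromosomes
    with 500 array markers each (~5,000 markers), a causal locus at
    chr5:35,940,090, a pool of 8 founder haplotypes copied in blocks of
    mean 1 Mb (the scale over which within-breed dog LD is near-complete;
    partial LD extends much further and arises here from block sharing),
    0.5% missing calls, and a litter of eight.
    """

    n_chromosomes: int = 10
    chrom_length_bp: int = 60_000_000
    n_markers_per_chrom: int = 500
    causal_chrom: str = "chr5"
    causal_pos: int = 35_940_090
    founder_haplotype_count: int = 8
    ld_block_length_bp: float = 1_000_000.0
    #: the identical-by-descent segment every carrier copy of the
    #: mutation-bearing haplotype shares around the causal position: a
    #: guaranteed core flank on each side (the embedded locus is by
    #: construction a mappable one, sitting well inside its carrier
    #: haplotype, as in the emulated study where the homozygous segment
    #: covered several Mb on both sides of the mutation) plus an
    #: exponential one-sided extension.  A recent mutation rides an
    #: ancestral haplotype far longer than background LD blocks.
    causal_ibd_core_bp: float = 3_000_000.0
    causal_ibd_half_length_bp: float = 10_000_000.0
    #: background frequency at which ordinary (non-carrier) chromosomes
    #: copy the imported mutation-bearing haplotype.  The haplotype entered
    #: the breed through a handful of imported animals and is rare locally
    #: (no carrier was found outside the family), so it contributes little
    #: to background diversity.
    causal_haplotype_background_freq: float = 0.02
    missing_rate: float = 0.005
    litter_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_markers_per_chrom",
            "founder_haplotype_count",
            "litter_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ld_block_length_bp <= 0:
            raise ValueError("ld_block_length_bp must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.causal_chrom not in self.chromosomes:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} not simulated")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValueError("causal_pos outside causal chromosome")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    causal_chrom: str
    causal_variant: VariantRecord
    carrier_ids: list[str]
    affected_ids: list[str]
    causal_gene_id: str


class SimulatedPedigree(Pedigree):
    """Pedigree plus the phase bookkeeping the genotype simulator needs.

    ``causal_alleles[iid]`` is the ordered allele pair at the causal locus:
    (allele inherited from the sire, allele from the dam); for founders the
    order is arbitrary haplotype order.
    """

    def __init__(self, individuals, causal_alleles: dict[str, tuple[int, int]]):
        super().__init__(individuals)
        self.causal_alleles = causal_alleles


def _mendelian_child_alleles(
    sire_pair: tuple[int, int], dam_pair: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int]:
    return (
        sire_pair[int(rng.integers(2))],
        dam_pair[int(rng.integers(2))],
    )


def simulate_pedigree(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    ascertain_affected: Optional[int] = None,
) -> SimulatedPedigree:
    """Simulate the three-generation family structure of the study design.

    The recessive allele enters the family twice, as happens when
    unrelated imported animals each contribute it: the sire is a carrier
    founder, and the dam inherits the allele from her carrier sire (the
    maternal grandsire).  One further daughter of the grandsire is a
    typed carrier, and two further daughters of his are typed
    non-carriers.  The proband litter is the carrier x carrier mating;
    its pups are drawn by unconditional Mendelian transmission, and
    phenotype is affected iff homozygous for the causal allele (full
    penetrance).

    ``ascertain_affected`` switches on litter-level ascertainment: the
    litter is redrawn until it contains exactly that many affected pups.
    Default is unconditional sampling.
    """
    rng = config.rng() if rng is None else rng
    if ascertain_affected is not None and not 0 <= ascertain_affected <= config.litter_size:
        raise ValueError("ascertain_affected outside [0, litter_size]")

    alleles: dict[str, tuple[int, int]] = {
        "M_GS": (1, 0),  # maternal grandsire, carrier (imported line)
        "M_GD": (0, 0),
        "SIRE": (1, 0),  # carrier founder (second imported line)
        "DAM": (1, 0),  # forced transmission: mutant from the carrier grandsire
        "AUNT": (1, 0),  # the grandsire's other typed carrier daughter
        # two further typed daughters of the grandsire, non-carriers
        # (inherited his wild-type haplotype)
        "SIB1": (0, 0),
        "SIB2": (0, 0),
    }

    def draw_litter() -> dict[str, tuple[int, int]]:
        return {
            f"PUP{i}": _mendelian_child_alleles(alleles["SIRE"], alleles["DAM"], rng)
            for i in range(1, config.litter_size + 1)
        }

    litter = draw_litter()
    if ascertain_affected is not None:
        while sum(sum(pair) == 2 for pair in litter.values()) != ascertain_affected:
            litter = draw_litter()
    alleles.update(litter)

    def pheno(iid: str) -> str:
        return AFFECTED if sum(alleles[iid]) == 2 else UNAFFECTED

    individuals = [
        Individual("M_GS", sex="M", phenotype=UNAFFECTED),
        Individual("M_GD", sex="F", phenotype=UNAFFECTED),
        Individual("SIRE", sex="M", phenotype=UNAFFECTED),
        Individual("DAM", sire="M_GS", dam="M_GD", sex="F", phenotype=UNAFFECTED),
        Individual("AUNT", sire="M_GS", dam="M_GD", sex="F", phenotype=UNAFFECTED),
        Individual("SIB1", sire="M_GS", dam="M_GD", sex="F", phenotype=UNAFFECTED),
        Individual("SIB2", sire="M_GS", dam="M_GD", sex="F", phenotype=UNAFFECTED),
    ]
    for i in range(1, config.litter_size + 1):
        iid = f"PUP{i}"
        individuals.append(
            Individual(
                iid,
                sire="SIRE",
                dam="DAM",
                sex="M" if rng.integers(2) else "F",
                phenotype=pheno(iid),
            )
        )
    for ind in individuals:  # assay genotype at the causal locus
        ind.genotype = sum(alleles[ind.id])
    return SimulatedPedigree(individuals, alleles)


def _marker_positions(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    positions = {}
    for chrom in config.chromosomes:
        pos: set[int] = set()
        while len(pos) < config.n_markers_per_chrom:
            draw = rng.integers(1, config.chrom_length_bp + 1,
                                size=config.n_markers_per_chrom - len(pos))
            pos.update(int(x) for x in draw if x != config.causal_pos)
        positions[chrom] = np.array(sorted(pos), dtype=np.int64)
    return positions


def _mosaic_indices(
    marker_pos: np.ndarray,
    chrom_length: int,
    config: SimConfig,
    rng: np.random.Generator,
    carries_causal: bool = False,
) -> np.ndarray:
    """Assign a pool-haplotype index to every marker by block copying.

    Block boundaries are a Poisson process with mean spacing
    ``ld_block_length_bp``.  A haplotype that carries the causal allele
    additionally copies the mutation-bearing pool haplotype (index 0)
    over an identical-by-descent segment around the causal position,
    with exponentially distributed one-sided extents of mean
    ``causal_ibd_half_length_bp``.  Non-carrier haplotypes are free to
    copy pool haplotype 0 anywhere — the ancestral haplotype exists in
    the breed without the mutation — which keeps marker LD with the
    causal allele imperfect, as in real data.
    """
    h = config.founder_haplotype_count
    bounds = [0.0]
    while bounds[-1] < chrom_length:
        bounds.append(bounds[-1] + rng.exponential(config.ld_block_length_bp))
    bounds_arr = np.array(bounds[1:])
    sources = rng.choice(h, size=len(bounds_arr), p=pool_copy_weights(config))
    block_of_marker = np.searchsorted(bounds_arr, marker_pos)
    idx = sources[block_of_marker]
    if carries_causal:
        ext = config.causal_ibd_half_length_bp - config.causal_ibd_core_bp
        left = config.causal_pos - config.causal_ibd_core_bp - rng.exponential(max(ext, 1.0))
        right = config.causal_pos + config.causal_ibd_core_bp + rng.exponential(max(ext, 1.0))
        idx = np.where((marker_pos >= left) & (marker_pos <= right), 0, idx)
    return idx


def simulate_founder_pool(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """Draw the breed's founder-haplotype pool: per chromosome, an
    (haplotype x marker) 0/1 allele matrix.

    Per-marker allele frequencies follow a drifted U-shaped Beta(0.5, 0.5)
    spectrum — chip markers are chosen to be polymorphic across breeds but
    inside one breed many sit near fixation, so downstream MAF pruning
    removes a large fraction, as with real array data.  Pool haplotype 0,
    the one the causal mutation rides, is a divergent haplotype brought in
    from a distant population: its alleles are uncorrelated with the
    locally drifted frequencies (Bernoulli 1/2), so at near-fixed markers
    it often carries the locally rare allele.
    """
    rng = config.rng() if rng is None else rng
    h = config.founder_haplotype_count
    pool: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        freq = rng.beta(0.5, 0.5, size=config.n_markers_per_chrom)
        pool[chrom] = (rng.random((h, config.n_markers_per_chrom)) < freq).astype(np.int8)
        pool[chrom][0] = (rng.random(config.n_markers_per_chrom) < 0.5).astype(np.int8)
    return pool


def pool_copy_weights(config: SimConfig) -> np.ndarray:
    """Background copying weights over pool haplotypes: the imported
    mutation-bearing haplotype (index 0) is locally rare."""
    h = config.founder_haplotype_count
    if h == 1:
        return np.ones(1)
    bg = config.causal_haplotype_background_freq
    weights = np.full(h, (1.0 - bg) / (h - 1))
    weights[0] = bg
    return weights


def simulate_genotypes(
    pedigree: SimulatedPedigree,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Drop SNP-array genotypes for every pedigree member.

    Founders receive mosaic copies of the founder-haplotype pool;
    non-founders inherit recombinant parental haplotypes (Poisson
    crossovers at 1 cM/Mb), with transmission at the causal locus
    conditioned on the causal genotypes already drawn for the pedigree.
    Genotypes are alternate-allele counts with missing calls introduced
    at ``missing_rate``.
    """
    rng = config.rng() if rng is None else rng
    positions = _marker_positions(config, rng)
    pool = simulate_founder_pool(config, rng)

    # per individual, per chromosome: two haplotype allele vectors
    haplotypes: dict[str, dict[str, np.ndarray]] = {}
    # causal allele carried by each of the two haplotypes, per individual
    hap_causal: dict[str, tuple[int, int]] = {}

    order: list[str] = []
    seen: set[str] = set()

    def topo(iid: str) -> None:
        if iid in seen:
            return
        seen.add(iid)
        for parent in pedigree.parents_of(iid):
            if parent:
                topo(parent)
        order.append(iid)

    for iid in pedigree.ids:
        topo(iid)

    for iid in order:
        sire, dam = pedigree.parents_of(iid)
        want = pedigree.causal_alleles[iid]
        if sire is None and dam is None:
            haps = {}
            for chrom in config.chromosomes:
                pair = []
                for k in range(2):
                    carries = chrom == config.causal_chrom and bool(want[k])
                    idx = _mosaic_indices(
                        positions[chrom],
                        config.chrom_length_bp,
                        config,
                        rng,
                        carries_causal=carries,
                    )
                    pair.append(pool[chrom][idx, np.arange(config.n_markers_per_chrom)])
                haps[chrom] = (pair[0], pair[1])
            haplotypes[iid] = haps
            hap_causal[iid] = want
        else:
            haps = {}
            for chrom in config.chromosomes:
                transmitted = []
                for parent, required in ((sire, want[0]), (dam, want[1])):
                    p_haps = haplotypes[parent][chrom]
                    p_causal = hap_causal[parent]
                    n_x = rng.poisson(config.chrom_length_bp / 1e8)
                    x_pos = np.sort(rng.integers(1, config.chrom_length_bp, size=n_x))
                    if chrom == config.causal_chrom and required == 1:
                        # the causal allele is transmitted on an intact core
                        # segment: crossovers do not fall inside the
                        # protected flank around the causal position (part
                        # of the embedded-mappable-locus guarantee)
                        core = config.causal_ibd_core_bp
                        x_pos = x_pos[
                            np.abs(x_pos - config.causal_pos) > core
                        ]
                    phase_flips = np.searchsorted(x_pos, positions[chrom]) % 2
                    if chrom == config.causal_chrom:
                        flips_at_causal = int(np.searchsorted(x_pos, config.causal_pos) % 2)
                        # choose the start phase so the haplotype covering the
                        # causal position carries the required allele
                        valid = [
                            s
                            for s in (0, 1)
                            if p_causal[s ^ flips_at_causal] == required
                        ]
                        if not valid:
                            raise AssertionError(
                                "pedigree causal genotype inconsistent with parental phase"
                            )
                        start = valid[int(rng.integers(len(valid)))]
                    else:
                        start = int(rng.integers(2))
                    phase = (start + phase_flips) % 2
                    child_hap = np.where(phase == 0, p_haps[0], p_haps[1])
                    transmitted.append(child_hap)
                haps[chrom] = (transmitted[0], transmitted[1])
            haplotypes[iid] = haps
            hap_causal[iid] = want

    sample_ids = list(pedigree.ids)
    blocks = []
    for chrom in config.chromosomes:
        geno = np.stack(
            [haplotypes[iid][chrom][0] + haplotypes[iid][chrom][1] for iid in sample_ids]
        ).astype(np.int8)
        blocks.append(geno)
    genotypes = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = np.where(mask, np.int8(MISSING), genotypes)

    marker_map = pd.DataFrame(
        {
            "chrom": np.repeat(config.chromosomes, config.n_markers_per_chrom),
            "bp": np.concatenate([positions[c] for c in config.chromosomes]),
        }
    )
    marker_ids = [
        f"{chrom}_m{j + 1}"
        for chrom in config.chromosomes
        for j in range(config.n_markers_per_chrom)
    ]
    is_case = np.array(
        [pedigree[iid].phenotype == AFFECTED for iid in sample_ids], dtype=bool
    )
    return GenotypeMatrix(sample_ids, marker_ids, marker_map, genotypes, is_case)


def default_region(config: SimConfig, half_width: int = 8_000_000) -> CandidateRegion:
    """The simulated candidate region: a window around the causal locus."""
    return CandidateRegion(
        config.causal_chrom,
        max(1, config.causal_pos - half_width),
        min(config.chrom_length_bp, config.causal_pos + half_width),
    )


def simulate_gene_models(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_genes: int = 30,
    region: Optional[CandidateRegion] = None,
) -> tuple[list[GeneModel], str]:
    """Place gene models in the candidate region; one contains the causal
    position inside its second exon.  Returns (models, causal_gene_id)."""
    rng = config.rng() if rng is None else rng
    region = default_region(config) if region is None else region
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    models: list[GeneModel] = []
    causal_index = int(rng.integers(n_genes))
    starts = np.sort(rng.choice(
        np.arange(region.start, region.end - 50_000, 60_000), size=n_genes, replace=False
    ))
    for i, gstart in enumerate(starts):
        gene_id = f"gene{i + 1:03d}"
        strand = "+" if rng.integers(2) else "-"
        if i == causal_index:
            # exon 2 straddles the causal position
            e1 = (config.causal_pos - 2_000, config.causal_pos - 1_500)
            e2 = (config.causal_pos - 120, config.causal_pos + 180)
            e3 = (config.causal_pos + 900, config.causal_pos + 1_400)
            models.append(GeneModel(gene_id, config.causal_chrom, strand, (e1, e2, e3)))
            continue
        n_exons = int(rng.integers(2, 7))
        pos = int(gstart)
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(120, 400))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(500, 3_000))
        models.append(GeneModel(gene_id, config.causal_chrom, strand, tuple(exons)))
    causal_gene_id = f"gene{causal_index + 1:03d}"
    return models, causal_gene_id


def simulate_synteny_blocks(
    config: SimConfig, region: Optional[CandidateRegion] = None
) -> list[SyntenyBlock]:
    """Two synteny blocks covering the candidate region, projecting onto two
    target-genome chromosomes (one inverted), as is typical of Mb-scale
    dog-to-mouse comparisons."""
    region = default_region(config) if region is None else region
    split = region.start + (region.end - region.start) // 4
    return [
        SyntenyBlock(region.chrom, region.start, split, "mmu9", 5_290_000,
                     5_290_000 + (split - region.start), "+"),
        SyntenyBlock(region.chrom, split + 1, region.end, "mmu11", 59_600_000,
                     59_600_000 + (region.end - split - 1), "-"),
    ]


def simulate_phenotype_annotations(
    gene_models: Sequence[GeneModel],
    causal_gene_id: str,
    rng: Optional[np.random.Generator] = None,
    n_skeletal: int = 19,
    seed: int = 0,
) -> list[PhenotypeAnnotation]:
    """Annotate ``n_skeletal`` genes (always including the causal gene) with
    skeletal phenotype terms; the rest receive unrelated terms."""
    rng = np.random.default_rng(seed) if rng is None else rng
    gene_ids = [gm.gene_id for gm in gene_models]
    if causal_gene_id not in gene_ids:
        raise ValueError("causal gene absent from gene models")
    n_skeletal = min(n_skeletal, len(gene_ids))
    others = [g for g in gene_ids if g != causal_gene_id]
    skeletal = {causal_gene_id, *rng.choice(others, size=n_skeletal - 1, replace=False)}
    annotations = []
    for g in gene_ids:
        if g in skeletal:
            term = SKELETAL_TERMS[int(rng.integers(len(SKELETAL_TERMS)))]
            annotations.append(PhenotypeAnnotation(g, term))
            if g == causal_gene_id:
                annotations.append(PhenotypeAnnotation(g, "postnatal lethality"))
        else:
            term = NON_SKELETAL_TERMS[int(rng.integers(len(NON_SKELETAL_TERMS)))]
            annotations.append(PhenotypeAnnotation(g, term))
    return annotations


def _draw_read_counts(
    genotype: int, rng: np.random.Generator, mean_depth: float = 10.0
) -> tuple[int, int]:
    depth = int(rng.poisson(mean_depth))
    if depth == 0:
        return (0, 0)
    if genotype == 0:
        return (depth, 0)
    if genotype == 2:
        return (0, depth)
    alt = int(rng.binomial(depth, 0.5))
    return (depth - alt, alt)


def simulate_region_variants(
    config: SimConfig,
    gene_models: Sequence[GeneModel],
    causal_gene_id: str,
    sample_ids: Sequence[str],
    affected_ids: Sequence[str],
    carrier_ids: Sequence[str],
    n_snps: int = 100,
    n_indels: int = 20,
    exonic_fraction: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    region: Optional[CandidateRegion] = None,
) -> tuple[list[VariantRecord], VariantRecord]:
    """Emit a candidate-region variant table including the causal deletion.

    ``n_snps + n_indels`` records are produced (the causal exonic 1-bp
    deletion counts as one of the indels); each non-causal variant falls
    in an exon with probability ``exonic_fraction``.  Affected samples are
    homozygous for the deletion with zero reference-supporting reads;
    carriers are heterozygous; everyone else is homozygous reference.
    Raises if the causal position is not exonic in the causal gene.
    """
    rng = config.rng() if rng is None else rng
    region = default_region(config) if region is None else region
    if n_indels < 1:
        raise ValueError("the causal deletion requires n_indels >= 1")
    if not 0.0 <= exonic_fraction <= 1.0:
        raise ValueError("exonic_fraction must lie in [0, 1]")
    causal_gene = next((g for g in gene_models if g.gene_id == causal_gene_id), None)
    if causal_gene is None:
        raise ValueError(f"causal gene {causal_gene_id!r} not in gene models")
    if not causal_gene.overlaps_exon(config.causal_chrom, config.causal_pos, config.causal_pos):
        raise ValueError("causal position is not exonic in the causal gene")

    exon_pool = [
        (gm.chrom, a, b) for gm in gene_models for (a, b) in gm.exons
    ]

    def _in_any_exon(pos: int) -> bool:
        return any(a <= pos <= b for gm in gene_models for a, b in gm.exons)

    genotypes_for = {}
    for s in sample_ids:
        if s in affected_ids:
            genotypes_for[s] = 2
        elif s in carrier_ids:
            genotypes_for[s] = 1
        else:
            genotypes_for[s] = 0

    causal = VariantRecord(
        chrom=config.causal_chrom,
        pos=config.causal_pos - 1,  # VCF left anchor
        ref="AG",
        alt="A",
        genotypes=dict(genotypes_for),
        read_counts={
            s: _draw_read_counts(genotypes_for[s], rng) for s in sample_ids
        },
    )
    # the affecteds must carry alt-supporting evidence (Del/Del with zero
    # reference reads); re-draw zero-depth affecteds
    for s in affected_ids:
        while causal.read_counts[s][1] == 0:
            causal.read_counts[s] = _draw_read_counts(2, rng)

    variants: list[VariantRecord] = [causal]
    bases = "ACGT"
    used = {causal.pos, config.causal_pos}
    for kind, count in (("SNP", n_snps), ("indel", n_indels - 1)):
        for _ in range(count):
            exonic = bool(rng.random() < exonic_fraction)
            while True:
                if exonic and exon_pool:
                    chrom, a, b = exon_pool[int(rng.integers(len(exon_pool)))]
                    pos = int(rng.integers(a, b + 1))
                else:
                    pos = int(rng.integers(region.start, region.end + 1))
                    chrom = region.chrom
                    if _in_any_exon(pos):
                        continue
                if pos not in used:
                    used.add(pos)
                    break
            ref = bases[int(rng.integers(4))]
            if kind == "SNP":
                alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
            else:
                ref, alt = ref + bases[int(rng.integers(4))], ref
            alt_freq = float(rng.uniform(0.05, 0.6))
            geno = {
                s: int(rng.binomial(2, alt_freq)) for s in sample_ids
            }
            reads = {s: _draw_read_counts(geno[s], rng) for s in sample_ids}
            variants.append(VariantRecord(chrom, pos, ref, alt, geno, reads))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, causal


@dataclass
class Cohort:
    """One complete synthetic study: all inputs plus the truth record."""

    config: SimConfig
    pedigree: SimulatedPedigree
    genotypes: GenotypeMatrix  # all pedigree members
    gwas_genotypes: GenotypeMatrix  # the array-genotyped subset (cases + relatives)
    variants: list[VariantRecord]
    gene_models: list[GeneModel]
    synteny_blocks: list[SyntenyBlock]
    phenotype_annotations: list[PhenotypeAnnotation]
    truth: TruthRecord


def simulate_cohort(
    config: SimConfig,
    ascertain_affected: Optional[int] = 3,
    n_snps: int = 100,
    n_indels: int = 20,
    exonic_fraction: float = 0.05,
) -> Cohort:
    """Generate a full study cohort from one seed.

    The default litter ascertainment (exactly three affected pups) and the
    genotyped subset (three cases plus seven controls: parents, maternal
    grandparents, a carrier aunt and two non-carrier aunts) mirror the
    family design the analysis pipeline targets; four of the seven
    controls are carriers, the rest homozygous wild type.  All stages draw from a single generator seeded by
    ``config.seed``, so identical configs give identical cohorts.
    """
    rng = config.rng()
    pedigree = simulate_pedigree(config, rng=rng, ascertain_affected=ascertain_affected)
    genotypes = simulate_genotypes(pedigree, config, rng=rng)
    gene_models, causal_gene_id = simulate_gene_models(config, rng=rng)
    synteny = simulate_synteny_blocks(config)
    annotations = simulate_phenotype_annotations(gene_models, causal_gene_id, rng=rng)

    affected = [i.id for i in pedigree if i.phenotype == AFFECTED]
    carriers = [
        iid for iid in pedigree.ids if sum(pedigree.causal_alleles[iid]) == 1
    ]
    controls = ["SIRE", "DAM", "M_GS", "M_GD", "AUNT", "SIB1", "SIB2"]
    sequenced = affected + controls[:2]  # affecteds + parents in the variant table
    variants, causal_variant = simulate_region_variants(
        config,
        gene_models,
        causal_gene_id,
        sample_ids=sequenced,
        affected_ids=affected,
        carrier_ids=carriers,
        n_snps=n_snps,
        n_indels=n_indels,
        exonic_fraction=exonic_fraction,
        rng=rng,
    )
    truth = TruthRecord(
        causal_chrom=config.causal_chrom,
        causal_variant=causal_variant,
        carrier_ids=carriers,
        affected_ids=affected,
        causal_gene_id=causal_gene_id,
    )
    gwas = genotypes.subset_samples(affected + controls)
    return Cohort(
        config, pedigree, genotypes, gwas, variants, gene_models, synteny,
        annotations, truth,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort table in its standard interchange format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_ped(cohort.pedigree, outdir / "pedigree.ped")
    paths["pedigree"] = outdir / "pedigree.ped"
    ped, mp = write_ped_map(cohort.gwas_genotypes, outdir / "genotypes")
    paths["ped"], paths["map"] = ped, mp
    vcf_path = outdir / "variants.vcf"
    sequenced = list(cohort.variants[0].genotypes)
    write_vcf(cohort.variants, sequenced, vcf_path)
    paths["vcf"] = vcf_path
    write_exons_bed(cohort.gene_models, outdir / "exons.bed")
    paths["exons"] = outdir / "exons.bed"
    write_synteny_tsv(cohort.synteny_blocks, outdir / "synteny.tsv")
    paths["synteny"] = outdir / "synteny.tsv"
    write_phenotype_tsv(cohort.phenotype_annotations, outdir / "phenotypes.tsv")
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    return paths
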