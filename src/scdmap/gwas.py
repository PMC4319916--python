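"""Family-based association mapping for underpowered cohorts.

Small single-family case/control designs (a handful of affected pups
against their relatives) rarely yield genome-wide significant single-marker
signals.  This module implements the pragmatic workflow that works in that
regime: prune uninformative markers, run per-marker allelic chi-squared
tests, rank the top-K markers and ask which chromosome is over-represented
among them, then refine a candidate interval from the sub-threshold markers
on that chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "AssociationResult",
    "CandidateRegion",
    "PruneReport",
    "MISSING",
    "prune_markers",
    "allelic_chi2",
    "genotypic_chi2",
    "association_scan",
    "top_k_chromosome_enrichment",
    "refine_region",
    "read_ped_map",
    "write_ped_map",
    "write_association_tsv",
    "write_region_bed",
]

#: sentinel for a missing genotype call (distinct from 0 = hom reference)
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x biallelic markers, coded as alternate-allele counts.

    ``genotypes`` is an int8 array of shape (n_samples, n_markers) with
    values 0/1/2 or :data:`MISSING`.  ``marker_map`` has one row per marker
    with columns ``chrom`` and ``bp`` (1-based), sorted by (chrom, bp).
    ``is_case`` labels every sample.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    marker_map: pd.DataFrame
    genotypes: np.ndarray
    is_case: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        n_samples, n_markers = self.genotypes.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.marker_ids) != n_markers or len(self.marker_map) != n_markers:
            raise ValueError("marker annotation length does not match genotype columns")
        if len(self.is_case) != n_samples:
            raise ValueError("case labels must cover all samples")
        chrom_codes = pd.factorize(self.marker_map["chrom"])[0]
        order = np.lexsort((self.marker_map["bp"].to_numpy(), chrom_codes))
        if not np.array_equal(order, np.arange(n_markers)):
            raise ValueError("marker map must be sorted by (chrom, bp)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            marker_map=self.marker_map.iloc[keep].reset_index(drop=True),
            genotypes=self.genotypes[:, keep],
            is_case=self.is_case.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            marker_ids=list(self.marker_ids),
            marker_map=self.marker_map.copy(),
            genotypes=self.genotypes[rows],
            is_case=self.is_case[rows],
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker over non-missing calls (pooled)."""
        g = self.genotypes
        called = g != MISSING
        n_alleles = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = np.where(
                n_alleles > 0,
                np.where(called, g, 0).sum(axis=0) / np.maximum(n_alleles, 1),
                np.nan,
            )
        return np.minimum(alt_freq, 1.0 - alt_freq)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)


@dataclass
class PruneReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int


@dataclass
class AssociationResult:
    marker_id: str
    chrom: str
    bp: int
    chi2: float
    df: int
    p: float
    maf: float
    log10_p: float = field(default=float("nan"))


@dataclass(frozen=True)
class CandidateRegion:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def prune_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.1,
    max_missing: float = 0.2,
) -> tuple[GenotypeMatrix, PruneReport]:
    """Remove markers with MAF < ``maf_min`` or missingness > ``max_missing``.

    Both removals are strict inequalities, so a marker sitting exactly at
    either threshold is retained (PLINK ``--maf`` / ``--geno`` semantics).
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= max_missing <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    if g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    maf = g.maf()
    miss = g.missing_rate()
    fail_maf = ~(maf >= maf_min)  # NaN-MAF (all missing) markers also fail
    fail_miss = miss > max_missing
    keep = ~(fail_maf | fail_miss)
    report = PruneReport(
        n_input=g.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int((fail_miss & ~fail_maf).sum()),
        n_retained=int(keep.sum()),
    )
    return g.subset_markers(keep), report


def _chi2_tail(chi2: float, df: int) -> tuple[float, float]:
    """Survival probability and -log10(p), evaluated via the log tail so that
    statistics of order 150+ (p ~ 1e-36) keep full relative precision."""
    logsf = stats.chi2.logsf(chi2, df)
    return float(np.exp(logsf)), float(-logsf / math.log(10.0))


def allelic_chi2(
    case_genotype_counts: Sequence[int],
    control_genotype_counts: Sequence[int],
) -> AssociationResult:
    """Pearson chi-squared on the 2x2 allele-count table, df = 1.

    Inputs are genotype-count triples (hom-ref, het, hom-alt); each
    individual contributes two alleles.  No continuity correction is
    applied.  If either allele is absent from the pooled table the test is
    uninformative and chi2 = 0, p = 1 is returned.
    """
    ca = np.asarray(case_genotype_counts, dtype=float)
    co = np.asarray(control_genotype_counts, dtype=float)
    if ca.shape != (3,) or co.shape != (3,):
        raise ValueError("genotype counts must be triples (hom-ref, het, hom-alt)")
    if np.any(ca < 0) or np.any(co < 0):
        raise ValueError("negative genotype count")
    # allele counts: (ref, alt) per group
    a, b = 2 * ca[0] + ca[1], 2 * ca[2] + ca[1]
    c, d = 2 * co[0] + co[1], 2 * co[2] + co[1]
    if a + b == 0 or c + d == 0:
        raise ValueError("zero total alleles in one group")
    n = a + b + c + d
    if (a + c) == 0 or (b + d) == 0:
        chi2 = 0.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p, log10_p = _chi2_tail(chi2, 1)
    alt_freq = (b + d) / n
    return AssociationResult(
        marker_id="",
        chrom="",
        bp=0,
        chi2=float(chi2),
        df=1,
        p=p,
        maf=float(min(alt_freq, 1 - alt_freq)),
        log10_p=log10_p,
    )


def genotypic_chi2(
    case_genotype_counts: Sequence[int],
    control_genotype_counts: Sequence[int],
) -> AssociationResult:
    """Pearson chi-squared on the 2x3 genotype table.

    All-zero genotype columns are dropped first; the degrees of freedom are
    (columns - 1) after dropping.  With fewer than two non-empty columns
    the test is undefined and chi2/p are NaN with df = 0.
    """
    table = np.array([case_genotype_counts, control_genotype_counts], dtype=float)
    if table.shape != (2, 3):
        raise ValueError("genotype counts must be triples")
    if np.any(table < 0):
        raise ValueError("negative genotype count")
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("one group has no genotyped individuals")
    table = table[:, table.sum(axis=0) > 0]
    df = table.shape[1] - 1
    if df < 1:
        return AssociationResult("", "", 0, float("nan"), 0, float("nan"), float("nan"))
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p, log10_p = _chi2_tail(chi2, df)
    return AssociationResult("", "", 0, chi2, df, p, float("nan"), log10_p)


def association_scan(
    g: GenotypeMatrix, test: str = "allelic"
) -> list[AssociationResult]:
    """Run the per-marker case/control chi-squared test across all markers.

    The allelic scan is fully vectorised; the scalar
    :func:`allelic_chi2` is the reference implementation it must agree
    with (property-tested).  Markers where one group is entirely missing
    are reported with p = NaN and excluded from downstream ranking.
    """
    if test not in ("allelic", "genotypic"):
        raise ValueError(f"unknown test {test!r}")
    maf = g.maf()
    results: list[AssociationResult] = []
    if test == "genotypic":
        for j in range(g.n_markers):
            col = g.genotypes[:, j]
            triples = []
            for grp in (g.is_case, ~g.is_case):
                calls = col[grp & (col != MISSING)]
                triples.append([int((calls == k).sum()) for k in (0, 1, 2)])
            try:
                r = genotypic_chi2(*triples)
            except ValueError:
                r = AssociationResult("", "", 0, float("nan"), 0, float("nan"), float("nan"))
            results.append(
                AssociationResult(
                    g.marker_ids[j],
                    str(g.marker_map["chrom"].iloc[j]),
                    int(g.marker_map["bp"].iloc[j]),
                    r.chi2,
                    r.df,
                    r.p,
                    maf[j],
                    r.log10_p,
                )
            )
        return results

    geno = g.genotypes
    called = geno != MISSING
    alt = np.where(called, geno, 0).astype(float)
    case = g.is_case
    a_alt = alt[case].sum(axis=0)
    a_n = 2.0 * called[case].sum(axis=0)
    c_alt = alt[~case].sum(axis=0)
    c_n = 2.0 * called[~case].sum(axis=0)
    a_ref = a_n - a_alt
    c_ref = c_n - c_alt
    n = a_n + c_n
    ref_tot = a_ref + c_ref
    alt_tot = a_alt + c_alt
    denom = a_n * c_n * ref_tot * alt_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(
            denom > 0, n * (a_ref * c_alt - a_alt * c_ref) ** 2 / np.maximum(denom, 1), 0.0
        )
    valid = (a_n > 0) & (c_n > 0)
    logsf = stats.chi2.logsf(chi2, 1)
    p = np.where(valid, np.exp(logsf), np.nan)
    chi2 = np.where(valid, chi2, np.nan)
    log10_p = np.where(valid, -logsf / math.log(10.0), np.nan)
    for j in range(g.n_markers):
        results.append(
            AssociationResult(
                g.marker_ids[j],
                str(g.marker_map["chrom"].iloc[j]),
                int(g.marker_map["bp"].iloc[j]),
                float(chi2[j]),
                1,
                float(p[j]),
                float(maf[j]),
                float(log10_p[j]),
            )
        )
    return results


def top_k_chromosome_enrichment(
    results: Sequence[AssociationResult], k: int = 100
) -> tuple[pd.Series, str]:
    """Proportion of the top-``k`` markers (by ascending p) per chromosome.

    Ties at the k-th p-value are broken deterministically by (chrom, bp).
    Returns the per-chromosome proportions (summing to 1, descending) and
    the arg-max chromosome, the candidate for harbouring the causal locus.
    """
    scored = [r for r in results if r.p == r.p]  # drop NaN p
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scored):
        raise ValueError(f"k = {k} exceeds the {len(scored)} testable markers")
    ranked = sorted(scored, key=lambda r: (r.p, r.chrom, r.bp))[:k]
    counts = pd.Series([r.chrom for r in ranked]).value_counts()
    proportions = (counts / k).sort_values(ascending=False, kind="stable")
    return proportions, str(proportions.index[0])


def refine_region(
    results: Sequence[AssociationResult], p_threshold: float = 0.005
) -> Optional[CandidateRegion]:
    """Span of markers with p < ``p_threshold`` on a single chromosome.

    Returns None when no marker passes (the distinct empty-region signal).
    """
    chroms = {r.chrom for r in results}
    if len(chroms) > 1:
        raise ValueError("refine_region expects results from a single chromosome")
    passing = [r for r in results if r.p == r.p and r.p < p_threshold]
    if not passing:
        return None
    positions = [r.bp for r in passing]
    return CandidateRegion(chroms.pop(), min(positions), max(positions))


# ---------------------------------------------------------------------------
# PED/MAP and result IO


def write_ped_map(
    g: GenotypeMatrix, prefix: str | Path, family_id: str = "FAM1"
) -> tuple[Path, Path]:
    """Write a PED/MAP pair (alleles coded 1/2, missing 0 0).

    Phenotype column: 2 = case, 1 = control.  Parent/sex columns are
    zeroed; the full pedigree travels separately in the extended PED.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    code = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            pheno = "2" if g.is_case[i] else "1"
            alleles = " ".join(code[int(x)] for x in g.genotypes[i])
            fh.write(f"{family_id}\t{sid}\t0\t0\t0\t{pheno}\t{alleles}\n")
    with open(map_path, "w") as fh:
        for j, mid in enumerate(g.marker_ids):
            chrom = g.marker_map["chrom"].iloc[j]
            bp = int(g.marker_map["bp"].iloc[j])
            fh.write(f"{chrom}\t{mid}\t0\t{bp}\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_df = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "marker", "cm", "bp"],
        dtype={"chrom": str},
    )
    sample_ids, is_case, rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            sample_ids.append(fields[1])
            is_case.append(fields[5] == "2")
            pairs = fields[6:]
            geno = []
            for a1, a2 in zip(pairs[0::2], pairs[1::2]):
                if a1 == "0" or a2 == "0":
                    geno.append(MISSING)
                else:
                    geno.append((a1 == "2") + (a2 == "2"))
            rows.append(geno)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=map_df["marker"].tolist(),
        marker_map=map_df[["chrom", "bp"]].copy(),
        genotypes=np.array(rows, dtype=np.int8),
        is_case=np.array(is_case, dtype=bool),
    )


def write_association_tsv(results: Sequence[AssociationResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker": r.marker_id,
                "chrom": r.chrom,
                "bp": r.bp,
                "maf": r.maf,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "log10_p": r.log10_p,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_region_bed(region: CandidateRegion, path: str | Path, name: str = "candidate") -> None:
    """BED export: 0-based half-open."""
    with open(path, "w") as fh:
        fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\t{name}\n")
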