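"""In-silico PCR-RFLP assay design and interpretation.

A PCR-RFLP assay genotypes a known variant by amplifying across it and
digesting the product with a restriction enzyme whose recognition site is
present on one allele but destroyed on the other.  The gel band pattern
then reads out the genotype: homozygotes show one allele's fragments,
carriers show the union of both.

Digestion here is purely combinatorial: IUPAC-aware site scanning on both
strands, cuts at a fixed offset within the site, fragment lengths only.
PCR chemistry (cycles, annealing) is not modelled; amplicons are exact
primer-delimited sequences supplied by the caller.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "Enzyme",
    "Amplicon",
    "BandPattern",
    "RflpAssay",
    "digest",
    "find_discriminating_enzymes",
    "expected_patterns",
    "call_genotype",
    "genotype_cohort",
    "read_enzyme_table",
    "write_genotype_calls",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and cut offset.

    ``cut_offset`` is the number of bases of the site left of the cut on
    the strand where the site matches; None defaults to the site midpoint
    (fragment lengths, not cut chemistry, drive the assay).
    """

    name: str
    site: str
    cut_offset: Optional[int] = None

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise ValueError(f"recognition site {site!r} shorter than 4 bases")
        if any(b not in ambiguous_dna_values for b in site):
            raise ValueError(f"non-IUPAC character in site {site!r}")
        if self.cut_offset is not None and not (0 <= self.cut_offset <= len(site)):
            raise ValueError("cut offset outside recognition site")

    @property
    def offset(self) -> int:
        return len(self.site) // 2 if self.cut_offset is None else self.cut_offset


class BandPattern:
    """A multiset of gel fragment lengths in bp."""

    def __init__(self, lengths: Sequence[int]):
        if any(x <= 0 for x in lengths):
            raise ValueError("fragment lengths must be positive")
        self._counts = Counter(int(x) for x in lengths)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self._counts.elements(), reverse=True))

    @property
    def bands(self) -> tuple[int, ...]:
        """Distinct lengths, largest first (what a gel lane shows)."""
        return tuple(sorted(self._counts, reverse=True))

    def total(self) -> int:
        return sum(self._counts.elements())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BandPattern) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"BandPattern({list(self.lengths)})"


def _site_regex(site: str) -> re.Pattern[str]:
    pattern = "".join(
        b if len(ambiguous_dna_values[b]) == 1 else f"[{ambiguous_dna_values[b]}]"
        for b in site
    )
    return re.compile(f"(?=({pattern}))")  # lookahead: overlapping sites count


def digest(seq: str, enzyme: Optional[Enzyme]) -> BandPattern:
    """Cut a sequence at every recognition site on either strand.

    Cut positions are collected from the forward match (cut after
    ``offset`` bases of the site) and from reverse-strand matches (the
    symmetric position), de-duplicated, and converted to fragment lengths.
    With no enzyme or no site the whole sequence is one fragment.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if enzyme is None:
        return BandPattern([len(seq)])
    cuts: set[int] = set()
    fwd = _site_regex(enzyme.site)
    rev = _site_regex(reverse_complement(enzyme.site))
    size = len(enzyme.site)
    for m in fwd.finditer(seq):
        cuts.add(m.start() + enzyme.offset)
    for m in rev.finditer(seq):
        # site on the bottom strand: the top-strand cut sits at the
        # mirrored offset from the far end of the match
        cuts.add(m.start() + size - enzyme.offset)
    cuts = {c for c in cuts if 0 < c < len(seq)}
    bounds = [0, *sorted(cuts), len(seq)]
    return BandPattern([b - a for a, b in zip(bounds, bounds[1:])])


@dataclass
class Amplicon:
    """Primer-delimited amplicon in both allelic states."""

    wt_seq: str
    mut_seq: str
    name: str = "amplicon"

    def __post_init__(self) -> None:
        self.wt_seq = self.wt_seq.upper()
        self.mut_seq = self.mut_seq.upper()
        if not self.wt_seq or not self.mut_seq:
            raise ValueError("both allele sequences are required")

    @property
    def wt_length(self) -> int:
        return len(self.wt_seq)

    @property
    def mut_length(self) -> int:
        return len(self.mut_seq)


@dataclass
class RflpAssay:
    """A discriminating enzyme with its expected per-allele band patterns."""

    amplicon: Amplicon
    enzyme: Enzyme
    wt_pattern: BandPattern
    mut_pattern: BandPattern
    tolerance: float = 0.05


def find_discriminating_enzymes(
    amplicon: Amplicon, enzymes: Sequence[Enzyme], tolerance: float = 0.05
) -> list[RflpAssay]:
    """Return assays for every enzyme whose digestion distinguishes the alleles."""
    if not enzymes:
        raise ValueError("empty enzyme table")
    assays = []
    for enz in enzymes:
        wt = digest(amplicon.wt_seq, enz)
        mut = digest(amplicon.mut_seq, enz)
        if wt != mut:
            assays.append(RflpAssay(amplicon, enz, wt, mut, tolerance))
    return assays


def _merge_bands(lengths: Sequence[int], tolerance: float) -> list[int]:
    """Collapse fragment lengths indistinguishable on a gel.

    Lengths within ``tolerance`` (relative) of the running cluster mean are
    merged into one band, represented by the cluster maximum.
    """
    out: list[int] = []
    for x in sorted(set(lengths)):
        if out and (x - out[-1]) <= tolerance * x:
            out[-1] = max(out[-1], x)
        else:
            out.append(x)
    return out


def _bands_match(observed: Sequence[int], expected: Sequence[int], tolerance: float) -> bool:
    obs = sorted(observed)
    exp = sorted(expected)
    if len(obs) != len(exp):
        return False
    return all(abs(o - e) <= tolerance * max(o, e) for o, e in zip(obs, exp))


def expected_patterns(assay: RflpAssay) -> dict[str, list[int]]:
    """Expected gel band lists (merged within tolerance) per genotype."""
    tol = assay.tolerance
    het_raw = list(assay.wt_pattern.bands) + list(assay.mut_pattern.bands)
    return {
        "hom_wt": _merge_bands(assay.wt_pattern.bands, tol),
        "hom_mut": _merge_bands(assay.mut_pattern.bands, tol),
        "het": _merge_bands(het_raw, tol),
    }


def call_genotype(observed: BandPattern | Sequence[int], assay: RflpAssay) -> str:
    """Call a genotype from an observed band pattern.

    Matching is on distinguishable bands (a gel shows presence, not copy
    number), with near-equal lengths merged within the assay's resolution
    tolerance.  A pattern matching no genotype, or more than one, is
    ``uninterpretable``.
    """
    bands = observed.bands if isinstance(observed, BandPattern) else sorted(set(observed))
    merged = _merge_bands(bands, assay.tolerance)
    matches = [
        geno
        for geno, exp in expected_patterns(assay).items()
        if _bands_match(merged, exp, assay.tolerance)
    ]
    return matches[0] if len(matches) == 1 else "uninterpretable"


def genotype_cohort(
    patterns: Mapping[str, BandPattern | Sequence[int]],
    assay: RflpAssay,
    is_case: Mapping[str, bool],
) -> tuple[pd.DataFrame, tuple[int, int, int], tuple[int, int, int]]:
    """Call genotypes for a cohort and build association-test inputs.

    Returns the per-sample call table plus the (hom-wt, het, hom-mut)
    genotype-count triples for cases and controls, the direct inputs of
    :func:`scdmap.gwas.allelic_chi2`.  Uninterpretable samples are kept in
    the table but excluded from the counts.
    """
    rows = []
    counts = {True: [0, 0, 0], False: [0, 0, 0]}
    index = {"hom_wt": 0, "het": 1, "hom_mut": 2}
    for sample, pattern in patterns.items():
        if pattern is None or (not isinstance(pattern, BandPattern) and len(pattern) == 0):
            raise ValueError(f"sample {sample!r} has no band pattern")
        call = call_genotype(pattern, assay)
        case = bool(is_case.get(sample, False))
        rows.append({"sample": sample, "genotype": call, "is_case": case})
        if call in index:
            counts[case][index[call]] += 1
    table = pd.DataFrame(rows, columns=["sample", "genotype", "is_case"])
    return table, tuple(counts[True]), tuple(counts[False])


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Read a TSV enzyme table with columns name, site, offset (blank = midpoint)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "site": str})
    enzymes = []
    for _, row in df.iterrows():
        offset = row.get("offset")
        offset = None if pd.isna(offset) else int(offset)
        enzymes.append(Enzyme(str(row["name"]), str(row["site"]), offset))
    return enzymes


def write_genotype_calls(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
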