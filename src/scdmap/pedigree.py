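"""Pedigree data model, Mendelian checking, and autosomal-recessive segregation.

The pedigree model targets small livestock/companion-animal families: a few
dozen individuals, biallelic assay genotypes at a single diagnostic locus,
and a fully penetrant recessive phenotype.  Genotypes are stored as the
count of mutant alleles (0 = hom wild type, 1 = heterozygous carrier,
2 = hom mutant) with ``None`` for untyped individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "MendelianViolation",
    "SegregationResult",
    "ConcordanceSummary",
    "check_mendelian",
    "test_ar_segregation",
    "genotype_phenotype_concordance",
    "read_ped",
    "write_ped",
]

# Phenotype / genotype vocabularies
AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

GENOTYPE_LABELS = {0: "hom_wt", 1: "het", 2: "hom_mut", None: "untyped"}
LABEL_TO_GENOTYPE = {v: k for k, v in GENOTYPE_LABELS.items()}


@dataclass
class Individual:
    """One pedigree member.

    ``genotype`` is the diagnostic-assay genotype as a mutant-allele count
    (0/1/2) or ``None`` when untyped.
    """

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = "U"  # 'M', 'F', or 'U'
    phenotype: str = UNKNOWN
    genotype: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"invalid sex {self.sex!r} for {self.id}")
        if self.phenotype not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise ValueError(f"invalid phenotype {self.phenotype!r} for {self.id}")
        if self.genotype is not None and self.genotype not in (0, 1, 2):
            raise ValueError(f"invalid genotype {self.genotype!r} for {self.id}")


class Pedigree:
    """Container of :class:`Individual` keyed by id.

    Validates acyclicity (no individual is its own ancestor) and parental
    sex consistency on construction.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self:
            for parent, want_sex in ((ind.sire, "M"), (ind.dam, "F")):
                if parent is None:
                    continue
                p = self._members.get(parent)
                if p is not None and p.sex not in (want_sex, "U"):
                    raise ValueError(
                        f"{parent!r} is listed as "
                        f"{'sire' if want_sex == 'M' else 'dam'} of {ind.id!r} "
                        f"but has sex {p.sex!r}"
                    )
        # cycle check via DFS
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            state[iid] = 1
            ind = self._members[iid]
            for parent in (ind.sire, ind.dam):
                if parent is None or parent not in self._members:
                    continue
                if state.get(parent) == 1:
                    raise ValueError(f"pedigree cycle involving {parent!r}")
                if parent not in state:
                    visit(parent)
            state[iid] = 2

        for iid in self._members:
            if iid not in state:
                visit(iid)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        ind = self._members[iid]
        return (
            ind.sire if ind.sire in self._members else None,
            ind.dam if ind.dam in self._members else None,
        )

    def founders(self) -> list[str]:
        return [i.id for i in self if self.parents_of(i.id) == (None, None)]

    def affected(self) -> list[str]:
        return [i.id for i in self if i.phenotype == AFFECTED]

    def with_genotype(self, iid: str, genotype: Optional[int]) -> "Pedigree":
        """Return a copy with one individual's assay genotype replaced."""
        members = [
            replace(i, genotype=genotype) if i.id == iid else replace(i)
            for i in self
        ]
        return Pedigree(members)


@dataclass(frozen=True)
class MendelianViolation:
    child: str
    child_genotype: int
    sire: Optional[str]
    sire_genotype: Optional[int]
    dam: Optional[str]
    dam_genotype: Optional[int]


def _transmissible(genotype: Optional[int]) -> set[int]:
    """Alleles (0 = wild type, 1 = mutant) a parent of that genotype can pass."""
    if genotype is None:
        return {0, 1}
    return {0: {0}, 1: {0, 1}, 2: {1}}[genotype]


def check_mendelian(pedigree: Pedigree) -> list[MendelianViolation]:
    """Flag children whose biallelic genotype is impossible given their parents.

    A child genotype is possible iff it can be written as one allele drawn
    from each parent's transmissible set; untyped or absent parents
    contribute the unconstrained set {0, 1}.
    """
    violations = []
    for ind in pedigree:
        if ind.genotype is None:
            continue
        sire, dam = pedigree.parents_of(ind.id)
        if sire is None and dam is None:
            continue
        sire_g = pedigree[sire].genotype if sire else None
        dam_g = pedigree[dam].genotype if dam else None
        possible = {
            a + b
            for a in _transmissible(sire_g)
            for b in _transmissible(dam_g)
        }
        if ind.genotype not in possible:
            violations.append(
                MendelianViolation(ind.id, ind.genotype, sire, sire_g, dam, dam_g)
            )
    return violations


@dataclass
class SegregationResult:
    consistent: bool
    obligate_carriers: set[str] = field(default_factory=set)
    possible_sources: set[str] = field(default_factory=set)
    conflicts: list[str] = field(default_factory=list)


def _genotype_domain(ind: Individual) -> set[int]:
    """Admissible genotypes for one individual under a fully penetrant AR model."""
    domain = {0, 1, 2} if ind.genotype is None else {ind.genotype}
    if ind.phenotype == AFFECTED:
        domain &= {2}
    elif ind.phenotype == UNAFFECTED:
        domain &= {0, 1}
    return domain


def _enumerate_assignments(pedigree: Pedigree) -> Iterator[dict[str, int]]:
    """Yield every genotype assignment consistent with typed data, phenotypes
    (full penetrance) and Mendelian transmission.

    Depth-first search in topological (parents-first) order with pruning;
    exact for the family-scale pedigrees this package targets.
    """
    order: list[str] = []
    seen: set[str] = set()

    def add(iid: str) -> None:
        if iid in seen:
            return
        seen.add(iid)
        for parent in pedigree.parents_of(iid):
            if parent is not None:
                add(parent)
        order.append(iid)

    for iid in pedigree.ids:
        add(iid)

    domains = {iid: _genotype_domain(pedigree[iid]) for iid in order}
    assignment: dict[str, int] = {}

    def rec(k: int) -> Iterator[dict[str, int]]:
        if k == len(order):
            yield dict(assignment)
            return
        iid = order[k]
        sire, dam = pedigree.parents_of(iid)
        for g in sorted(domains[iid]):
            if sire is not None or dam is not None:
                sire_alleles = _transmissible(assignment.get(sire)) if sire else {0, 1}
                dam_alleles = _transmissible(assignment.get(dam)) if dam else {0, 1}
                if g not in {a + b for a in sire_alleles for b in dam_alleles}:
                    continue
            assignment[iid] = g
            yield from rec(k + 1)
            del assignment[iid]

    yield from rec(0)


def test_ar_segregation(pedigree: Pedigree) -> SegregationResult:
    """Test consistency with a fully penetrant autosomal recessive model.

    The pedigree is consistent iff at least one genotype assignment exists
    in which every affected individual is homozygous mutant, every
    unaffected individual is not, typed genotypes are honoured, and all
    transmissions are Mendelian.  Obligate carriers are the individuals
    heterozygous in *every* consistent assignment (parents of affecteds
    always qualify); possible allele sources are the founders that carry
    the mutant allele in at least one consistent assignment.
    """
    if not pedigree.affected():
        raise ValueError("segregation test requires at least one affected individual")
    if all(i.phenotype == UNKNOWN for i in pedigree):
        raise ValueError("pedigree carries no phenotype data")

    achievable: dict[str, set[int]] = {iid: set() for iid in pedigree.ids}
    n_assignments = 0
    full = {iid: _genotype_domain(pedigree[iid]) for iid in pedigree.ids}
    for assignment in _enumerate_assignments(pedigree):
        n_assignments += 1
        for iid, g in assignment.items():
            achievable[iid].add(g)
        if all(achievable[iid] == full[iid] for iid in achievable):
            break  # nothing further to learn

    if n_assignments == 0:
        conflicts = [
            f"affected {iid} cannot be homozygous mutant given typed relatives"
            for iid in pedigree.affected()
        ]
        return SegregationResult(False, set(), set(), conflicts)

    obligate = {
        iid
        for iid, gset in achievable.items()
        if gset and gset <= {1, 2} and pedigree[iid].phenotype != AFFECTED
    }
    founders = set(pedigree.founders())
    sources = {
        iid for iid in founders if achievable[iid] & {1, 2}
    }
    return SegregationResult(True, obligate, sources, [])


@dataclass
class ConcordanceSummary:
    table: pd.DataFrame  # phenotype x genotype-label counts
    penetrance: Optional[float]  # affected hom-mut / total hom-mut, None if undefined
    discordant: list[str]


def genotype_phenotype_concordance(pedigree: Pedigree) -> ConcordanceSummary:
    """Tabulate assay genotype against phenotype and estimate penetrance.

    Unknown-phenotype individuals (e.g. stillborn but morphologically
    normal pups) are excluded from the concordance table.  Penetrance is
    the point estimate affected hom-mutant / all hom-mutant; it is
    undefined (None) when no typed hom-mutant individual is present.
    Discordant individuals are typed affecteds that are not hom-mutant and
    typed hom-mutant individuals that are not affected.
    """
    typed = [i for i in pedigree if i.genotype is not None]
    if not typed:
        raise ValueError("no typed individuals")
    rows = [
        {"phenotype": i.phenotype, "genotype": GENOTYPE_LABELS[i.genotype]}
        for i in typed
        if i.phenotype != UNKNOWN
    ]
    table = (
        pd.DataFrame(rows, columns=["phenotype", "genotype"])
        .value_counts()
        .unstack(fill_value=0)
        if rows
        else pd.DataFrame()
    )
    hom_mut = [i for i in typed if i.genotype == 2 and i.phenotype != UNKNOWN]
    if hom_mut:
        penetrance = sum(i.phenotype == AFFECTED for i in hom_mut) / len(hom_mut)
    else:
        penetrance = None
    discordant = [
        i.id
        for i in typed
        if (i.phenotype == AFFECTED and i.genotype != 2)
        or (i.phenotype == UNAFFECTED and i.genotype == 2)
    ]
    return ConcordanceSummary(table, penetrance, discordant)


# ---------------------------------------------------------------------------
# Extended-PED IO: the standard 6 columns plus phenotype detail and assay
# genotype label.

_SEX_OUT = {"M": "1", "F": "2", "U": "0"}
_SEX_IN = {"1": "M", "2": "F", "0": "U", "-9": "U"}
_PHENO_OUT = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}
_PHENO_IN = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


def write_ped(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    """Write an 8-column extended PED (FID IID PAT MAT SEX PHENO detail assay)."""
    rows = []
    for ind in pedigree:
        rows.append(
            [
                family_id,
                ind.id,
                ind.sire or "0",
                ind.dam or "0",
                _SEX_OUT[ind.sex],
                _PHENO_OUT[ind.phenotype],
                ind.phenotype,
                GENOTYPE_LABELS[ind.genotype],
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_ped(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    individuals = []
    for _, row in df.iterrows():
        genotype = LABEL_TO_GENOTYPE.get(row[7]) if len(row) > 7 else None
        individuals.append(
            Individual(
                id=row[1],
                sire=None if row[2] == "0" else row[2],
                dam=None if row[3] == "0" else row[3],
                sex=_SEX_IN.get(row[4], "U"),
                phenotype=_PHENO_IN.get(row[5], UNKNOWN),
                genotype=genotype,
            )
        )
    return Pedigree(individuals)
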