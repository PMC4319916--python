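"""Check a genotyped family for autosomal recessive segregation.

The three-generation family: heterozygous parents and maternal grandsire,
one further het daughter of the grandsire, three affected homozygous pups,
and stillborn-but-normal pups of unknown phenotype.
"""

from scdmap.pedigree import (
    check_mendelian,
    genotype_phenotype_concordance,
    test_ar_segregation,
)
from scdmap.worked_example import family_pedigree

pedigree = family_pedigree()
violations = check_mendelian(pedigree)
print(f"Mendelian violations among typed trios: {len(violations)}")

result = test_ar_segregation(pedigree)
print(f"autosomal recessive model: "
      f"{'consistent' if result.consistent else 'inconsistent'}")
print(f"obligate carriers: {', '.join(sorted(result.obligate_carriers))}")
print(f"possible founder allele sources: {', '.join(sorted(result.possible_sources))}")

summary = genotype_phenotype_concordance(pedigree)
print(f"penetrance (affected hom-mut / all hom-mut): {summary.penetrance:.2f}")
print(f"discordant individuals: {summary.discordant or 'none'}")
print("Full concordance between assay genotype and phenotype supports a "
      "fully penetrant recessive lethal allele.")
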