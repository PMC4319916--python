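"""Generate a synthetic mapping cohort and look at its ground truth.

Builds a three-generation family segregating a fully penetrant recessive
lethal allele, SNP-array genotypes with LD around the embedded causal
locus, and a candidate-region variant table, then prints what was planted
where.  Every stage is reproducible from the single seed.
"""

from scdmap.simulate import SimConfig, simulate_cohort

config = SimConfig(seed=42)
cohort = simulate_cohort(config)

truth = cohort.truth
print(f"pedigree: {len(cohort.pedigree)} individuals, "
      f"{len(truth.affected_ids)} affected pups ({', '.join(truth.affected_ids)})")
print(f"carriers: {', '.join(truth.carrier_ids)}")
print(f"array data: {cohort.gwas_genotypes.n_samples} samples x "
      f"{cohort.gwas_genotypes.n_markers} markers "
      f"({int(cohort.gwas_genotypes.is_case.sum())} cases)")
v = truth.causal_variant
print(f"planted causal variant: {v.chrom}:{v.pos} {v.ref}>{v.alt} "
      f"(1-bp deletion) in exon of {truth.causal_gene_id}")
print(f"variant table: {len(cohort.variants)} records in the candidate region")

# The affected pups must be homozygous with zero reference-supporting reads:
for pup in truth.affected_ids:
    ref_reads, alt_reads = v.read_counts[pup]
    print(f"  {pup}: genotype {v.genotype_of(pup)}, reads ref/alt = {ref_reads}/{alt_reads}")
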