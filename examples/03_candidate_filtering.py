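"""Whittle a candidate-region variant table down to the causal mutation.

The cascade keeps variants with read evidence, homozygous non-reference
in every genotyped affected pup, inside exons, within genes whose mouse
orthologs show a skeletal phenotype (transferred through synteny blocks),
and absent from other cohorts.
"""

from scdmap.filters import map_synteny, phenotype_restrict, run_filter_cascade
from scdmap.gwas import CandidateRegion
from scdmap.simulate import SKELETAL_QUERY_TERMS, SimConfig, simulate_cohort

config = SimConfig(seed=42)
cohort = simulate_cohort(config)

# project the mapped interval onto the model-organism genome
region = CandidateRegion(config.causal_chrom,
                         config.causal_pos - 8_000_000, config.causal_pos + 8_000_000)
targets = map_synteny(region, cohort.synteny_blocks)
for chrom, start, end in targets:
    print(f"syntenic target interval: {chrom}:{start:,}-{end:,}")

genes = phenotype_restrict(
    [gm.gene_id for gm in cohort.gene_models],
    cohort.phenotype_annotations,
    SKELETAL_QUERY_TERMS,
)
print(f"genes with a skeletal phenotype annotation: {len(genes)} of "
      f"{len(cohort.gene_models)}")

kept, audits = run_filter_cascade(
    cohort.variants,
    cohort.truth.affected_ids,
    cohort.gene_models,
    candidate_genes=genes,
)
for audit in audits:
    print(f"  {audit.stage}: {audit.n_input} -> {audit.n_retained}")
print(f"final candidates: {len(kept)}")
causal = cohort.truth.causal_variant
print("causal deletion retained:",
      any(v.key == causal.key for v in kept))
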