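# Methods

## The mapping problem

A fully penetrant autosomal recessive lethal allele segregating in a
single small family gives a case/control design of a few animals: here,
three affected pups against seven genotyped relatives. No single SNP can
reach genome-wide significance at that sample size, and family structure
violates the independence assumptions of standard GWAS anyway. The
workflow this package implements treats the per-marker test only as a
ranking device: the 100 best-ranked markers are tallied per chromosome,
the most over-represented chromosome is carried forward, and a candidate
interval is refined as the min–max span of that chromosome's markers with
unadjusted p < 0.005. The interval is then intersected with external
knowledge (exons, cross-species phenotype annotation, cross-cohort
genotypes) rather than with more statistics.

## Association statistics

`allelic_chi2` builds the 2×2 allele-count table (each diploid individual
contributes two alleles) and computes Pearson's χ² without continuity
correction, df = 1; the closed form N(ad−bc)²⁄((a+b)(c+d)(a+c)(b+d)) is
the property-tested reference. Tail probabilities are evaluated in log
space (`chi2.logsf`) so statistics of order 150 (p ~ 10⁻³⁶) keep full
relative precision; p-values are reported to at least four significant
figures. `genotypic_chi2` is the companion 2×3 genotype-table test
(df = 2, all-zero columns dropped; fewer than two non-empty columns makes
the test undefined and is reported as NaN with df 0).

On the diagnostic-cohort counts — cases (0, 0, 3), controls (126, 4, 0)
as (hom-wt, het, hom-mut) — the allelic statistic is 157.14 (df 1,
p = 4.759×10⁻³⁶) while the genotypic statistic is 133.0 (df 2). A
published headline value of "χ²(2, N = 133) = 157" can only be the df = 1
allelic statistic despite its df = 2 notation; the package computes both
and leaves the choice explicit.

Marker pruning follows PLINK semantics: a marker is removed when its
pooled-sample MAF is strictly below the threshold or its missing-call
proportion strictly exceeds it, so boundary markers are retained.
Multiple-testing correction is deliberately absent: the method consumes
unadjusted p-values by design.

## Candidate filtering conventions

* Per-sample genotype evidence is the pair of quality-passing read counts
  supporting (ref, alt); the upstream caller is assumed to have applied
  its base/mapping-quality ≥ 20 threshold. A sample with (0, 0) reads has
  an unknown genotype; a record unknown in every sample is dropped.
  Unknown genotypes in affected samples do not veto a candidate (a
  variant homozygous in one affected and unreadable in another stays).
* Indels are VCF-style left-anchored; exon overlap is tested on the
  affected reference bases excluding the anchor, with 1-based inclusive
  interval arithmetic, so a deletion of an exon's terminal base counts as
  exonic.
* Synteny projection interpolates linearly inside each block and honours
  orientation; Mb-scale candidate intervals do not need base-precise
  orthology.
* Phenotype restriction is case-insensitive substring matching over
  free-text annotation terms, mirroring manual phenotype-browser queries;
  ontology traversal is out of scope.
* The quality, zygosity and exon filters are independent and
  order-commutative (property-tested); every stage reports an audit count
  with input = retained + removed.

## Coding consequence

c. coordinates are 1-based with c.1 the A of the initiator ATG.
Deletions and duplications are accepted at any equivalent position but
3'-normalized for reporting, per HGVS convention. Translation uses the
standard genetic code and stops at the first in-frame stop; the stop is
never counted as a residue, so a premature stop "in place of residue 66"
leaves a 65-residue product, and the initiator Met is a residue (ATG TAA
translates to the single residue M). Frameshifts are named
p.(RefPosAltfsTerN) with N = stop − first + 1; a mutant translation that
never reaches a stop is reported with Ter"?". Domain status is
classified as intact (entirely before the first altered residue), lost
(entirely at or beyond the premature stop) or altered (anything
overlapping the changed stretch).

The NMD verdict applies the canonical 50-nt rule only: a premature
termination codon escapes decay iff it lies in the last exon or within
50 nt upstream of the final exon–exon junction; the verdict is returned
together with the distance rather than as a bare label, because the rule
has known exceptions (e.g. AUG-proximal PTCs) that the package does not
model. On the bundled synthetic transcript the PTC at codon 66 is 245 nt
upstream of the final junction and the rule says "targeted"; reports for
real transcripts depend entirely on their exon structure, which is an
input.

The real canine HES7 mRNA is not distributed with the package. The
worked-example transcript is a synthetic construction with the same
geometry: 675-nt CDS, 224-residue product, and a c.126delG consequence of
p.(Thr43ProfsTer24) with residue 42 left synonymous (CCG→CCA, both Pro)
so the first altered residue is 43. The construction is deterministic
and checked base-by-base in its builder.

## PCR-RFLP model

Digestion is combinatorial: IUPAC-aware site scanning on both strands
(overlapping occurrences each cut), a cut at a fixed offset within the
site (midpoint when the enzyme table gives none), fragment lengths as the
differences of cut positions. Cut positions from both strands are kept,
which preserves two invariants exactly — fragments sum to the input
length, and digestion is invariant under reverse complement — at the cost
that a palindromic site with a staggered offset contributes the small
overhang fragment explicitly. Fragment *lengths* drive everything; cut
chemistry, PCR thermodynamics and incubation parameters are not modelled,
and amplicons are exact primer-delimited sequences.

Gel calls operate on distinguishable bands, not fragment multisets: bands
within a relative resolution tolerance (default 5%, matching 1% agarose,
where 578 and 579 bp co-migrate) are merged, a lane is called hom-wt /
hom-mut / het when it matches exactly one expected pattern, and anything
else — including a partial pattern or an assay whose alleles differ by
only an unresolvable shift — is uninterpretable.

The worked-example amplicon is again a synthetic stand-in built to the
assay's geometry: 579-bp wild type with one BsrBI site (canonical core
CCGCTC, embedded in the printed context TCCGCTCC) cutting 107 bp from the
5' end, and the 578-bp single-base-deletion allele uncut.

## Pedigree analysis

Genotypes are mutant-allele counts (0/1/2). `check_mendelian` flags
children whose genotype cannot be composed from one transmissible allele
per parent (untyped parents unconstrained). `test_ar_segregation`
enumerates all genotype assignments consistent with typed data,
phenotypes under full penetrance, and Mendelian transmission
(depth-first, parents first, with pruning — exact for family-scale
pedigrees); the model is consistent iff an assignment exists, obligate
carriers are the non-affected individuals carrying the allele in every
assignment (always including both parents of every affected), and
possible allele sources are the founders carrying it in at least one.
Unknown-phenotype individuals (stillborn but morphologically normal pups)
are excluded from concordance tables but participate in transmission
checks. Penetrance is the point estimate affected-hom-mut / all-hom-mut,
undefined when no typed homozygote exists; only the autosomal recessive
model is tested.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not canine demography. Design choices, with defaults:

* **Family structure.** Three generations: a carrier maternal grandsire
  and wild-type granddam; their carrier daughter (the dam), one carrier
  and two non-carrier further daughters; a carrier founder sire (the
  allele enters twice, as with unrelated imported animals); a litter of
  8 drawn by unconditional Mendelian transmission. Affected ⇔ homozygous
  causal (full penetrance). Litter-level ascertainment is off by default;
  the study-design cohort (`simulate_cohort`) conditions on exactly 3
  affected pups and genotypes 10 animals: the 3 cases plus 7 controls of
  whom 4 are carriers.
* **Markers.** 10 chromosomes × 60 Mb × 500 markers (~5,000 total),
  uniformly placed. Per-marker allele frequencies follow a drifted
  U-shaped Beta(0.5, 0.5): chip markers chosen for cross-breed
  polymorphism sit near fixation inside one breed, and MAF pruning then
  removes roughly half of them, as with real array data.
* **LD.** Founder chromosomes are mosaics of a pool of 8 breed
  haplotypes copied in blocks of mean 1 Mb (the scale of near-complete
  within-breed LD; longer-range partial LD emerges from block sharing).
  Non-founders inherit parental haplotypes with Poisson crossovers at
  1 cM/Mb.
* **The causal haplotype.** Pool haplotype 0 carries the mutation. It is
  an imported, locally rare haplotype: its alleles are drawn
  independently of the local frequencies (Bernoulli ½), and ordinary
  chromosomes copy it with background weight 2%. Every carrier copy
  shares an identical-by-descent segment around the causal position
  (chr5:35,940,090): a guaranteed core flank of 3 Mb per side — the
  embedded locus is by construction a mappable one sitting well inside
  its carrier haplotype, and family meioses do not recombine inside the
  core — plus an exponential one-sided extension of mean 10 Mb. Without
  the core guarantee, exponential truncation immediately beside the
  locus would occasionally leave one flank without informative markers,
  a real phenomenon but not the study condition being emulated.
* **Variants.** The candidate-region table contains a configurable
  number of SNPs and indels with Poisson(10) read depths, a configurable
  exonic fraction, and always the causal exonic 1-bp deletion
  (left-anchored `AG>A`), homozygous with zero reference-supporting
  reads in every affected sample.
* **Reproducibility.** One `numpy` generator seeded from `SimConfig.seed`
  drives every stage; identical configs give byte-identical cohorts.

What the generator does **not** emulate: realistic breed history or
kinship beyond the one family, genotyping error (only missingness),
multi-allelic markers, interference in recombination, and any LD decay
profile beyond block sharing. Passing the recovery tests therefore shows
the pipeline's logic is sound under the assumed tag-SNP structure, not
that real array data of this size always map cleanly.

Measured behaviour at the defaults over 200 independent cohorts: the
top-100 heuristic selects the causal chromosome in ~96% of replicates
(median top-chromosome share ~45%); when selected, the p < 0.005 region
(median span ~16 Mb) contains the causal position in ~99.5% of
replicates; the filter cascade retains the causal deletion in 100%.
The residual containment misses are replicates whose flanking markers
happen to be uninformative on one side — the acceptance script reports
the rates it actually measures for its seed.

## Problem sizes

Unit tests run on miniature cohorts (3 chromosomes × 80 markers);
recovery tests and the acceptance script use 50 cohorts at the default
10 × 500-marker configuration, which completes in a few seconds on one
CPU. Randomised property tests are seeded (or hypothesis-derandomized)
for determinism.
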