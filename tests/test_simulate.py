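"""Synthetic-cohort generator: Mendelian structure, LD construction,
variant tables, and reproducibility."""

import numpy as np
import pytest

from scdmap.gwas import MISSING
from scdmap.pedigree import AFFECTED, check_mendelian
from scdmap.pedigree import test_ar_segregation as ar_segregation
from scdmap.simulate import (
    SimConfig,
    pool_copy_weights,
    simulate_cohort,
    simulate_founder_pool,
    simulate_gene_models,
    simulate_genotypes,
    simulate_pedigree,
    simulate_region_variants,
)
from scdmap.variants import GENOTYPE_UNKNOWN


class TestSimConfig:
    def test_rejects_zero_litter(self):
        with pytest.raises(ValueError):
            SimConfig(litter_size=0)

    def test_rejects_bad_missing_rate(self):
        with pytest.raises(ValueError):
            SimConfig(missing_rate=1.5)

    def test_rejects_causal_position_outside_chromosome(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length_bp=1_000, causal_pos=2_000)


class TestSimulatePedigree:
    def test_carrier_cross_quarter_affected(self, small_config):
        """Mendelian oracle: carrier x carrier pups are affected with
        probability 1/4; 10,000 pups must fall within 3 binomial SEs."""
        config = SimConfig(litter_size=8, seed=5)
        rng = np.random.default_rng(5)
        n = affected = 0
        while n < 10_000:
            pedigree = simulate_pedigree(config, rng=rng)
            pups = [i for i in pedigree if i.sire == "SIRE"]
            affected += sum(i.phenotype == AFFECTED for i in pups)
            n += len(pups)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(affected / n - 0.25) < 3 * se

    def test_carrier_by_wild_type_never_affected(self, small_config):
        """The grandsire x granddam mating (carrier x hom-wt) yields no
        affected offspring and carriers at rate ~1/2 among its free draws."""
        rng = np.random.default_rng(7)
        from scdmap.simulate import _mendelian_child_alleles

        draws = [
            _mendelian_child_alleles((1, 0), (0, 0), rng) for _ in range(10_000)
        ]
        assert all(sum(pair) < 2 for pair in draws)
        carrier_fraction = np.mean([sum(pair) == 1 for pair in draws])
        assert abs(carrier_fraction - 0.5) < 3 * np.sqrt(0.25 / len(draws))

    def test_full_penetrance_link(self, small_config):
        for seed in range(10):
            pedigree = simulate_pedigree(small_config, rng=np.random.default_rng(seed))
            for ind in pedigree:
                hom = sum(pedigree.causal_alleles[ind.id]) == 2
                assert (ind.phenotype == AFFECTED) == hom

    def test_ascertainment_fixes_affected_count(self, small_config):
        for seed in range(5):
            pedigree = simulate_pedigree(
                small_config, rng=np.random.default_rng(seed), ascertain_affected=3
            )
            assert len(pedigree.affected()) == 3

    def test_ar_segregation_consistent_on_simulated(self, small_config):
        for seed in range(10):
            pedigree = simulate_pedigree(small_config, rng=np.random.default_rng(seed))
            if not pedigree.affected():
                continue
            assert ar_segregation(pedigree).consistent


class TestSimulateGenotypes:
    def test_no_missing_when_rate_zero(self, small_config):
        from dataclasses import replace

        config = replace(small_config, missing_rate=0.0)
        pedigree = simulate_pedigree(config, rng=np.random.default_rng(1))
        g = simulate_genotypes(pedigree, config, rng=np.random.default_rng(1))
        assert not (g.genotypes == MISSING).any()

    def test_affected_share_identical_core_haplotype(self, small_config):
        """All affected pups are homozygous for the same carrier haplotype
        across the protected core around the causal position."""
        cohort = simulate_cohort(small_config)
        g = cohort.genotypes
        chr_mask = (g.marker_map["chrom"] == small_config.causal_chrom).to_numpy()
        bp = g.marker_map["bp"].to_numpy()
        core = chr_mask & (
            np.abs(bp - small_config.causal_pos) <= small_config.causal_ibd_core_bp
        )
        rows = [g.sample_ids.index(s) for s in cohort.truth.affected_ids]
        core_geno = g.genotypes[np.ix_(rows, np.flatnonzero(core))]
        for j in range(core_geno.shape[1]):
            called = core_geno[:, j][core_geno[:, j] != MISSING]
            assert len(set(called.tolist())) <= 1  # identical across cases
            assert all(c in (0, 2) for c in called)  # and homozygous

    def test_founder_heterozygosity_matches_pool_enumeration(self):
        """Mean founder heterozygosity agrees with brute-force enumeration
        over the weighted founder-haplotype pool, within 3 SEs over
        replicate cohorts."""
        diffs = []
        for seed in range(25):
            config = SimConfig(
                n_chromosomes=2,
                chrom_length_bp=8_000_000,
                n_markers_per_chrom=120,
                causal_chrom="chr2",
                causal_pos=4_000_000,
                missing_rate=0.0,
                seed=seed,
            )
            rng = config.rng()
            from scdmap.simulate import _marker_positions

            positions = _marker_positions(config, rng)
            pool = simulate_founder_pool(config, rng)
            weights = pool_copy_weights(config)
            # brute-force enumeration: P(het) at a marker is the probability
            # that two independent weighted draws from the pool disagree
            alleles = pool["chr1"].astype(float)
            p1 = weights @ alleles
            expected = float(np.mean(2 * p1 * (1 - p1)))

            pedigree = simulate_pedigree(config, rng=rng)
            g = simulate_genotypes(pedigree, config, rng=rng)
            chr1 = (g.marker_map["chrom"] == "chr1").to_numpy()
            founders = [g.sample_ids.index(f) for f in ("M_GS", "M_GD", "SIRE")]
            observed = float((g.genotypes[np.ix_(founders, np.flatnonzero(chr1))] == 1).mean())
            diffs.append(observed - expected)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se


class TestSimulateRegionVariants:
    @pytest.fixture()
    def setup(self, small_config):
        rng = np.random.default_rng(3)
        models, causal_gene = simulate_gene_models(small_config, rng=rng, n_genes=10)
        return small_config, models, causal_gene, rng

    def test_only_causal_when_minimal(self, setup):
        config, models, causal_gene, rng = setup
        variants, causal = simulate_region_variants(
            config, models, causal_gene,
            sample_ids=["a1", "a2", "c1"], affected_ids=["a1", "a2"],
            carrier_ids=["c1"], n_snps=0, n_indels=1, rng=rng,
        )
        assert variants == [causal]

    def test_affecteds_hom_alt_with_zero_ref_reads(self, setup):
        config, models, causal_gene, rng = setup
        _, causal = simulate_region_variants(
            config, models, causal_gene,
            sample_ids=["a1", "a2", "c1"], affected_ids=["a1", "a2"],
            carrier_ids=["c1"], n_snps=5, n_indels=2, rng=rng,
        )
        for s in ("a1", "a2"):
            assert causal.genotype_of(s) == 2
            ref_reads, alt_reads = causal.read_counts[s]
            assert ref_reads == 0 and alt_reads > 0

    def test_exonic_fraction_recount(self, setup):
        config, models, causal_gene, rng = setup
        variants, causal = simulate_region_variants(
            config, models, causal_gene,
            sample_ids=["a1"], affected_ids=["a1"], carrier_ids=[],
            n_snps=400, n_indels=5, exonic_fraction=0.1, rng=rng,
        )

        def exonic(v):
            start, end = v.affected_span()
            return any(
                gm.overlaps_exon(v.chrom, start, end) for gm in models
            )

        n_exonic = sum(exonic(v) for v in variants if v.key != causal.key)
        n = len(variants) - 1
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(n_exonic / n - 0.1) < 3 * se
        assert exonic(causal)

    def test_causal_not_exonic_raises(self, setup):
        config, models, causal_gene, rng = setup
        intronic_only = [
            gm for gm in models if gm.gene_id != causal_gene
        ]
        with pytest.raises(ValueError, match="exonic|causal"):
            simulate_region_variants(
                config, intronic_only, intronic_only[0].gene_id,
                sample_ids=["a1"], affected_ids=["a1"], carrier_ids=[], rng=rng,
            )


class TestCohort:
    def test_byte_identical_reproducibility(self, small_config):
        c1 = simulate_cohort(small_config)
        c2 = simulate_cohort(small_config)
        assert np.array_equal(c1.genotypes.genotypes, c2.genotypes.genotypes)
        assert c1.genotypes.marker_map.equals(c2.genotypes.marker_map)
        assert [v.key for v in c1.variants] == [v.key for v in c2.variants]
        assert all(
            v1.read_counts == v2.read_counts
            for v1, v2 in zip(c1.variants, c2.variants)
        )
        assert c1.truth.causal_gene_id == c2.truth.causal_gene_id

    def test_truth_record_invariants(self, small_cohort):
        truth = small_cohort.truth
        pedigree = small_cohort.pedigree
        for iid in truth.affected_ids:
            assert sum(pedigree.causal_alleles[iid]) == 2
            assert truth.causal_variant.genotype_of(iid) in (2, GENOTYPE_UNKNOWN)
            sire, dam = pedigree.parents_of(iid)
            for parent in (sire, dam):
                assert sum(pedigree.causal_alleles[parent]) >= 1
        assert truth.causal_chrom == small_cohort.config.causal_chrom

    def test_gwas_subset_is_three_cases_seven_controls(self, small_cohort):
        g = small_cohort.gwas_genotypes
        assert g.n_samples == 10
        assert int(g.is_case.sum()) == 3

    def test_simulated_trios_mendelian_clean(self, small_cohort):
        assert check_mendelian(small_cohort.pedigree) == []

    def test_causal_gene_contains_locus_in_exon(self, small_cohort):
        config = small_cohort.config
        causal_gene = next(
            gm
            for gm in small_cohort.gene_models
            if gm.gene_id == small_cohort.truth.causal_gene_id
        )
        assert causal_gene.overlaps_exon(
            config.causal_chrom, config.causal_pos, config.causal_pos
        )

    def test_synteny_blocks_cover_region_on_two_targets(self, small_cohort):
        targets = {b.target_chrom for b in small_cohort.synteny_blocks}
        assert len(targets) == 2


def test_write_cohort_creates_standard_formats(tmp_path, small_cohort):
    from scdmap.simulate import write_cohort

    paths = write_cohort(small_cohort, tmp_path)
    for key in ("pedigree", "ped", "map", "vcf", "exons", "synteny", "phenotypes"):
        assert paths[key].exists() and paths[key].stat().st_size > 0
    # BED is 0-based half-open: first exon row must match the gene model
    first = paths["exons"].read_text().splitlines()[0].split("\t")
    gm = small_cohort.gene_models[0]
    assert int(first[1]) == gm.exons[0][0] - 1
    assert int(first[2]) == gm.exons[0][1]
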