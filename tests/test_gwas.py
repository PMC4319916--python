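"""Marker pruning, chi-squared association tests, top-K enrichment,
and candidate-region refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from scdmap.gwas import (
    MISSING,
    AssociationResult,
    GenotypeMatrix,
    allelic_chi2,
    association_scan,
    genotypic_chi2,
    prune_markers,
    read_ped_map,
    refine_region,
    top_k_chromosome_enrichment,
    write_ped_map,
)


def make_matrix(genotypes, chroms=None, is_case=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    chroms = chroms or ["chr1"] * m
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        marker_map=pd.DataFrame({"chrom": chroms, "bp": np.arange(1, m + 1) * 1000}),
        genotypes=genotypes,
        is_case=np.zeros(n, dtype=bool) if is_case is None else np.asarray(is_case),
    )


class TestAllelicChi2:
    def test_cohort_worked_example(self):
        """3 hom-mutant cases vs 126 hom-wt + 4 het controls: the published
        genotyping outcome of the 133-dog cohort."""
        r = allelic_chi2((0, 0, 3), (126, 4, 0))
        assert round(r.chi2) == 157
        assert r.chi2 == pytest.approx(157.1446, abs=1e-3)
        assert r.df == 1
        assert r.p == pytest.approx(4.759e-36, rel=1e-3)

    def test_identical_distributions_null(self):
        r = allelic_chi2((5, 3, 2), (5, 3, 2))
        assert r.chi2 == 0.0
        assert r.p == 1.0

    def test_perfect_separation_small(self):
        # allele table a=4,b=0 / c=0,d=4 -> N(ad-bc)^2/(rows*cols) = 8
        r = allelic_chi2((0, 0, 2), (2, 0, 0))
        assert r.chi2 == pytest.approx(8.0)

    def test_zero_alleles_in_group_raises(self):
        with pytest.raises(ValueError):
            allelic_chi2((0, 0, 0), (1, 0, 0))

    def test_monomorphic_site_uninformative(self):
        r = allelic_chi2((2, 0, 0), (3, 0, 0))
        assert r.chi2 == 0.0 and r.p == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 30), min_size=6, max_size=6))
    def test_matches_independent_contingency_oracle(self, counts):
        """The hand-rolled statistic equals scipy's Pearson chi-squared
        (no continuity correction) on the 2x2 allele table."""
        case, control = counts[:3], counts[3:]
        a = 2 * case[0] + case[1]
        b = 2 * case[2] + case[1]
        c = 2 * control[0] + control[1]
        d = 2 * control[2] + control[1]
        if a + b == 0 or c + d == 0:
            return
        r = allelic_chi2(case, control)
        if (a + c) == 0 or (b + d) == 0:
            assert r.chi2 == 0.0
            return
        expected = chi2_contingency([[a, b], [c, d]], correction=False)
        assert r.chi2 == pytest.approx(expected.statistic, rel=1e-12, abs=1e-12)
        assert r.p == pytest.approx(expected.pvalue, rel=1e-9, abs=1e-300)


class TestGenotypicChi2:
    def test_cohort_worked_example_df2(self):
        r = genotypic_chi2((0, 0, 3), (126, 4, 0))
        oracle = chi2_contingency([[0, 0, 3], [126, 4, 0]], correction=False)
        assert r.df == 2
        assert r.chi2 == pytest.approx(oracle.statistic, rel=1e-12)
        # the df=1 allelic value (~157), not this one, matches the published
        # "chi-squared = 157" headline
        assert r.chi2 == pytest.approx(133.0, abs=0.1)

    def test_identical_distributions_null(self):
        assert genotypic_chi2((4, 4, 2), (4, 4, 2)).chi2 == pytest.approx(0.0)

    def test_single_genotype_column_undefined(self):
        r = genotypic_chi2((5, 0, 0), (7, 0, 0))
        assert r.df == 0
        assert np.isnan(r.chi2)


class TestPruneMarkers:
    def test_monomorphic_removed(self):
        g = make_matrix([[0], [0], [0], [0]])
        pruned, report = prune_markers(g)
        assert pruned.n_markers == 0
        assert report.n_removed_maf == 1

    def test_exact_maf_boundary_retained(self):
        # 10 samples, 2/20 alt alleles: MAF exactly 0.1, no missing calls
        col = [1, 1] + [0] * 8
        g = make_matrix(np.array([col]).T)
        pruned, _ = prune_markers(g, maf_min=0.1)
        assert pruned.n_markers == 1

    def test_missingness_strictly_above_threshold_removed(self):
        col = [MISSING, MISSING, MISSING, 1, 1, 0, 0, 1, 0, 1]  # 3/10 missing
        g = make_matrix(np.array([col]).T)
        pruned, report = prune_markers(g, max_missing=0.2)
        assert pruned.n_markers == 0
        assert report.n_removed_missing == 1

    def test_exact_missingness_boundary_retained(self):
        col = [MISSING, MISSING, 1, 1, 0, 0, 1, 0, 1, 1]  # 2/10 missing
        g = make_matrix(np.array([col]).T)
        pruned, _ = prune_markers(g, max_missing=0.2)
        assert pruned.n_markers == 1

    def test_idempotent(self, rng):
        geno = rng.integers(-1, 3, size=(12, 60)).astype(np.int8)
        g = make_matrix(geno)
        once, _ = prune_markers(g)
        twice, report = prune_markers(once)
        assert report.n_retained == once.n_markers
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_audit_counts_balance(self, rng):
        geno = rng.integers(-1, 3, size=(10, 80)).astype(np.int8)
        _, report = prune_markers(make_matrix(geno))
        assert report.n_input == report.n_retained + report.n_removed_maf + report.n_removed_missing


def test_association_scan_agrees_with_scalar_test(rng):
    """The vectorised scan must reproduce the scalar reference per marker."""
    geno = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
    is_case = np.array([True] * 3 + [False] * 7)
    g = make_matrix(geno, is_case=is_case)
    results = association_scan(g)
    for j, r in enumerate(results):
        col = geno[:, j]
        triples = []
        for grp in (is_case, ~is_case):
            calls = col[grp & (col != MISSING)]
            triples.append([int((calls == k).sum()) for k in (0, 1, 2)])
        if sum(triples[0]) == 0 or sum(triples[1]) == 0:
            assert np.isnan(r.p)
            continue
        ref = allelic_chi2(*triples)
        assert r.chi2 == pytest.approx(ref.chi2, rel=1e-9, abs=1e-12)
        assert r.p == pytest.approx(ref.p, rel=1e-9, abs=1e-300)


def fake_results(rows):
    """rows: list of (chrom, bp, p)."""
    return [
        AssociationResult(f"m{i}", chrom, bp, 1.0, 1, p, 0.2)
        for i, (chrom, bp, p) in enumerate(rows)
    ]


class TestTopKEnrichment:
    def test_single_chromosome_proportion_one(self):
        results = fake_results([("chr3", 1000 * i, 1e-5) for i in range(10)])
        props, candidate = top_k_chromosome_enrichment(results, k=10)
        assert candidate == "chr3"
        assert props["chr3"] == 1.0

    def test_constructed_60_13_8_split(self):
        """60 of the top 100 markers on chr5, 13 on chr18, 8 on chr12."""
        rows = (
            [("chr5", i * 100, 1e-6) for i in range(60)]
            + [("chr18", i * 100, 1e-5) for i in range(13)]
            + [("chr12", i * 100, 1e-4) for i in range(8)]
            + [(f"chr{1 + i % 4}", i * 100, 1e-3) for i in range(19)]
            + [("chr9", i * 100, 0.9) for i in range(200)]
        )
        props, candidate = top_k_chromosome_enrichment(fake_results(rows), k=100)
        assert candidate == "chr5"
        assert props["chr5"] == pytest.approx(0.60)
        assert props["chr18"] == pytest.approx(0.13)
        assert props["chr12"] == pytest.approx(0.08)
        assert props.sum() == pytest.approx(1.0)

    def test_ties_broken_deterministically(self, rng):
        rows = [(f"chr{1 + i % 5}", 1000 + i, 0.01) for i in range(50)]
        results = fake_results(rows)
        props1, cand1 = top_k_chromosome_enrichment(results, k=20)
        shuffled = list(results)
        rng.shuffle(shuffled)
        props2, cand2 = top_k_chromosome_enrichment(shuffled, k=20)
        assert cand1 == cand2
        assert props1.equals(props2)

    def test_k_exceeding_markers_raises(self):
        with pytest.raises(ValueError):
            top_k_chromosome_enrichment(fake_results([("chr1", 1, 0.5)]), k=2)


class TestRefineRegion:
    def test_span_of_passing_markers(self):
        results = fake_results(
            [
                ("chr5", 10_000_000, 0.001),
                ("chr5", 20_000_000, 0.1),
                ("chr5", 30_000_000, 0.002),
                ("chr5", 40_000_000, 0.5),
            ]
        )
        region = refine_region(results, 0.005)
        assert (region.chrom, region.start, region.end) == ("chr5", 10_000_000, 30_000_000)

    def test_no_passing_marker_returns_none(self):
        assert refine_region(fake_results([("chr5", 1, 0.9)]), 0.005) is None

    def test_single_marker_degenerate_region(self):
        region = refine_region(fake_results([("chr5", 35_940_090, 1e-4)]), 0.005)
        assert region.start == region.end == 35_940_090

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            refine_region(fake_results([("chr1", 1, 0.5), ("chr2", 2, 0.5)]))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(1, 10**7), st.floats(1e-10, 1.0)),
            min_size=1,
            max_size=30,
        ),
        st.floats(1e-6, 0.5),
        st.floats(1e-6, 0.5),
    )
    def test_nested_thresholds_give_nested_regions(self, markers, t1, t2):
        lo, hi = sorted((t1, t2))
        results = fake_results([("chr1", bp, p) for bp, p in markers])
        inner = refine_region(results, lo)
        outer = refine_region(results, hi)
        if inner is not None:
            assert outer is not None
            assert outer.start <= inner.start <= inner.end <= outer.end


def test_ped_map_round_trip(tmp_path, small_cohort):
    g = small_cohort.gwas_genotypes
    write_ped_map(g, tmp_path / "cohort")
    back = read_ped_map(tmp_path / "cohort")
    assert back.sample_ids == g.sample_ids
    assert back.marker_ids == g.marker_ids
    assert np.array_equal(back.genotypes, g.genotypes)
    assert np.array_equal(back.is_case, g.is_case)
    assert back.marker_map["bp"].tolist() == g.marker_map["bp"].tolist()
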