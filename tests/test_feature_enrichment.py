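import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from g4atlas.feature_enrichment import (
    associated,
    count_associated,
    empirical_p,
    enrichment_test,
    qvalues,
    select_top_expressed,
    strand_bias_in_genes,
)
from g4atlas.matched_controls import build_control_sets
from g4atlas.sequence_io import AnnotationTrack, GenomeSequence, GenomicInterval


def iv(start, end, chrom="c", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestAssociated:
    def test_adjacency_boundary(self):
        assert not associated(iv(0, 10), iv(10, 20), window=0)
        assert associated(iv(0, 10), iv(10, 20), window=1)

    def test_gap_exactly_window(self):
        assert associated(iv(0, 10), iv(310, 320), window=300)
        assert not associated(iv(0, 10), iv(311, 320), window=300)

    def test_symmetry_and_chromosomes(self):
        assert associated(iv(310, 320), iv(0, 10), window=300)
        assert not associated(
            iv(0, 10), GenomicInterval("d", 0, 10), window=500
        )

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            associated(iv(0, 10), iv(20, 30), window=-1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 50),
        s2=st.integers(0, 500), l2=st.integers(1, 50),
        w=st.integers(0, 100),
    )
    def test_window_monotone(self, s1, l1, s2, l2, w):
        a, b = iv(s1, s1 + l1), iv(s2, s2 + l2)
        if associated(a, b, window=w):
            assert associated(a, b, window=w + 1)


class TestCountAssociated:
    def test_query_counted_once(self):
        motifs = [iv(0, 10), iv(100, 110), iv(200, 210)]
        feature = [iv(5, 105)]  # overlaps two motifs
        assert count_associated(motifs, feature, 0) == 2

    def test_empty_subject(self):
        assert count_associated([iv(0, 10)], [], 0) == 0

    def test_matches_all_pairs_brute_force(self, rng):
        from conftest import random_track

        lengths = {"chr1": 10_000, "chr2": 5_000}
        for w in (0, 50, 300):
            q = random_track(rng, 80, lengths, stranded=False, max_len=200)
            s = random_track(rng, 60, lengths, stranded=False, max_len=200)
            brute = sum(
                1
                for a in q.intervals
                if any(associated(a, b, w) for b in s.intervals)
            )
            assert count_associated(q, s, w) == brute


class TestEmpiricalP:
    def test_observed_beyond_all_nulls(self):
        p = empirical_p(54, list(range(54)), "enriched")
        assert p == pytest.approx(1 / 55)
        p1000 = empirical_p(54, [0] * 1000, "enriched")
        assert p1000 == pytest.approx(1 / 1001)

    def test_all_ties_give_one(self):
        assert empirical_p(7, [7] * 100, "enriched") == 1.0
        assert empirical_p(7, [7] * 100, "depleted") == 1.0

    def test_uniform_null_direct_count(self):
        nulls = [v for v in range(5, 15) for _ in range(100)]
        p = empirical_p(10, nulls, "enriched")
        assert p == pytest.approx((500 + 1) / 1001)

    def test_literal_mode(self):
        assert empirical_p(10, [0] * 1000, "enriched", mode="literal") == 0.0

    def test_two_sided_sum_at_least_one(self, rng):
        nulls = rng.poisson(20, size=500)
        for obs in (10, 20, 30):
            pe = empirical_p(obs, nulls, "enriched")
            pd = empirical_p(obs, nulls, "depleted")
            assert pe + pd >= 1.0

    def test_super_uniform_under_null(self, rng):
        """Add-one empirical P with the observed drawn from the same
        generator as the null is a valid (super-uniform) P-value."""
        n_sets, reps = 100, 1000
        draws = rng.poisson(12, size=(reps, n_sets + 1))
        ps = np.array(
            [empirical_p(d[0], d[1:], "enriched") for d in draws]
        )
        for alpha in (0.01, 0.05, 0.1):
            frac = np.mean(ps <= alpha)
            slack = 3 * np.sqrt(alpha * (1 - alpha) / reps)
            assert frac <= alpha + slack


@pytest.fixture(scope="module")
def enrichment_setup():
    from g4atlas.synthetic_data import (
        FeatureClassSpec,
        SimulationSpec,
        plant_motifs,
        random_genome,
        synth_features,
    )

    spec = SimulationSpec(
        chrom_lengths=(150_000,), gc_fraction=0.36,
        n_planted_motifs=60, seed=13,
        feature_classes=(
            FeatureClassSpec("promoters", 60, 200, 20, motif_colocation=0.5),
        ),
    )
    rng = np.random.default_rng(13)
    g = random_genome(spec, rng)
    g, truth = plant_motifs(g, spec, rng)
    feats = synth_features(g, spec, truth, rng)
    coll = build_control_sets(truth, g, n_sets=100, seed=2)
    return g, truth, feats["promoters"], coll


class TestEnrichmentTest:
    @pytest.fixture
    def setup(self, enrichment_setup):
        return enrichment_setup

    def test_planted_enrichment_detected(self, setup):
        g, truth, promoters, coll = setup
        res = enrichment_test(truth, coll, promoters, window=0)
        assert res.direction == "enriched"
        assert res.p_value <= 0.05
        assert res.observed_overlap > res.expected_overlap

    def test_saturating_feature_gives_p_one_in_literal_mode(self, setup):
        g, truth, _, coll = setup
        whole = AnnotationTrack(
            "genome", [GenomicInterval("chr1", 0, 150_000)]
        )
        res = enrichment_test(truth, coll, whole, window=0, mode="literal")
        assert res.observed_overlap == len(truth)
        assert res.expected_overlap == len(truth)
        assert res.p_value == 1.0

    def test_unreachable_feature_observed_zero(self, setup):
        g, truth, _, coll = setup
        far = AnnotationTrack("far", [GenomicInterval("chrX", 0, 100)])
        res = enrichment_test(truth, coll, far, window=0)
        assert res.observed_overlap == 0

    def test_cardinality_mismatch_rejected(self, setup):
        g, truth, promoters, coll = setup
        sub = AnnotationTrack("sub", truth.intervals[:5])
        with pytest.raises(ValueError):
            enrichment_test(sub, coll, promoters)


class TestQValues:
    def test_all_ones(self):
        assert np.all(qvalues([1.0, 1.0, 1.0]) == 1.0)

    def test_pi0_one_equals_bh(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            p = rng.uniform(1e-8, 1, size=n)
            ours = qvalues(p, pi0=1.0)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_pi0_estimate_range(self, rng):
        p = np.concatenate([rng.uniform(size=400), rng.uniform(0, 0.01, 100)])
        q = qvalues(p)
        assert np.all((q >= 0) & (q <= 1))

    def test_fallback_below_20_tests(self, rng):
        p = rng.uniform(size=10)
        np.testing.assert_allclose(
            qvalues(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestStrandBias:
    def gene(self, start, end, strand, chrom="c"):
        return GenomicInterval(chrom, start, end, strand)

    def test_transcribed_strand_convention(self):
        # motif on '-' inside a '+' gene lies on the template strand
        motifs = AnnotationTrack("m", [iv(10, 20, strand="-")])
        genes = AnnotationTrack("g", [self.gene(0, 100, "+")])
        k, n, p = strand_bias_in_genes(motifs, genes)
        assert (k, n) == (1, 1)

    def test_published_counts_give_tiny_p(self):
        p = stats.binomtest(219, 303, 0.5).pvalue
        assert p < 1e-12

    def test_balanced_counts_in_p_one_region(self):
        # at exactly half, every outcome ties into the minimum-likelihood
        # two-sided sum, so the exact P is 1
        p = stats.binomtest(150, 300, 0.5).pvalue
        assert p == 1.0
        # just off-centre the P is still near 1
        assert stats.binomtest(153, 300, 0.5).pvalue > 0.7

    def test_binomial_against_exact_sum_oracle(self):
        from math import comb

        k, n = 37, 60
        pk = comb(n, k) * 0.5**n
        oracle = sum(
            comb(n, i) * 0.5**n
            for i in range(n + 1)
            if comb(n, i) * 0.5**n <= pk * (1 + 1e-12)
        )
        got = stats.binomtest(k, n, 0.5).pvalue
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_largest_overlap_resolution(self):
        motifs = AnnotationTrack("m", [iv(10, 30, strand="+")])
        genes = AnnotationTrack(
            "g",
            [self.gene(0, 15, "+"), self.gene(12, 100, "-")],
        )
        # overlap with second gene (18 bp) beats first (5 bp); motif '+'
        # within a '-' gene lies on the template strand, so resolution to
        # the larger overlap flips the call relative to the first gene
        k, n, p = strand_bias_in_genes(motifs, genes)
        assert (k, n) == (1, 1)

    def test_unstranded_gene_rejected(self):
        motifs = AnnotationTrack("m", [iv(10, 30, strand="+")])
        genes = AnnotationTrack("g", [iv(0, 100, strand=".")])
        with pytest.raises(ValueError):
            strand_bias_in_genes(motifs, genes)

    def test_planted_bias_recovered(self, rng):
        """Genes with 50/50 strands; motifs planted on the template strand
        are recovered as such."""
        genes, motifs = [], []
        for i in range(40):
            gs = ("+", "-")[i % 2]
            start = i * 1000
            genes.append(self.gene(start, start + 800, gs))
            motifs.append(
                iv(start + 100, start + 130,
                   strand="-" if gs == "+" else "+")
            )
        k, n, p = strand_bias_in_genes(
            AnnotationTrack("m", motifs), AnnotationTrack("g", genes)
        )
        assert (k, n) == (40, 40)
        assert p < 1e-9


class TestSelectTopExpressed:
    def make_track(self, expressions):
        return AnnotationTrack(
            "genes",
            [iv(i * 100, i * 100 + 50, strand="+") for i in range(len(expressions))],
            [
                {"gene_id": f"g{i:03d}", "expression": e}
                for i, e in enumerate(expressions)
            ],
        )

    def test_top_n(self):
        track = self.make_track([5.0, 1.0, 9.0, 3.0, 7.0])
        top = select_top_expressed(track, 3)
        assert [a["gene_id"] for a in top.attributes] == ["g002", "g004", "g000"]

    def test_n_larger_than_track(self):
        track = self.make_track([1.0, 2.0])
        assert len(select_top_expressed(track, 10)) == 2

    def test_matches_sort_oracle(self, rng):
        exprs = list(rng.uniform(0, 100, size=50))
        track = self.make_track(exprs)
        top = select_top_expressed(track, 20)
        oracle = sorted(
            range(50), key=lambda i: (-exprs[i], f"g{i:03d}")
        )[:20]
        assert [a["gene_id"] for a in top.attributes] == [
            f"g{i:03d}" for i in oracle
        ]

    def test_missing_expression_rejected(self):
        track = AnnotationTrack(
            "g", [iv(0, 10)], [{"gene_id": "a"}]
        )
        with pytest.raises(ValueError):
            select_top_expressed(track, 1)
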