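import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svgraph.breakpoint_genotyper import (
    GenotypingParams,
    depth_test,
    error_likelihood,
    fisher_strand_phred,
    genotype_breakpoint,
    genotype_posterior,
    het_likelihood,
    hom_likelihood,
    poisson_lambda,
    strand_table,
)
from svgraph.errors import GenotypingError
from svgraph.graph_align import BreakpointCounts

from oracles import fisher_exact_two_sided, normal_sf, poisson_pmf

HAPS = ("ALT", "REF")


def make_counts(r_ref=0, r_alt=0, neither=0, ref_strands=None, alt_strands=None):
    c = BreakpointCounts("bp", HAPS)
    c.counts["REF"] = r_ref
    c.counts["ALT"] = r_alt
    c.neither = neither
    c.strands["REF"] = list(ref_strands or [r_ref - r_ref // 2, r_ref // 2])
    c.strands["ALT"] = list(alt_strands or [r_alt - r_alt // 2, r_alt // 2])
    return c


class TestPoissonLambda:
    def test_spec_values(self):
        assert poisson_lambda(30, 150, 15) == pytest.approx(27.0)
        assert poisson_lambda(35, 150, 15) == pytest.approx(31.5)

    def test_zero_overlap_gives_depth(self):
        assert poisson_lambda(30, 150, 0) == pytest.approx(30.0)

    def test_overlap_at_least_read_length_rejected(self):
        with pytest.raises(GenotypingError):
            poisson_lambda(30, 150, 150)

    def test_default_overlap_is_ten_percent(self):
        p = GenotypingParams(depth=30, read_length=150)
        assert p.overlap_bases == 15
        assert p.lam() == pytest.approx(27.0)


class TestLikelihoods:
    def params(self, depth=30.0, eps=0.01, **kw):
        # lambda = depth * (150-15)/150 = 0.9 * depth
        return GenotypingParams(depth=depth, read_length=150, eps=eps, **kw)

    def test_het_likelihood_matches_pmf_oracle(self):
        params = self.params(depth=20 / 0.9)  # lambda = 20
        counts = make_counts(r_ref=10, r_alt=10)
        expected = poisson_pmf(10, 10.0) ** 2
        assert het_likelihood(counts, "REF", "ALT", params) == pytest.approx(expected, rel=1e-9)

    def test_het_zero_counts_closed_form(self):
        params = self.params(depth=30)  # lambda = 27
        counts = make_counts()
        assert het_likelihood(counts, "REF", "ALT", params) == pytest.approx(math.exp(-27.0), rel=1e-9)

    def test_het_symmetry(self):
        params = self.params()
        c1 = make_counts(r_ref=7, r_alt=13)
        assert het_likelihood(c1, "REF", "ALT", params) == pytest.approx(
            het_likelihood(c1, "ALT", "REF", params), rel=1e-12
        )

    def test_het_requires_distinct_haplotypes(self):
        with pytest.raises(GenotypingError):
            het_likelihood(make_counts(), "REF", "REF", self.params())

    def test_hom_likelihood_matches_pmf_oracle(self):
        params = self.params(depth=20 / 0.9, eps=0.05)  # mean 19
        counts = make_counts(r_ref=19)
        assert hom_likelihood(counts, "REF", params) == pytest.approx(
            poisson_pmf(19, 19.0), rel=1e-9
        )

    def test_hom_zero_eps_zero_count(self):
        params = self.params(depth=30, eps=0.0)
        assert hom_likelihood(make_counts(), "REF", params) == pytest.approx(math.exp(-27.0), rel=1e-9)

    def test_hom_monotone_decreasing_in_lambda_above_count(self):
        counts = make_counts(r_ref=5)
        values = [
            hom_likelihood(counts, "REF", self.params(depth=d, eps=0.0)) for d in (10, 20, 30, 40)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_error_likelihood_zero_eps(self):
        params = self.params(eps=0.0)
        assert error_likelihood(make_counts(neither=0), params) == pytest.approx(1.0)
        assert error_likelihood(make_counts(neither=3), params) == 0.0

    def test_error_likelihood_closed_form(self):
        params = self.params(depth=20 / 0.9, eps=0.05)  # lambda*eps = 1.0
        assert error_likelihood(make_counts(neither=1), params) == pytest.approx(
            math.exp(-1.0), rel=1e-9
        )


class TestGenotypePosterior:
    def params(self, **kw):
        return GenotypingParams(depth=30, read_length=150, eps=0.01, **kw)

    def test_hom_alt_recovery(self):
        gl = genotype_posterior(make_counts(r_alt=30), self.params())
        assert gl.best == ("ALT", "ALT")

    def test_het_recovery(self):
        gl = genotype_posterior(make_counts(r_ref=13, r_alt=14), self.params())
        assert gl.best == ("ALT", "REF")

    def test_matches_enumeration_oracle(self):
        lam = 27.0
        eps = 0.01
        r_alt, r_ref, neither = 30, 0, 0
        total = r_alt + r_ref + neither
        oracle = {
            ("ALT", "ALT"): poisson_pmf(r_alt, lam * (1 - eps))
            * poisson_pmf(total - r_alt, lam * eps),
            ("ALT", "REF"): poisson_pmf(r_alt, lam / 2)
            * poisson_pmf(r_ref, lam / 2)
            * poisson_pmf(neither, lam * eps),
            ("REF", "REF"): poisson_pmf(r_ref, lam * (1 - eps))
            * poisson_pmf(total - r_ref, lam * eps),
        }
        best_oracle = max(oracle, key=oracle.get)
        gl = genotype_posterior(make_counts(r_ref=r_ref, r_alt=r_alt, neither=neither), self.params())
        assert gl.best == best_oracle == ("ALT", "ALT")
        z = sum(oracle.values())
        for g, v in oracle.items():
            assert gl.posteriors[g] == pytest.approx(v / z, rel=1e-6)

    def test_degenerate_prior_forces_genotype(self):
        priors = {("ALT", "ALT"): 0.0, ("ALT", "REF"): 1.0, ("REF", "REF"): 0.0}
        gl = genotype_posterior(make_counts(r_alt=40), self.params(priors=priors))
        assert gl.best == ("ALT", "REF")

    def test_posteriors_sum_to_one(self, rng):
        for _ in range(20):
            c = make_counts(
                r_ref=int(rng.integers(0, 40)),
                r_alt=int(rng.integers(0, 40)),
                neither=int(rng.integers(0, 5)),
            )
            gl = genotype_posterior(c, self.params())
            assert sum(gl.posteriors.values()) == pytest.approx(1.0, abs=1e-12)

    def test_prior_rescaling_invariance(self):
        c = make_counts(r_ref=10, r_alt=12, neither=1)
        p1 = {("ALT", "ALT"): 0.2, ("ALT", "REF"): 0.3, ("REF", "REF"): 0.5}
        p2 = {g: 7.0 * v for g, v in p1.items()}
        gl1 = genotype_posterior(c, self.params(priors=p1))
        gl2 = genotype_posterior(c, self.params(priors=p2))
        for g in gl1.posteriors:
            assert gl1.posteriors[g] == pytest.approx(gl2.posteriors[g], rel=1e-12)

    def test_zero_priors_rejected(self):
        priors = {("ALT", "ALT"): 0.0, ("ALT", "REF"): 0.0, ("REF", "REF"): 0.0}
        with pytest.raises(GenotypingError):
            genotype_posterior(make_counts(r_alt=5), self.params(priors=priors))

    def test_gq_capped(self):
        gl = genotype_posterior(make_counts(r_alt=30), self.params())
        assert 0 <= gl.gq <= 100


class TestDepthTest:
    def test_at_expectation_passes(self):
        p, ok = depth_test(27, GenotypingParams(depth=30, read_length=150))
        assert ok and p > 0.9

    def test_far_from_expectation_fails(self):
        params = GenotypingParams(depth=30, read_length=150)
        lam = params.lam()
        extreme = int(round(lam + 10 * math.sqrt(lam)))
        p, ok = depth_test(extreme, params)
        assert not ok
        z = (extreme - lam) / math.sqrt(lam)
        assert p == pytest.approx(2 * normal_sf(abs(z)), rel=1e-9)

    def test_two_sided_symmetry(self):
        params = GenotypingParams(depth=30, read_length=150)
        lam = params.lam()
        p_hi, _ = depth_test(int(lam + 8), params)
        p_lo, _ = depth_test(int(lam - 8), params)
        assert p_hi == pytest.approx(p_lo, rel=1e-9)


class TestFisherStrand:
    def test_balanced_table_phred_zero(self):
        assert fisher_strand_phred([[10, 10], [10, 10]]) == pytest.approx(0.0, abs=1e-9)

    def test_extreme_bias_large_phred(self):
        phred = fisher_strand_phred([[20, 0], [0, 20]])
        p_oracle = fisher_exact_two_sided([[20, 0], [0, 20]])
        assert phred == pytest.approx(-10 * math.log10(p_oracle), rel=1e-6)
        assert phred > 30

    def test_row_swap_invariance(self):
        t1 = fisher_strand_phred([[12, 3], [5, 9]])
        t2 = fisher_strand_phred([[5, 9], [12, 3]])
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            table = [[int(rng.integers(0, 15)) for _ in range(2)] for _ in range(2)]
            expected = fisher_exact_two_sided(table)
            got = fisher_strand_phred(table)
            assert got == pytest.approx(-10 * math.log10(max(expected, 1e-300)), rel=1e-6, abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(GenotypingError):
            fisher_strand_phred([[1, -1], [0, 2]])


class TestGenotypeBreakpoint:
    def params(self, **kw):
        return GenotypingParams(depth=30, read_length=150, eps=0.01, **kw)

    def test_single_read_fails_low_reads(self):
        bg = genotype_breakpoint(make_counts(r_alt=1), self.params())
        assert bg.flags["low_reads"] and not bg.passing
        assert bg.genotype is not None  # genotype still reported

    def test_clean_het_passes(self):
        bg = genotype_breakpoint(make_counts(r_ref=13, r_alt=14), self.params())
        assert bg.passing
        assert bg.genotype == ("ALT", "REF")

    def test_excess_depth_fails(self):
        bg = genotype_breakpoint(make_counts(r_ref=60, r_alt=60), self.params())
        assert bg.flags["bad_depth"] and not bg.passing

    def test_low_gq_flag(self):
        # nearly uninformative counts: GQ below 10
        bg = genotype_breakpoint(make_counts(r_ref=9, r_alt=13, neither=0), self.params())
        if bg.likelihoods.gq < 10:
            assert bg.flags["low_gq"]
        else:  # construct a harder tie
            bg = genotype_breakpoint(make_counts(r_ref=11, r_alt=13), self.params())
            assert bg.flags["low_gq"] == (bg.likelihoods.gq < 10)

    def test_strand_bias_default_semantics(self):
        counts = make_counts(r_ref=14, r_alt=13, ref_strands=[14, 0], alt_strands=[0, 13])
        bg = genotype_breakpoint(counts, self.params())
        assert bg.fisher_phred > 30
        assert bg.flags["strand_bias"]
        balanced = genotype_breakpoint(make_counts(r_ref=14, r_alt=13), self.params())
        assert not balanced.flags["strand_bias"]

    def test_strand_bias_verbatim_switch_inverts(self):
        counts = make_counts(r_ref=14, r_alt=13, ref_strands=[14, 0], alt_strands=[0, 13])
        bg = genotype_breakpoint(counts, self.params(fisher_strand_verbatim=True))
        assert not bg.flags["strand_bias"]

    def test_generative_model_recovery(self):
        # property: counts drawn from the model are called correctly >= 95%
        r = np.random.default_rng(42)
        params = self.params()
        lam = params.lam()
        n = 1000
        correct_het = correct_hom = 0
        for _ in range(n):
            c = make_counts(
                r_ref=int(r.poisson(lam / 2)),
                r_alt=int(r.poisson(lam / 2)),
                neither=int(r.poisson(lam * 0.01)),
            )
            if genotype_posterior(c, params).best == ("ALT", "REF"):
                correct_het += 1
            c2 = make_counts(
                r_alt=int(r.poisson(lam * 0.99)), neither=int(r.poisson(lam * 0.01))
            )
            if genotype_posterior(c2, params).best == ("ALT", "ALT"):
                correct_hom += 1
        assert correct_het / n >= 0.95
        assert correct_hom / n >= 0.95


@given(
    lam_scale=st.floats(min_value=1.0, max_value=50.0),
    r1=st.integers(min_value=0, max_value=100),
    r2=st.integers(min_value=0, max_value=100),
)
@settings(max_examples=60, deadline=None)
def test_likelihood_log_space_equals_direct_formula(lam_scale, r1, r2):
    params = GenotypingParams(depth=lam_scale / 0.9, read_length=150, eps=0.01)
    counts = make_counts(r_ref=r1, r_alt=r2)
    lam = params.lam()
    direct = poisson_pmf(r1, lam / 2) * poisson_pmf(r2, lam / 2)
    got = het_likelihood(counts, "REF", "ALT", params)
    assert got == pytest.approx(direct, rel=1e-9, abs=1e-300)
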