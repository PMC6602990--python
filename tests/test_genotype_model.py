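import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgtlink.genotype_model import (
    AmplificationModel,
    NO_AMPLIFICATION,
    SitePileup,
    amplified_likelihood,
    genotype_posterior,
    haploid_posteriors_from_counts,
    posterior_from_pl,
    posteriors_from_counts,
    read_set_likelihood,
)


def pileup(reads, base_error=0.01):
    return SitePileup("S", "chr1", 100, "A", "G", list(reads), base_error)


def oracle_posterior(reads, ref, alt, base_error, ado, far, prior=(0.25, 0.5, 0.25)):
    """Independent oracle: exhaustive enumeration over (true genotype,
    post-amplification genotype, per-read haplotype choice)."""
    e = base_error
    gts = [(ref, ref), (ref, alt), (alt, alt)]

    def p_read(read, hap):
        return 1 - e if read == hap else e / 3

    def amp_states(gt):
        a, b = gt
        if a == b:
            other = alt if a == ref else ref
            return [((a, b), 1 - far), (tuple(sorted((a, other))), far)]
        return [((a, b), 1 - ado), ((a, a), ado / 2), ((b, b), ado / 2)]

    joint = []
    for gt, pri in zip(gts, prior):
        mass = 0.0
        for amp_gt, p_amp in amp_states(gt):
            for picks in itertools.product((0, 1), repeat=len(reads)):
                term = p_amp * 0.5 ** len(reads)
                for r, k in zip(reads, picks):
                    term *= p_read(r, amp_gt[k])
                mass += term
        joint.append(pri * mass)
    total = sum(joint)
    return [v / total for v in joint]


class TestReadSetLikelihood:
    def test_matching_hom_pair(self):
        assert read_set_likelihood(pileup("AA"), ("A", "A")) == pytest.approx(0.9801, abs=1e-12)

    def test_het_mixture(self):
        # per-read term (0.99 + 0.01/3)/2, squared
        expected = ((0.99 + 0.01 / 3) / 2) ** 2
        assert read_set_likelihood(pileup("AG"), ("A", "G")) == pytest.approx(expected)
        assert expected == pytest.approx(0.246678, abs=5e-7)

    def test_empty_reads_gives_one(self):
        assert read_set_likelihood(pileup(""), ("A", "G")) == 1.0

    def test_haploid_genotype(self):
        assert read_set_likelihood(pileup("A"), ("A",)) == pytest.approx(0.99)

    def test_bad_read_allele_rejected(self):
        with pytest.raises(ValueError, match="read allele"):
            read_set_likelihood(pileup(["T"]), ("A", "A"))


class TestAmplifiedLikelihood:
    def test_het_with_dropout(self):
        amp = AmplificationModel(ado_rate=0.2, false_allele_rate=0.0)
        got = amplified_likelihood(pileup("AA"), ("A", "G"), amp)
        expected = (0.8 * read_set_likelihood(pileup("AA"), ("A", "G"))
                    + 0.1 * 0.9801 + 0.1 * (0.01 / 3) ** 2)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(0.295353, abs=5e-6)

    def test_degenerate_amplification_is_identity(self):
        for gt in (("A", "G"), ("A", "A"), ("G", "G")):
            assert amplified_likelihood(pileup("AAG"), gt, NO_AMPLIFICATION) == \
                pytest.approx(read_set_likelihood(pileup("AAG"), gt), rel=1e-15)

    def test_hom_without_false_allele_channel(self):
        amp = AmplificationModel(ado_rate=0.3, false_allele_rate=0.0)
        assert amplified_likelihood(pileup("AA"), ("A", "A"), amp) == \
            pytest.approx(read_set_likelihood(pileup("AA"), ("A", "A")), rel=1e-15)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            AmplificationModel(ado_rate=0.8, false_allele_rate=0.5)
        with pytest.raises(ValueError):
            AmplificationModel(ado_rate=-0.1)


class TestGenotypePosterior:
    def test_concordant_reads_pick_homozygote(self):
        # expected value frozen from the exhaustive path enumeration below
        amp = AmplificationModel(0.2, 0.01)
        uniform = {("A", "A"): 1 / 3, ("A", "G"): 1 / 3, ("G", "G"): 1 / 3}
        post = genotype_posterior(pileup("A" * 6), amp, uniform)
        assert post.mode() == ("A", "A")
        expected = oracle_posterior(list("AAAAAA"), "A", "G", 0.01, 0.2, 0.01,
                                    prior=(1 / 3, 1 / 3, 1 / 3))
        assert post.probs[("A", "A")] == pytest.approx(expected[0], rel=1e-12)
        assert post.probs[("A", "A")] > 0.85

    def test_no_reads_returns_prior(self):
        prior = {("A", "A"): 0.25, ("A", "G"): 0.5, ("G", "G"): 0.25}
        post = genotype_posterior(pileup(""), NO_AMPLIFICATION, prior)
        assert post.probs == prior

    def test_haploid_likelihood_ratio(self):
        p = SitePileup("S", "chr1", 1, "A", "T", ["T"] * 3, 0.01)
        post = genotype_posterior(p, NO_AMPLIFICATION, ploidy="haploid")
        ratio = post.probs[("T",)] / post.probs[("A",)]
        assert ratio == pytest.approx((0.99 / (0.01 / 3)) ** 3, rel=1e-9)

    def test_posterior_sums_to_one(self):
        amp = AmplificationModel(0.2, 0.01)
        for reads in ("A", "AG", "AAAGG", "GGG"):
            post = genotype_posterior(pileup(reads), amp)
            assert sum(post.probs.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("reads", ["", "A", "AG", "AAG", "AGGG", "AAAAGG"])
    @pytest.mark.parametrize("ado,far", [(0.0, 0.0), (0.2, 0.01), (0.45, 0.3)])
    def test_matches_exhaustive_enumeration(self, reads, ado, far):
        """Posterior equals the brute-force path enumeration to 1e-12."""
        if not reads:
            return
        amp = AmplificationModel(ado, far)
        post = genotype_posterior(pileup(reads), amp)
        expected = oracle_posterior(list(reads), "A", "G", 0.01, ado, far)
        got = [post.probs[g] for g in (("A", "A"), ("A", "G"), ("G", "G"))]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_more_concordant_reads_monotone(self):
        amp = AmplificationModel(0.2, 0.01)
        probs = [
            genotype_posterior(pileup("A" * n), amp).probs[("A", "A")]
            for n in range(1, 7)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestPosteriorFromPL:
    def test_phred_arithmetic(self):
        post = posterior_from_pl("S", "chr1", 1, "A", "G", (0, 30, 200))
        lik = [1.0, 1e-3, 1e-20]
        prior = [0.25, 0.5, 0.25]
        joint = [l * p for l, p in zip(lik, prior)]
        expected = [j / sum(joint) for j in joint]
        got = [post.probs[g] for g in (("A", "A"), ("A", "G"), ("G", "G"))]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_flat_pl_returns_prior(self):
        post = posterior_from_pl("S", "chr1", 1, "A", "G", (0, 0, 0))
        assert post.probs[("A", "G")] == pytest.approx(0.5)
        assert post.probs[("A", "A")] == pytest.approx(0.25)

    def test_strong_het(self):
        post = posterior_from_pl("S", "chr1", 1, "A", "G", (50, 0, 50))
        assert post.probs[("A", "G")] == pytest.approx(
            0.5 / (0.5 + 0.5e-5), rel=1e-9)
        assert post.probs[("A", "G")] > 0.99998

    def test_negative_pl_rejected(self):
        with pytest.raises(ValueError):
            posterior_from_pl("S", "chr1", 1, "A", "G", (0, -5, 10))


class TestVectorisedCounts:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        n_ref=st.integers(0, 6), n_alt=st.integers(0, 6), n_oth=st.integers(0, 2),
        ado=st.floats(0.0, 0.5), far=st.floats(0.0, 0.3),
    )
    def test_matches_scalar_route(self, n_ref, n_alt, n_oth, ado, far):
        """Count-based posteriors equal the per-read scalar computation."""
        amp = AmplificationModel(ado, far)
        reads = ["A"] * n_ref + ["G"] * n_alt + ["other"] * n_oth
        arr = posteriors_from_counts(
            np.array([n_ref]), np.array([n_alt]), np.array([n_oth]), amp, 0.01)
        if reads:
            post = genotype_posterior(pileup(reads), amp)
            expected = [post.probs[g] for g in (("A", "A"), ("A", "G"), ("G", "G"))]
        else:
            expected = [0.25, 0.5, 0.25]
        np.testing.assert_allclose(arr[0], expected, rtol=1e-10, atol=1e-15)

    def test_haploid_counts(self):
        arr = haploid_posteriors_from_counts(
            np.array([0, 3]), np.array([3, 0]), np.array([0, 0]),
            NO_AMPLIFICATION, 0.01)
        # all-alt reads favour the alt allele and vice versa, symmetrically
        assert arr[0, 1] > 0.999
        assert arr[1, 0] == pytest.approx(arr[0, 1])
        np.testing.assert_allclose(arr.sum(axis=1), 1.0)
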