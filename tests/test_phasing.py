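import pytest

from pgtlink.genotype_model import GenotypePosterior
from pgtlink.phasing import (
    AMBIGUOUS,
    DISCORDANT,
    IDENTICAL_CONSENSUS,
    POLAR_BODY_CONFLICT,
    ParentalHaplotypePair,
    PhasingError,
    TransmittedAllele,
    augment_with_polar_bodies,
    deduce_transmitted_allele,
    phase_with_proband,
    phase_without_proband,
)


class TestDeduceTransmittedAllele:
    def test_mendelian_subtraction(self):
        assert deduce_transmitted_allele(("A", "G"), ("A", "A"), ("A", "G")) == "G"
        assert deduce_transmitted_allele(("A", "G"), ("A", "A"), ("A", "A")) == "A"

    def test_ambiguous_returns_none(self):
        assert deduce_transmitted_allele(("A", "G"), ("A", "G"), ("A", "G")) is None

    def test_inconsistent_returns_none(self):
        assert deduce_transmitted_allele(("A", "G"), ("A", "A"), ("G", "G")) is None

    def test_homozygous_carrier_uninformative(self):
        assert deduce_transmitted_allele(("A", "A"), ("A", "G"), ("A", "A")) is None

    def test_sperm_haploid_observation(self):
        assert deduce_transmitted_allele(("A", "G"), None, ("G",),
                                         sample_kind="sperm") == "G"
        assert deduce_transmitted_allele(("A", "G"), None, ("T",),
                                         sample_kind="sperm") is None

    def test_x_linked_male_embryo(self):
        assert deduce_transmitted_allele(("A", "G"), None, ("G",),
                                         inheritance="x_linked",
                                         sample_sex="male") == "G"


def certain(gt, sample="S", pos=1):
    if len(gt) == 2:
        a = sorted(set(gt) | ({"A", "G"} if len(set(gt)) == 1 else set(gt)))
        ref, alt = (a + ["G"])[:2]
        gts = [(ref, ref), (ref, alt), (alt, alt)]
        ploidy = "diploid"
    else:
        gts, ploidy = [("A",), ("G",)], "haploid"
    probs = {g: 0.0 for g in gts}
    key = tuple(sorted(gt)) if len(gt) == 2 else gt
    probs[key] = 1.0
    return GenotypePosterior(sample, "chr1", pos, probs, ploidy)


def posts(gts, sample="S"):
    return {pos: certain(gt, sample, pos) for pos, gt in gts.items()}


class TestPhaseWithProband:
    def test_affected_proband_labels_disease(self):
        carrier = posts({1: ("A", "G")}, "F")
        other = posts({1: ("A", "A")}, "M")
        proband = posts({1: ("A", "G")}, "P")
        pair = phase_with_proband(proband, carrier, other, "affected")
        assert pair.phase[1] == ("G", "A")

    def test_unaffected_sibling_complementary_labelling(self):
        carrier = posts({1: ("A", "G")}, "F")
        other = posts({1: ("A", "A")}, "M")
        proband = posts({1: ("A", "G")}, "P")
        pair = phase_with_proband(proband, carrier, other, "unaffected")
        assert pair.phase[1] == ("A", "G")

    def test_all_het_site_discarded(self):
        carrier = posts({1: ("A", "G")}, "F")
        other = posts({1: ("A", "G")}, "M")
        proband = posts({1: ("A", "G")}, "P")
        pair = phase_with_proband(proband, carrier, other, "affected")
        assert 1 not in pair.phase
        assert pair.discarded_sites[0].reason == AMBIGUOUS

    def test_sample_mixup_guard(self):
        # proband impossible under Mendelian transmission at every site
        carrier = posts({i: ("A", "G") for i in range(8)}, "F")
        other = posts({i: ("A", "A") for i in range(8)}, "M")
        proband = posts({i: ("G", "G") for i in range(8)}, "P")
        with pytest.raises(PhasingError, match="mix-up"):
            phase_with_proband(proband, carrier, other, "affected")


def toy_sources(strings, sites=(10, 20, 30, 40, 50)):
    return [
        TransmittedAllele(f"E{i+1}", dict(zip(sites, s)))
        for i, s in enumerate(strings)
    ]


class TestPhaseWithoutProband:
    def test_perfectly_separable_toy(self):
        srcs = toy_sources(["ACGTA", "ACGTA", "GTTAC", "GTTAC"])
        pair = phase_without_proband(srcs, {"E1": True, "E2": True,
                                            "E3": False, "E4": False})
        assert pair.n_sites == 5
        assert pair.phase[10] == ("A", "G")
        assert pair.phase[30] == ("G", "T")

    def test_single_discordant_site_survives(self):
        # E2 wrong at site 10 only: one discordant source, site retained
        srcs = toy_sources(["ACGTA", "GCGTA", "ACGTA", "GTTAC", "GTTAC", "GTTAC"])
        pair = phase_without_proband(
            srcs, {"E1": True, "E2": True, "E3": True,
                   "E4": False, "E5": False, "E6": False})
        assert 10 in pair.phase and pair.phase[10] == ("A", "G")

    def test_two_discordant_sources_discard_site(self):
        # both E2 (class 1) and E4 (class 2) wrong at site 10
        srcs = toy_sources(["ACGTA", "GCGTA", "ACGTA",
                            "ATTAC", "GTTAC", "GTTAC"])
        pair = phase_without_proband(
            srcs, {"E1": True, "E2": True, "E3": True,
                   "E4": False, "E5": False, "E6": False})
        assert 10 not in pair.phase
        reasons = {d.pos: d.reason for d in pair.discarded_sites}
        assert reasons[10] == DISCORDANT
        assert pair.n_sites == 4

    def test_identical_consensus_discarded(self):
        # site 20 has C on both haplotypes: uninformative, discarded
        srcs = toy_sources(["ACGTA", "ACGTA", "GCTAC", "GCTAC"])
        pair = phase_without_proband(srcs, {"E1": True, "E2": True,
                                            "E3": False, "E4": False})
        assert 20 not in pair.phase
        reasons = {d.pos: d.reason for d in pair.discarded_sites}
        assert reasons[20] == IDENTICAL_CONSENSUS
        assert pair.n_sites == 4

    def test_three_sources_rejected(self):
        srcs = toy_sources(["ACGTA", "ACGTA", "GTTAC"])
        with pytest.raises(PhasingError, match="4"):
            phase_without_proband(srcs, {"E1": True})

    def test_mutation_in_both_classes_fails(self):
        srcs = toy_sources(["ACGTA", "ACGTA", "GTTAC", "GTTAC"])
        with pytest.raises(PhasingError, match="evenly|both"):
            phase_without_proband(srcs, {"E1": True, "E2": False,
                                         "E3": True, "E4": False})

    def test_single_recombinant_mutation_carrier_tolerated(self):
        # E3 groups with the normal class but carries the mutation (a
        # crossover between the linkage sites and the mutation): labelling
        # follows the per-class majority instead of aborting
        srcs = toy_sources(["ACGTA", "ACGTA", "ACGTA",
                            "GTTAC", "GTTAC", "GTTAC"])
        pair = phase_without_proband(
            srcs, {"E1": True, "E2": True, "E3": True,
                   "E4": False, "E5": False, "E6": True})
        assert pair.phase[10] == ("A", "G")

    def test_no_mutation_carrier_fails(self):
        srcs = toy_sources(["ACGTA", "ACGTA", "GTTAC", "GTTAC"])
        with pytest.raises(PhasingError, match="carries"):
            phase_without_proband(srcs, {"E1": False, "E2": False,
                                         "E3": False, "E4": False})

    def test_order_invariance(self):
        strings = ["ACGTA", "GTTAC", "ACGTA", "GTTAC", "ACGTA"]
        muts = {"E1": True, "E3": True, "E5": True, "E2": False, "E4": False}
        srcs = toy_sources(strings)
        pair1 = phase_without_proband(srcs, muts)
        pair2 = phase_without_proband(list(reversed(srcs)), muts)
        assert pair1.phase == pair2.phase

    def test_unknowns_do_not_count_as_discordant(self):
        srcs = toy_sources(["ACGTA", "ACGTA", "GTTAC", "GTTAC"])
        srcs[1].alleles[10] = None
        pair = phase_without_proband(srcs, {"E1": True, "E2": True,
                                            "E3": False, "E4": False})
        assert pair.phase[10] == ("A", "G")


class TestAugmentWithPolarBodies:
    def base_pair(self):
        return ParentalHaplotypePair("M", {10: ("G", "A"), 20: ("C", "T")})

    def test_concordant_site_kept(self):
        trans = {"E1": TransmittedAllele("E1", {10: "G", 20: "C"})}
        pair, excl = augment_with_polar_bodies(
            self.base_pair(), trans, {"E1": {10: "G", 20: "C"}})
        assert excl == {}
        assert pair.n_sites == 2

    def test_conflict_excludes_site_for_that_embryo(self):
        trans = {"E1": TransmittedAllele("E1", {10: "G", 20: "C"}),
                 "E2": TransmittedAllele("E2", {10: "G"})}
        pair, excl = augment_with_polar_bodies(
            self.base_pair(), trans, {"E1": {10: "A"}})
        assert excl == {"E1": {10}}
        assert any(d.reason == POLAR_BODY_CONFLICT and d.source_id == "E1"
                   for d in pair.discarded_sites)
        # the site itself stays phased for other embryos
        assert 10 in pair.phase

    def test_missing_coverage_is_no_action(self):
        trans = {"E1": TransmittedAllele("E1", {10: "G", 20: "C"})}
        pair, excl = augment_with_polar_bodies(self.base_pair(), trans, {"E1": {}})
        assert excl == {}

    def test_paternal_carrier_rejected(self):
        with pytest.raises(ValueError, match="maternal"):
            augment_with_polar_bodies(self.base_pair(), {}, {}, carrier_role="father")
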