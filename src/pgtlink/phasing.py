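"""Phasing the carrier parent's disease-carrying vs normal haplotype.

With a proband (an affected or unaffected child/relative), the allele the
proband inherited from the carrier parent labels that haplotype directly.

Without a proband, the alleles transmitted by the carrier parent to each
embryo (or sperm cell) are deduced site by site, the sources are grouped
into two classes — the two parental haplotypes — by agreement at anchor
sites, a per-class consensus is built, and the class whose members carry
the causal mutation (from the PCR-amplified mutation-site genotype) is the
disease haplotype.  Sites with more than one discordant source, or where
both class consensuses coincide, are discarded as genotyping errors.  At
least four sources are required.

Phasing works on point-estimate genotypes (posterior modes with mass at or
above a configurable floor) for determinism and auditability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genotype_model import Genotype, GenotypePosterior

__all__ = [
    "TransmittedAllele",
    "DiscardedSite",
    "ParentalHaplotypePair",
    "PhasingError",
    "deduce_transmitted_allele",
    "transmitted_from_posteriors",
    "phase_with_proband",
    "phase_without_proband",
    "augment_with_polar_bodies",
]

DISCORDANT = "discordant"
IDENTICAL_CONSENSUS = "identical_consensus"
AMBIGUOUS = "ambiguous"
POLAR_BODY_CONFLICT = "polar_body_conflict"


class PhasingError(RuntimeError):
    """Raised when haplotype phasing cannot be completed."""


@dataclass
class TransmittedAllele:
    """Per-site allele a source (embryo/sperm/polar body) received from the
    carrier parent; None where the deduction is ambiguous or missing."""

    source_id: str
    alleles: dict[int, str | None]

    @property
    def completeness(self) -> float:
        if not self.alleles:
            return 0.0
        resolved = sum(1 for a in self.alleles.values() if a is not None)
        return resolved / len(self.alleles)


@dataclass(frozen=True)
class DiscardedSite:
    pos: int
    reason: str
    source_id: str | None = None


@dataclass
class ParentalHaplotypePair:
    """The carrier parent's phased haplotypes across the retained sites."""

    carrier_id: str
    phase: dict[int, tuple[str, str]]  # pos -> (disease_allele, normal_allele)
    discarded_sites: list[DiscardedSite] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.phase)

    def __post_init__(self) -> None:
        for pos, (d, n) in self.phase.items():
            if d == n:
                raise PhasingError(f"site {pos}: disease and normal alleles identical")


def deduce_transmitted_allele(
    carrier_gt: Genotype,
    other_gt: Genotype | None,
    sample_gt: Genotype,
    inheritance: str = "autosomal",
    sample_kind: str = "embryo",
    sample_sex: str | None = None,
) -> str | None:
    """The unique carrier allele consistent with Mendelian transmission.

    Returns None when the deduction is ambiguous (either carrier allele
    works) or inconsistent (neither does); ambiguity is a value, not an
    error.  Sperm and second polar bodies are haploid: the observed allele
    is the transmitted allele when it matches a carrier allele.
    """
    if len(carrier_gt) != 2 or carrier_gt[0] == carrier_gt[1]:
        return None  # homozygous carrier: uninformative
    if sample_kind in ("sperm", "polar_body"):
        if len(sample_gt) != 1:
            return None
        return sample_gt[0] if sample_gt[0] in carrier_gt else None
    if inheritance == "x_linked" and sample_sex == "male":
        if len(sample_gt) != 1:
            return None
        return sample_gt[0] if sample_gt[0] in carrier_gt else None
    if other_gt is None:
        return None
    possible = {
        c for c in carrier_gt
        if any(tuple(sorted((c, o))) == tuple(sorted(sample_gt)) for o in other_gt)
    }
    if len(possible) == 1:
        return next(iter(possible))
    return None


def transmitted_from_posteriors(
    source_id: str,
    carrier: dict[int, GenotypePosterior],
    other: dict[int, GenotypePosterior] | None,
    sample: dict[int, GenotypePosterior],
    min_mass: float = 0.5,
    inheritance: str = "autosomal",
    sample_kind: str = "embryo",
    sample_sex: str | None = None,
) -> TransmittedAllele:
    """Point-estimate transmitted alleles for one source across sites."""
    alleles: dict[int, str | None] = {}
    for pos, cpost in carrier.items():
        spost = sample.get(pos)
        if spost is None:
            alleles[pos] = None
            continue
        cgt = cpost.mode(min_mass)
        sgt = spost.mode(min_mass)
        ogt = None
        if other is not None and pos in other:
            ogt = other[pos].mode(min_mass)
        if cgt is None or sgt is None or (
            ogt is None and other is not None
            and sample_kind == "embryo"
            and not (inheritance == "x_linked" and sample_sex == "male")
        ):
            alleles[pos] = None
            continue
        alleles[pos] = deduce_transmitted_allele(
            cgt, ogt, sgt, inheritance, sample_kind, sample_sex
        )
    return TransmittedAllele(source_id, alleles)


def phase_with_proband(
    proband: dict[int, GenotypePosterior],
    carrier: dict[int, GenotypePosterior],
    other: dict[int, GenotypePosterior],
    proband_status: str,
    carrier_id: str = "carrier",
    min_mass: float = 0.5,
    max_inconsistent_fraction: float = 0.25,
    inheritance: str = "autosomal",
    proband_sex: str | None = None,
) -> ParentalHaplotypePair:
    """Phase from a child (or affected relative) with known disease status.

    The allele an affected proband inherited from the carrier parent is the
    disease allele; for an unaffected proband it is the normal allele.
    Ambiguous sites are discarded.  A proband Mendelian-inconsistent with
    the parents at more than ``max_inconsistent_fraction`` of informative
    sites triggers a hard error (sample mix-up guard).
    """
    if proband_status not in ("affected", "unaffected"):
        raise ValueError(f"proband_status must be affected|unaffected, got {proband_status!r}")
    phase: dict[int, tuple[str, str]] = {}
    discarded: list[DiscardedSite] = []
    n_informative = 0
    n_inconsistent = 0
    for pos, cpost in carrier.items():
        cgt = cpost.mode(min_mass)
        pgt = proband.get(pos).mode(min_mass) if pos in proband else None
        ogt = other.get(pos).mode(min_mass) if pos in other else None
        if cgt is None or pgt is None or cgt[0] == cgt[-1]:
            discarded.append(DiscardedSite(pos, AMBIGUOUS))
            continue
        if ogt is None and not (inheritance == "x_linked" and proband_sex == "male"):
            discarded.append(DiscardedSite(pos, AMBIGUOUS))
            continue
        n_informative += 1
        # detect Mendelian inconsistency: no carrier allele explains the proband
        hemi = inheritance == "x_linked" and proband_sex == "male"
        if hemi:
            consistent = any(pgt == (c,) for c in cgt)
        else:
            consistent = any(
                tuple(sorted((c, o))) == tuple(sorted(pgt))
                for c in cgt for o in (ogt or ())
            )
        if not consistent:
            n_inconsistent += 1
            discarded.append(DiscardedSite(pos, AMBIGUOUS, proband.get(pos).sample_id))
            continue
        transmitted = deduce_transmitted_allele(
            cgt, ogt, pgt, inheritance, "embryo", proband_sex
        )
        if transmitted is None:
            discarded.append(DiscardedSite(pos, AMBIGUOUS))
            continue
        other_allele = cgt[1] if transmitted == cgt[0] else cgt[0]
        if proband_status == "affected":
            phase[pos] = (transmitted, other_allele)
        else:
            phase[pos] = (other_allele, transmitted)
    if n_informative and n_inconsistent / n_informative > max_inconsistent_fraction:
        raise PhasingError(
            f"proband inconsistent with parents at {n_inconsistent}/{n_informative} "
            "informative sites — possible sample mix-up"
        )
    return ParentalHaplotypePair(carrier_id, phase, discarded)


def _consensus(class_members: list[TransmittedAllele], pos: int) -> str | None:
    votes = Counter(
        m.alleles.get(pos) for m in class_members if m.alleles.get(pos) is not None
    )
    if not votes:
        return None
    top = votes.most_common(2)
    if len(top) == 2 and top[0][1] == top[1][1]:
        return None  # tie
    return top[0][0]


def phase_without_proband(
    transmitted: list[TransmittedAllele],
    mutation_evidence: dict[str, bool],
    carrier_id: str = "carrier",
    min_sources: int = 4,
    anchor_fraction: float = 0.75,
    carrier_genotypes: dict[int, tuple[str, str]] | None = None,
) -> ParentalHaplotypePair:
    """Proband-free phasing by two-class grouping of transmitted alleles.

    1. anchor sites: resolved in at least ``anchor_fraction`` of sources;
    2. greedy seed-and-extend partition into two classes (seed = most
       complete source; each source joins the class whose consensus it
       matches at more anchor sites);
    3. per-class consensus allele at every site;
    4. discard sites with more than one discordant source, sites where the
       two consensuses coincide, and sites without both consensuses;
    5. the class whose members carry the causal mutation (PCR genotype at
       the mutation site) is the disease haplotype.

    When every source inherited the same carrier haplotype (no second
    class forms), the other haplotype is reconstructed as the carrier's
    complementary allele per site, provided ``carrier_genotypes`` (the
    carrier's heterozygous point calls) is supplied.
    """
    usable = [t for t in transmitted if any(a is not None for a in t.alleles.values())]
    if len(usable) < min_sources:
        raise PhasingError(
            f"proband-free phasing needs at least {min_sources} usable sources "
            f"(embryos or sperm); got {len(usable)}"
        )
    sites = sorted({pos for t in usable for pos in t.alleles})
    n_src = len(usable)
    anchors = [
        pos for pos in sites
        if sum(1 for t in usable if t.alleles.get(pos) is not None) >= anchor_fraction * n_src
    ]
    if not anchors:
        raise PhasingError("no anchor sites resolved in enough sources")

    # deterministic order regardless of input order: completeness, then id
    ordered = sorted(usable, key=lambda t: (-t.completeness, t.source_id))
    class_a: list[TransmittedAllele] = [ordered[0]]
    class_b: list[TransmittedAllele] = []
    for src in ordered[1:]:
        score_a = _agreement(src, class_a, anchors)
        score_b = _agreement(src, class_b, anchors) if class_b else (0, 0)
        if not class_b:
            # start the second class with the first source that disagrees
            (class_a if score_a[0] >= score_a[1] else class_b).append(src)
            continue
        if score_a[0] > score_b[0]:
            class_a.append(src)
        elif score_b[0] > score_a[0]:
            class_b.append(src)
        else:  # tie on matches: fewer mismatches wins, then class A
            (class_a if score_a[1] <= score_b[1] else class_b).append(src)
    complement_b = False
    if not class_b:
        if carrier_genotypes is None:
            raise PhasingError(
                "all sources fall into one haplotype class and no carrier "
                "genotypes were supplied to reconstruct the second haplotype"
            )
        complement_b = True

    phase_unlabelled: dict[int, tuple[str, str]] = {}  # (class A allele, class B allele)
    discarded: list[DiscardedSite] = []
    for pos in sites:
        cons_a = _consensus(class_a, pos)
        if complement_b:
            cgt = carrier_genotypes.get(pos)
            cons_b = None
            if cons_a is not None and cgt is not None and cons_a in cgt:
                other = [a for a in cgt if a != cons_a]
                cons_b = other[0] if len(other) == 1 else None
        else:
            cons_b = _consensus(class_b, pos)
        if cons_a is None or cons_b is None:
            discarded.append(DiscardedSite(pos, AMBIGUOUS))
            continue
        if cons_a == cons_b:
            discarded.append(DiscardedSite(pos, IDENTICAL_CONSENSUS))
            continue
        n_discordant = sum(
            1
            for members, cons in ((class_a, cons_a), (class_b, cons_b))
            for m in members
            if m.alleles.get(pos) is not None and m.alleles[pos] != cons
        )
        if n_discordant > 1:
            discarded.append(DiscardedSite(pos, DISCORDANT))
            continue
        phase_unlabelled[pos] = (cons_a, cons_b)

    # label by the per-class majority of mutation-site genotypes: a single
    # recombinant (or mutation-site genotyping error) must not abort phasing,
    # exactly as single discordant samples are tolerated at linkage sites
    def carrier_fraction(members: list[TransmittedAllele]) -> float:
        known = [mutation_evidence[m.source_id] for m in members
                 if m.source_id in mutation_evidence]
        return sum(known) / len(known) if known else -1.0

    frac_a, frac_b = carrier_fraction(class_a), carrier_fraction(class_b)
    if complement_b:
        # single observed class: its majority mutation status decides which
        # side it is; the complement is the other haplotype
        if frac_a < 0.0:
            raise PhasingError(
                "no source has mutation-site evidence; cannot label the disease haplotype"
            )
        if frac_a == 0.5:
            raise PhasingError(
                "mutation carriers split evenly across haplotype classes — phasing failed"
            )
        phase = {
            pos: (a, b) if frac_a > 0.5 else (b, a)
            for pos, (a, b) in phase_unlabelled.items()
        }
        return ParentalHaplotypePair(carrier_id, phase, discarded)
    if frac_a < 0.0 and frac_b < 0.0:
        raise PhasingError(
            "no source has mutation-site evidence; cannot label the disease haplotype"
        )
    if max(frac_a, frac_b) <= 0.0:
        raise PhasingError(
            "no source carries the causal mutation; cannot label the disease haplotype"
        )
    if frac_a == frac_b:
        raise PhasingError(
            "mutation carriers split evenly across haplotype classes — phasing failed"
        )
    if min(frac_a, frac_b) > 0.5:
        raise PhasingError(
            "both haplotype classes are majority mutation carriers — phasing failed"
        )
    a_is_disease = frac_a > frac_b
    phase = {
        pos: (a, b) if a_is_disease else (b, a)
        for pos, (a, b) in phase_unlabelled.items()
    }
    return ParentalHaplotypePair(carrier_id, phase, discarded)


def _agreement(
    src: TransmittedAllele, members: list[TransmittedAllele], anchors: list[int]
) -> tuple[int, int]:
    """(matches, mismatches) of ``src`` against a class consensus at anchors."""
    match = mismatch = 0
    for pos in anchors:
        a = src.alleles.get(pos)
        if a is None:
            continue
        cons = _consensus(members, pos)
        if cons is None:
            continue
        if a == cons:
            match += 1
        else:
            mismatch += 1
    return match, mismatch


def augment_with_polar_bodies(
    pair: ParentalHaplotypePair,
    embryo_transmitted: dict[str, TransmittedAllele],
    pb2_alleles: dict[str, dict[int, str | None]],
    carrier_role: str = "mother",
) -> tuple[ParentalHaplotypePair, dict[str, set[int]]]:
    """Cross-check embryo transmitted alleles against second polar bodies.

    The second polar body carries the sister chromatid of the egg
    pronucleus, so (absent a crossover between them) its allele equals the
    transmitted one.  Sites where PB2 contradicts the embryo are excluded
    from that embryo's evidence as genotyping errors; polar bodies only
    remove sites, they never overrule genotypes.  Returns the pair (with
    the conflicts recorded) and the per-embryo exclusion sets.
    """
    if carrier_role != "mother":
        raise ValueError("polar bodies are only informative for a maternal carrier")
    exclusions: dict[str, set[int]] = {}
    discarded = list(pair.discarded_sites)
    for embryo_id, trans in embryo_transmitted.items():
        pb = pb2_alleles.get(embryo_id)
        if not pb:
            continue
        for pos, allele in trans.alleles.items():
            pb_allele = pb.get(pos)
            if allele is None or pb_allele is None:
                continue
            if pb_allele != allele:
                exclusions.setdefault(embryo_id, set()).add(pos)
                discarded.append(DiscardedSite(pos, POLAR_BODY_CONFLICT, embryo_id))
    out = ParentalHaplotypePair(pair.carrier_id, dict(pair.phase), discarded)
    return out, exclusions
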