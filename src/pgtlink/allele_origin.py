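"""Per-site haplotype-origin evidence for each embryo.

At a phased linkage site the carrier parent is heterozygous, one allele on
the disease-carrying haplotype and the other on the normal haplotype.
Each joint genotype combination (carrier, other parent, embryo) is
classified by which carrier allele can explain the embryo's genotype under
Mendelian transmission:

* only the disease allele  -> *disease-supportive*
* only the normal allele   -> *normal-supportive*
* both, neither (Mendelian-inconsistent), or carrier homozygous -> *neutral*

Summing genotype-posterior-weighted combination probabilities per class and
giving the neutral class half weight to each side yields the per-site
evidence pair (p_disease, p_normal) that the linkage chain consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .genotype_model import Genotype, GenotypePosterior

__all__ = [
    "DISEASE_SUPPORTIVE",
    "NORMAL_SUPPORTIVE",
    "NEUTRAL",
    "SiteEvidence",
    "LinkageSiteCandidate",
    "classify_combination",
    "site_evidence",
    "site_evidence_batch",
    "collect_linkage_sites",
]

DISEASE_SUPPORTIVE = "disease_supportive"
NORMAL_SUPPORTIVE = "normal_supportive"
NEUTRAL = "neutral"


@dataclass
class SiteEvidence:
    """Evidence that the carrier-transmitted allele at one site is disease vs normal."""

    embryo_id: str
    chrom: str
    pos: int
    p_disease: float
    p_normal: float
    n_combinations: int = 0
    usable: bool = True


def _possible_carrier_alleles(
    carrier_gt: Genotype,
    other_gt: Genotype,
    embryo_gt: Genotype,
    phase_at_site: tuple[str, str],
    inheritance: str,
    embryo_sex: str | None,
) -> set[str] | None:
    """Carrier alleles that can explain the embryo genotype; None = uninformative."""
    disease_allele, normal_allele = phase_at_site
    if len(carrier_gt) == 2 and carrier_gt[0] == carrier_gt[1]:
        return None  # homozygous carrier carries no phase information
    if set(carrier_gt) != {disease_allele, normal_allele}:
        raise ValueError(
            f"phase {phase_at_site} inconsistent with carrier genotype {carrier_gt}"
        )
    male_x = inheritance == "x_linked" and embryo_sex == "male"
    possible: set[str] = set()
    for c in (disease_allele, normal_allele):
        if male_x:
            # hemizygous embryo: the single X allele comes from the carrier mother
            if embryo_gt == (c,):
                possible.add(c)
        else:
            for o in other_gt:
                if tuple(sorted((c, o))) == tuple(sorted(embryo_gt)):
                    possible.add(c)
                    break
    return possible


def classify_combination(
    carrier_gt: Genotype,
    other_gt: Genotype,
    embryo_gt: Genotype,
    phase_at_site: tuple[str, str],
    inheritance: str = "autosomal",
    embryo_sex: str | None = None,
) -> str:
    """Classify one (carrier, other, embryo) genotype combination.

    Mendelian-inconsistent combinations (no carrier allele explains the
    embryo) are pooled into *neutral*: inconsistency signals a genotyping
    error, exactly what the half-half weighting absorbs.
    """
    possible = _possible_carrier_alleles(
        carrier_gt, other_gt, embryo_gt, phase_at_site, inheritance, embryo_sex
    )
    disease_allele, normal_allele = phase_at_site
    if possible == {disease_allele}:
        return DISEASE_SUPPORTIVE
    if possible == {normal_allele}:
        return NORMAL_SUPPORTIVE
    return NEUTRAL


def site_evidence(
    carrier: GenotypePosterior,
    other: GenotypePosterior,
    embryo: GenotypePosterior,
    phase_at_site: tuple[str, str],
    inheritance: str = "autosomal",
    embryo_sex: str | None = None,
) -> SiteEvidence:
    """Evidence pair from the full posterior triple at one site.

    Each combination is weighted by the product of the member posteriors;
    class sums S_d, S_n, S_neutral give p_disease = S_d + S_neutral/2 and
    p_normal = S_n + S_neutral/2, normalised to sum to one.
    """
    sums = {DISEASE_SUPPORTIVE: 0.0, NORMAL_SUPPORTIVE: 0.0, NEUTRAL: 0.0}
    n_comb = 0
    for (cg, cp), (og, op_), (eg, ep) in product(
        carrier.probs.items(), other.probs.items(), embryo.probs.items()
    ):
        w = cp * op_ * ep
        if w == 0.0:
            continue
        label = classify_combination(cg, og, eg, phase_at_site, inheritance, embryo_sex)
        sums[label] += w
        n_comb += 1
    p_d = sums[DISEASE_SUPPORTIVE] + 0.5 * sums[NEUTRAL]
    p_n = sums[NORMAL_SUPPORTIVE] + 0.5 * sums[NEUTRAL]
    total = p_d + p_n
    if total <= 0.0:
        return SiteEvidence(embryo.sample_id, embryo.chrom, embryo.pos,
                            0.5, 0.5, n_comb, usable=False)
    return SiteEvidence(
        embryo.sample_id, embryo.chrom, embryo.pos,
        p_d / total, p_n / total, n_comb,
    )


def _contribution_tensor(alt_is_disease: bool) -> np.ndarray:
    """3x3x3 tensor of disease-side contribution per genotype combination.

    Indexed (carrier, other, embryo) over (hom-ref, het, hom-alt); built by
    the scalar classifier so both routes stay consistent by construction.
    """
    ref, alt = "0", "1"
    gts = [(ref, ref), (ref, alt), (alt, alt)]
    phase = (alt, ref) if alt_is_disease else (ref, alt)
    weight = {DISEASE_SUPPORTIVE: 1.0, NORMAL_SUPPORTIVE: 0.0, NEUTRAL: 0.5}
    t = np.empty((3, 3, 3))
    for i, cg in enumerate(gts):
        for j, og in enumerate(gts):
            for k, eg in enumerate(gts):
                t[i, j, k] = weight[classify_combination(cg, og, eg, phase)]
    return t


_TENSOR_ALT_DISEASE = _contribution_tensor(True)
_TENSOR_REF_DISEASE = _contribution_tensor(False)


def site_evidence_batch(
    carrier_post: np.ndarray,
    other_post: np.ndarray,
    embryo_post: np.ndarray,
    alt_is_disease: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised evidence pairs for many diploid autosomal sites.

    Inputs are (S, 3) posteriors over (hom-ref, het, hom-alt) and an (S,)
    boolean giving the phase orientation (True: alt allele is on the
    disease haplotype).  Returns (p_disease, p_normal), each (S,),
    normalised pairwise.
    """
    pd_alt = np.einsum("si,sj,sk,ijk->s", carrier_post, other_post, embryo_post,
                       _TENSOR_ALT_DISEASE)
    pd_ref = np.einsum("si,sj,sk,ijk->s", carrier_post, other_post, embryo_post,
                       _TENSOR_REF_DISEASE)
    p_d = np.where(alt_is_disease, pd_alt, pd_ref)
    # classes partition the posterior mass, so p_d + p_n == total mass == 1,
    # but renormalise to guard against round-off
    pn_alt = np.einsum("si,sj,sk,ijk->s", carrier_post, other_post, embryo_post,
                       1.0 - _TENSOR_ALT_DISEASE)
    pn_ref = np.einsum("si,sj,sk,ijk->s", carrier_post, other_post, embryo_post,
                       1.0 - _TENSOR_REF_DISEASE)
    p_n = np.where(alt_is_disease, pn_alt, pn_ref)
    total = p_d + p_n
    return p_d / total, p_n / total


@dataclass
class LinkageSiteCandidate:
    """Filter-relevant summary of one candidate linkage site for one embryo."""

    chrom: str
    pos: int
    embryo_reads: int
    carrier_het_mass: float
    phase_known: bool
    has_pl: bool = False


def collect_linkage_sites(
    candidates: Iterable[LinkageSiteCandidate],
    mutation_pos: int,
    window_mb: float = 1.5,
    min_reads: int = 2,
    carrier_het_floor: float = 0.5,
    whitelist: Sequence[int] | None = None,
) -> tuple[list[LinkageSiteCandidate], list[LinkageSiteCandidate]]:
    """Select and order the linkage sites for one embryo.

    Keeps sites within ``window_mb`` of the mutation where the embryo has
    at least ``min_reads`` reads (or an imported PL record), the carrier is
    informative (heterozygous posterior mass at or above the floor) and the
    phase is known.  A whitelist bypasses every filter except the window.
    Returns (upstream, downstream) lists sorted nearest-first; the mutation
    site itself is never a linkage site.
    """
    window_bp = window_mb * 1e6
    wl = set(whitelist) if whitelist is not None else None
    kept = []
    for c in candidates:
        if c.pos == mutation_pos or abs(c.pos - mutation_pos) > window_bp:
            continue
        if wl is not None:
            if c.pos in wl:
                kept.append(c)
            continue
        if c.embryo_reads < min_reads and not c.has_pl:
            continue
        if c.carrier_het_mass < carrier_het_floor or not c.phase_known:
            continue
        kept.append(c)
    upstream = sorted((c for c in kept if c.pos < mutation_pos),
                      key=lambda c: mutation_pos - c.pos)
    downstream = sorted((c for c in kept if c.pos > mutation_pos),
                        key=lambda c: c.pos - mutation_pos)
    return upstream, downstream
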