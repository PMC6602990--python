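"""Per-sample genotype posteriors under a single-cell amplification error model.

Single-cell whole-genome amplification (MALBAC-style WGA) distorts
genotypes before sequencing: a heterozygote may lose one allele (allele
dropout, ADO) and a homozygote may gain a spurious second allele.  The
likelihood of the observed reads given a *true* genotype therefore sums
over the possible *post-amplification* genotypes:

    P(reads | gt) = sum_amp P(amp | gt) * P(reads | amp)

where P(reads | amp) is a product over reads of the half-half haplotype
mixture: each read is drawn from one of the two haplotypes of the
(post-amplification) genotype with probability 1/2, matching its allele
with probability ``1 - base_error`` and any specific other base with
``base_error / 3``.  Haploid (hemizygous) sites degenerate to a single
haplotype with no ADO channel.

Genotypes are tuples of allele labels: ``("A", "G")`` diploid, ``("A",)``
haploid; the model is allele-symbolic (indels are atomic labels).

Alongside the per-pileup scalar operations, :func:`posteriors_from_counts`
exposes the same model vectorised over many sites keyed by (ref, alt,
other) read counts — the form used by the family pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Genotype",
    "SitePileup",
    "AmplificationModel",
    "GenotypePosterior",
    "read_set_likelihood",
    "amplified_likelihood",
    "genotype_posterior",
    "posterior_from_pl",
    "diploid_genotypes",
    "haploid_genotypes",
    "default_prior",
    "likelihoods_from_counts",
    "posteriors_from_counts",
]

Genotype = tuple[str, ...]

#: default genotype priors (Hardy-Weinberg at allele frequency 1/2)
DIPLOID_PRIOR = (0.25, 0.5, 0.25)
HAPLOID_PRIOR = (0.5, 0.5)


def diploid_genotypes(ref: str, alt: str) -> list[Genotype]:
    return [(ref, ref), (ref, alt), (alt, alt)]


def haploid_genotypes(ref: str, alt: str) -> list[Genotype]:
    return [(ref,), (alt,)]


def default_prior(genotypes: list[Genotype]) -> dict[Genotype, float]:
    weights = DIPLOID_PRIOR if len(genotypes) == 3 else HAPLOID_PRIOR
    return dict(zip(genotypes, weights))


@dataclass
class SitePileup:
    """Observed read alleles for one sample at one site."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    reads: list[str]
    base_error: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_error < 0.75):
            raise ValueError(f"base_error {self.base_error} outside [0, 0.75)")


@dataclass(frozen=True)
class AmplificationModel:
    """ADO / spurious-allele rates of the whole-genome amplification step."""

    ado_rate: float = 0.2
    false_allele_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("ado_rate", "false_allele_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} {v} outside [0, 1)")
        if self.ado_rate + self.false_allele_rate >= 1.0:
            raise ValueError("ado_rate + false_allele_rate must be < 1")


#: noiseless amplification (bulk DNA)
NO_AMPLIFICATION = AmplificationModel(ado_rate=0.0, false_allele_rate=0.0)


@dataclass
class GenotypePosterior:
    """Posterior over genotypes for one sample at one site."""

    sample_id: str
    chrom: str
    pos: int
    probs: dict[Genotype, float]
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, not 1")

    def mode(self, min_mass: float = 0.0) -> Genotype | None:
        """Most probable genotype, or None if its mass is below ``min_mass``."""
        gt = max(self.probs, key=self.probs.get)
        return gt if self.probs[gt] >= min_mass else None


def _p_read_given_hap(read: str, hap: str, base_error: float) -> float:
    return 1.0 - base_error if read == hap else base_error / 3.0


def read_set_likelihood(pileup: SitePileup, gt_after_amp: Genotype) -> float:
    """P(reads | post-amplification genotype): product of half-half mixtures."""
    alphabet = {pileup.ref_allele, pileup.alt_allele}
    lik = 1.0
    for read in pileup.reads:
        if read not in alphabet and read != "other":
            raise ValueError(
                f"read allele {read!r} not in {{ref, alt, 'other'}} for "
                f"{pileup.chrom}:{pileup.pos}"
            )
        terms = [_p_read_given_hap(read, h, pileup.base_error) for h in gt_after_amp]
        lik *= sum(terms) / len(terms)
    return lik


def _amp_transitions(
    true_gt: Genotype, ref: str, alt: str, amp: AmplificationModel
) -> list[tuple[Genotype, float]]:
    """Post-amplification genotype distribution given the true genotype."""
    if len(true_gt) == 1:
        # hemizygous: a spurious allele turns the single allele into a mixture
        other = alt if true_gt[0] == ref else ref
        return [(true_gt, 1.0 - amp.false_allele_rate),
                ((true_gt[0], other), amp.false_allele_rate)]
    a, b = true_gt
    if a == b:
        other = alt if a == ref else ref
        return [(true_gt, 1.0 - amp.false_allele_rate),
                ((a, other), amp.false_allele_rate)]
    return [(true_gt, 1.0 - amp.ado_rate),
            ((a, a), amp.ado_rate / 2.0),
            ((b, b), amp.ado_rate / 2.0)]


def amplified_likelihood(
    pileup: SitePileup, true_gt: Genotype, amp: AmplificationModel
) -> float:
    """P(reads | true genotype), summing over post-amplification genotypes."""
    return sum(
        p * read_set_likelihood(pileup, gt_amp)
        for gt_amp, p in _amp_transitions(true_gt, pileup.ref_allele, pileup.alt_allele, amp)
    )


def genotype_posterior(
    pileup: SitePileup,
    amp: AmplificationModel = NO_AMPLIFICATION,
    prior: dict[Genotype, float] | None = None,
    ploidy: str = "diploid",
) -> GenotypePosterior:
    """Bayes posterior over genotypes given the pileup.

    With no reads the prior is returned unchanged.
    """
    if ploidy == "diploid":
        gts = diploid_genotypes(pileup.ref_allele, pileup.alt_allele)
    else:
        gts = haploid_genotypes(pileup.ref_allele, pileup.alt_allele)
    if prior is None:
        prior = default_prior(gts)
    total_prior = sum(prior.values())
    if abs(total_prior - 1.0) > 1e-9:
        raise ValueError("prior must sum to 1")
    if not pileup.reads:
        return GenotypePosterior(pileup.sample_id, pileup.chrom, pileup.pos,
                                 dict(prior), ploidy)
    joint = {gt: prior.get(gt, 0.0) * amplified_likelihood(pileup, gt, amp) for gt in gts}
    norm = sum(joint.values())
    if norm <= 0.0:
        raise ZeroDivisionError(
            f"zero joint mass at {pileup.chrom}:{pileup.pos} for {pileup.sample_id}"
        )
    probs = {gt: v / norm for gt, v in joint.items()}
    return GenotypePosterior(pileup.sample_id, pileup.chrom, pileup.pos, probs, ploidy)


def posterior_from_pl(
    sample_id: str,
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    pl_values: tuple[int, ...],
    prior: dict[Genotype, float] | None = None,
) -> GenotypePosterior:
    """Posterior from Phred-scaled genotype likelihoods (e.g. GATK PL).

    A PL triple maps to diploid genotypes (hom-ref, het, hom-alt); a pair
    to a hemizygous site.
    """
    if any(pl < 0 for pl in pl_values):
        raise ValueError(f"negative PL value in {pl_values}")
    if len(pl_values) == 3:
        gts, ploidy = diploid_genotypes(ref_allele, alt_allele), "diploid"
    elif len(pl_values) == 2:
        gts, ploidy = haploid_genotypes(ref_allele, alt_allele), "haploid"
    else:
        raise ValueError(f"expected 2 or 3 PL values, got {len(pl_values)}")
    if prior is None:
        prior = default_prior(gts)
    lik = [10.0 ** (-pl / 10.0) for pl in pl_values]
    joint = {gt: prior.get(gt, 0.0) * l for gt, l in zip(gts, lik)}
    norm = sum(joint.values())
    probs = {gt: v / norm for gt, v in joint.items()}
    return GenotypePosterior(sample_id, chrom, pos, probs, ploidy)


# ---------------------------------------------------------------------------
# vectorised form over (n_ref, n_alt, n_other) read counts
# ---------------------------------------------------------------------------

def likelihoods_from_counts(
    n_ref: np.ndarray,
    n_alt: np.ndarray,
    n_other: np.ndarray,
    base_error: float,
) -> np.ndarray:
    """(S, 3) read-set likelihoods for genotypes (hom-ref, het, hom-alt).

    The per-read mixture term depends only on whether the read shows ref,
    alt or another base, so a site's read set is fully summarised by its
    three counts.
    """
    e = base_error
    match, mis = 1.0 - e, e / 3.0
    # rows: genotype; cols: read class (ref, alt, other)
    terms = np.array([
        [match, mis, mis],
        [(match + mis) / 2.0, (match + mis) / 2.0, mis],
        [mis, match, mis],
    ])
    counts = np.stack([n_ref, n_alt, n_other], axis=-1).astype(float)  # (S, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_terms = np.log(terms).T[None, :, :]  # (1, read class, genotype)
        # zero counts contribute exactly 0 even against log(0) = -inf terms
        contrib = np.where(counts[:, :, None] > 0, counts[:, :, None] * log_terms, 0.0)
    return np.exp(contrib.sum(axis=1))


def _amp_matrix(amp: AmplificationModel) -> np.ndarray:
    """Row-stochastic true->amplified genotype matrix over (hom-ref, het, hom-alt)."""
    ado, far = amp.ado_rate, amp.false_allele_rate
    return np.array([
        [1.0 - far, far, 0.0],
        [ado / 2.0, 1.0 - ado, ado / 2.0],
        [0.0, far, 1.0 - far],
    ])


def posteriors_from_counts(
    n_ref: np.ndarray,
    n_alt: np.ndarray,
    n_other: np.ndarray,
    amp: AmplificationModel,
    base_error: float,
    prior: tuple[float, float, float] = DIPLOID_PRIOR,
) -> np.ndarray:
    """(S, 3) genotype posteriors for many diploid sites at once.

    Sites with zero reads get the prior.  Numerically identical to calling
    :func:`genotype_posterior` per site with the equivalent read list.
    """
    read_lik = likelihoods_from_counts(n_ref, n_alt, n_other, base_error)  # P(reads|amp)
    lik = read_lik @ _amp_matrix(amp).T  # (S, 3): P(reads | true gt)
    joint = lik * np.asarray(prior)
    total = joint.sum(axis=1, keepdims=True)
    post = joint / total
    depth = np.asarray(n_ref) + np.asarray(n_alt) + np.asarray(n_other)
    post[depth == 0] = np.asarray(prior)
    return post


def haploid_posteriors_from_counts(
    n_ref: np.ndarray,
    n_alt: np.ndarray,
    n_other: np.ndarray,
    amp: AmplificationModel,
    base_error: float,
    prior: tuple[float, float] = HAPLOID_PRIOR,
) -> np.ndarray:
    """(S, 2) posteriors over (ref, alt) for hemizygous/haploid sites.

    The single true allele may gain a spurious partner during
    amplification (``false_allele_rate``); there is no dropout channel.
    """
    read_lik = likelihoods_from_counts(n_ref, n_alt, n_other, base_error)
    far = amp.false_allele_rate
    lik = np.stack(
        [
            (1.0 - far) * read_lik[:, 0] + far * read_lik[:, 1],
            (1.0 - far) * read_lik[:, 2] + far * read_lik[:, 1],
        ],
        axis=1,
    )
    joint = lik * np.asarray(prior)
    post = joint / joint.sum(axis=1, keepdims=True)
    depth = np.asarray(n_ref) + np.asarray(n_alt) + np.asarray(n_other)
    post[depth == 0] = np.asarray(prior)
    return post


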