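"""Recombination-aware chaining of site evidence into a disease posterior.

The hidden state is the haplotype origin (disease vs normal) of the
carrier-transmitted chromatid, anchored at the causal-mutation position
(site 0).  Moving outward through the linkage sites, the origin switches
between consecutive sites with the local recombination probability; each
site emits its evidence pair (p_disease, p_normal).  A backward recursion
gives P(sites 1..N | origin at site 0) for each flank; the two flanks are
independent given the state at site 0 and multiply.  Bayes' theorem with
the Mendelian 0.5/0.5 prior then yields the embryo's disease-carrying
posterior.  PCR evidence at the mutation itself enters as a special
linkage site with recombination 0 to the hidden state.

All chain arithmetic runs in log space so that posteriors at the 1e-8
scale keep full relative precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

from .allele_origin import SiteEvidence

__all__ = [
    "CATEGORIES",
    "AnalysisConfig",
    "ChainSite",
    "LinkageChain",
    "EmbryoCall",
    "chain_conditional",
    "chain_log_conditional",
    "posterior_disease",
    "classify",
    "error_probability",
    "brute_force_posterior",
]

CATEGORIES = ("normal", "normal_risk", "risk", "disease_risk", "disease")

MODES = (
    "p_plus_10sites",     # fixed whitelist of sites, with proband
    "bayes_p_plus",       # all collected sites, proband phasing
    "bayes_p_plus_pb",    # proband phasing plus polar-body error filtering
    "bayes_p_minus",      # proband-free phasing from >=4 embryos
    "bayes_p_minus_sperm",  # proband-free phasing from sperm cells
)


@dataclass
class AnalysisConfig:
    """Tunable parameters of a linkage analysis run."""

    prior_disease: float = 0.5
    prior_normal: float = 0.5
    window_mb: float = 1.5
    min_reads: int = 2
    thresholds: tuple[float, float, float, float] = (1e-4, 0.1, 0.6, 0.9)
    mode: str = "bayes_p_plus"
    # genotype / amplification model
    ado_rate: float = 0.2
    false_allele_rate: float = 0.01
    base_error: float = 0.01
    carrier_het_floor: float = 0.5
    phase_mode_mass: float = 0.5   # majority-mass floor for phasing point calls
    min_phase_sources: int = 4
    anchor_fraction: float = 0.75
    site_whitelist: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if abs(self.prior_disease + self.prior_normal - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        t = self.thresholds
        if not (0.0 < t[0] < t[1] < t[2] < t[3] < 1.0):
            raise ValueError(f"thresholds {t} must be strictly increasing inside (0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; valid: {MODES}")


@dataclass
class ChainSite:
    """One linkage site in a chain: evidence pair plus the transition to the
    previous (nearer to the mutation) site."""

    pos: int
    p_disease: float
    p_normal: float
    r_to_prev: float  # recombination probability between this site and the previous one

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_to_prev <= 0.5):
            raise ValueError(f"transition {self.r_to_prev} outside [0, 0.5]")


@dataclass
class LinkageChain:
    """Ordered linkage sites on one flank of the mutation, nearest-first."""

    embryo_id: str
    sites: list[ChainSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        # sites must be strictly ordered by distance from the mutation;
        # positions on one flank are monotone, so check strict monotonicity
        pos = [s.pos for s in self.sites]
        if len(pos) >= 2:
            increasing = all(a < b for a, b in zip(pos, pos[1:]))
            decreasing = all(a > b for a, b in zip(pos, pos[1:]))
            if not (increasing or decreasing):
                raise ValueError("chain sites are not ordered by distance from the mutation")

    @classmethod
    def from_evidence(
        cls,
        embryo_id: str,
        evidence: list[SiteEvidence],
        transitions: list[float],
    ) -> "LinkageChain":
        if len(evidence) != len(transitions):
            raise ValueError("one transition per site required (site i to site i-1)")
        sites = [
            ChainSite(ev.pos, ev.p_disease, ev.p_normal, r)
            for ev, r in zip(evidence, transitions)
        ]
        return cls(embryo_id, sites)


def _log(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


def _logaddexp(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    m = max(a, b)
    return m + math.log1p(math.exp(-abs(a - b)))


def chain_log_conditional(chain: LinkageChain, state_at_mutation: str) -> float:
    """log P(sites 1..N | origin state at site 0), by backward recursion.

    Recursion (state D at site i-1):
        P(i..N | i-1 = D) = P(i+1..N | i = D) * p_d(i) * (1 - r_i)
                          + P(i+1..N | i = N) * p_n(i) * r_i
    and the mirror for state N; the empty chain contributes log 1 = 0.
    """
    if state_at_mutation not in ("disease", "normal"):
        raise ValueError(f"state must be 'disease' or 'normal', got {state_at_mutation!r}")
    g_d = 0.0  # log P(sites i+1..N | site i disease), starting past the far end
    g_n = 0.0
    for site in reversed(chain.sites):
        ld, ln = _log(site.p_disease), _log(site.p_normal)
        lr, lnr = _log(site.r_to_prev), _log(1.0 - site.r_to_prev)
        new_d = _logaddexp(g_d + ld + lnr, g_n + ln + lr)
        new_n = _logaddexp(g_d + ld + lr, g_n + ln + lnr)
        g_d, g_n = new_d, new_n
    return g_d if state_at_mutation == "disease" else g_n


def chain_conditional(chain: LinkageChain, state_at_mutation: str) -> float:
    """P(sites 1..N | origin state at site 0) on the probability scale."""
    return math.exp(chain_log_conditional(chain, state_at_mutation))


def posterior_disease(
    upstream: LinkageChain,
    downstream: LinkageChain,
    mutation_site_evidence: SiteEvidence | None = None,
    config: AnalysisConfig | None = None,
) -> float:
    """P(embryo carries disease | all sites), combining both flanks.

    The flanks are conditionally independent given the origin at the
    mutation; direct (PCR) evidence at the mutation site enters with
    recombination 0, i.e. as a plain factor per state.
    """
    if config is None:
        config = AnalysisConfig()
    if upstream.embryo_id != downstream.embryo_id:
        raise ValueError("chains belong to different embryos")
    log_l_d = (chain_log_conditional(upstream, "disease")
               + chain_log_conditional(downstream, "disease"))
    log_l_n = (chain_log_conditional(upstream, "normal")
               + chain_log_conditional(downstream, "normal"))
    if mutation_site_evidence is not None:
        log_l_d += _log(mutation_site_evidence.p_disease)
        log_l_n += _log(mutation_site_evidence.p_normal)
    log_num = log_l_d + _log(config.prior_disease)
    log_alt = log_l_n + _log(config.prior_normal)
    if log_num == -math.inf and log_alt == -math.inf:
        raise ZeroDivisionError(
            f"both state likelihoods vanish for embryo {upstream.embryo_id}: "
            "evidence is jointly impossible under either origin"
        )
    return math.exp(log_num - _logaddexp(log_num, log_alt))


def classify(p_disease: float, config: AnalysisConfig | None = None) -> str:
    """Five-category call from the disease posterior.

    Bounds (t1..t4 = 1e-4, 0.1, 0.6, 0.9 by default):
    p < t1 -> normal; t1 <= p < t2 -> normal_risk; t2 <= p <= t3 -> risk;
    t3 < p <= t4 -> disease_risk; p > t4 -> disease.  Boundary ties fall to
    the more cautious category.
    """
    t1, t2, t3, t4 = (config or AnalysisConfig()).thresholds
    if not (0.0 <= p_disease <= 1.0):
        raise ValueError(f"probability {p_disease} outside [0, 1]")
    if p_disease < t1:
        return "normal"
    if p_disease < t2:
        return "normal_risk"
    if p_disease <= t3:
        return "risk"
    if p_disease <= t4:
        return "disease_risk"
    return "disease"


def error_probability(p_disease: float, category: str) -> float:
    """Probability that the categorical call is wrong.

    p for normal-side calls, 1 - p for disease-side calls; a "risk" call is
    indeterminate and reports the symmetric worst case min(p, 1-p).
    """
    if category in ("normal", "normal_risk"):
        return p_disease
    if category in ("disease", "disease_risk"):
        return 1.0 - p_disease
    if category == "risk":
        return min(p_disease, 1.0 - p_disease)
    raise ValueError(f"unknown category {category!r}")


@dataclass
class EmbryoCall:
    """Final per-embryo result."""

    embryo_id: str
    p_disease: float
    category: str
    error_probability: float
    n_sites_used: int
    region_span_bp: int
    mode: str
    site_audit: list[dict] = field(default_factory=list)


def brute_force_posterior(
    upstream: LinkageChain,
    downstream: LinkageChain,
    mutation_site_evidence: SiteEvidence | None = None,
    config: AnalysisConfig | None = None,
) -> float:
    """Exact posterior by exhaustive enumeration of haplotype-origin paths.

    Enumerates every assignment of disease/normal origin to all sites
    (2^(N+N') paths), accumulating transition and emission weights per
    state at the mutation.  Verification oracle; refuses > 20 sites.
    """
    if config is None:
        config = AnalysisConfig()
    n_total = len(upstream.sites) + len(downstream.sites)
    if n_total > 20:
        raise ValueError(f"{n_total} sites: brute force limited to 20")

    def flank_likelihood(chain: LinkageChain, state0: str) -> float:
        total = 0.0
        n = len(chain.sites)
        for states in product(("disease", "normal"), repeat=n):
            w = 1.0
            prev = state0
            for site, st in zip(chain.sites, states):
                w *= (1.0 - site.r_to_prev) if st == prev else site.r_to_prev
                w *= site.p_disease if st == "disease" else site.p_normal
                prev = st
            total += w
        return total

    l_d = flank_likelihood(upstream, "disease") * flank_likelihood(downstream, "disease")
    l_n = flank_likelihood(upstream, "normal") * flank_likelihood(downstream, "normal")
    if mutation_site_evidence is not None:
        l_d *= mutation_site_evidence.p_disease
        l_n *= mutation_site_evidence.p_normal
    num = l_d * config.prior_disease
    den = num + l_n * config.prior_normal
    if den == 0.0:
        raise ZeroDivisionError("both state likelihoods vanish")
    return num / den
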