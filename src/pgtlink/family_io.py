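"""Family-level orchestration: inputs, analysis modes, reports.

Reads the multi-sample VCF and the sample sheet, validates the family
design against the causal-mutation specification, runs the selected
analysis mode end to end (phase -> collect linkage sites -> per-site
evidence -> recombination-aware chain -> posterior -> five-category call)
and writes tab-delimited / JSON reports with a per-site audit trail.

Genotype source policy: bulk samples (parents, proband) use imported
Phred-scaled genotype likelihoods (PL) when present, otherwise their
allele-depth read counts with a noiseless amplification model; single-cell
samples (embryos, sperm, polar bodies) always go through the
whole-genome-amplification error model over their read counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
import yaml

from . import allele_origin, genotype_model, linkage_bayes, phasing
from .allele_origin import LinkageSiteCandidate, SiteEvidence
from .genotype_model import AmplificationModel, GenotypePosterior, NO_AMPLIFICATION
from .linkage_bayes import AnalysisConfig, EmbryoCall, LinkageChain
from .recomb_map import RecombinationMap, recombination_probability

logger = logging.getLogger(__name__)

__all__ = [
    "MutationSpec",
    "SampleRecord",
    "FamilyDesign",
    "FamilyData",
    "FamilyValidationError",
    "load_family",
    "run_analysis",
    "write_reports",
]

SINGLE_CELL_ROLES = {"embryo", "sperm", "polar_body"}


class FamilyValidationError(ValueError):
    """Raised for inconsistent sample sheets or mutation specifications."""


@dataclass(frozen=True)
class MutationSpec:
    """The causal mutation under test."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    inheritance: str = "autosomal"
    carrier: str = "mother"

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise FamilyValidationError("mutation alleles must be non-empty")
        if self.inheritance not in ("autosomal", "x_linked"):
            raise FamilyValidationError("inheritance must be autosomal or x_linked")
        if self.carrier not in ("father", "mother", "both"):
            raise FamilyValidationError("carrier must be father, mother or both")


@dataclass
class SampleRecord:
    sample_id: str
    role: str
    sex: str | None = None
    linked_embryo: str | None = None
    affected: bool | None = None


@dataclass
class FamilyDesign:
    father_id: str
    mother_id: str
    embryo_ids: list[str]
    proband: tuple[str, bool] | None = None  # (sample_id, affected)
    polar_bodies: dict[str, dict[str, str]] = field(default_factory=dict)  # embryo -> {pb1, pb2}
    sperm_ids: list[str] = field(default_factory=list)
    sexes: dict[str, str] = field(default_factory=dict)

    def carrier_other(self, mutation: MutationSpec) -> tuple[str, str]:
        if mutation.carrier == "father":
            return self.father_id, self.mother_id
        return self.mother_id, self.father_id


@dataclass
class SiteRecord:
    """Per-site read summaries for every sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    counts: dict[str, tuple[int, int, int]]          # sample -> (ref, alt, other)
    pl: dict[str, tuple[int, ...] | None]


@dataclass
class FamilyData:
    design: FamilyDesign
    mutation: MutationSpec
    sites: dict[int, SiteRecord]                     # linkage sites, keyed by position
    mutation_site: SiteRecord


def _parse_sheet(path: str | Path) -> list[SampleRecord]:
    if str(path).endswith((".yaml", ".yml")):
        with open(path) as fh:
            entries = yaml.safe_load(fh) or []
        if isinstance(entries, dict):
            entries = entries.get("samples", [])
        return [
            SampleRecord(
                sample_id=str(e["sample_id"]),
                role=str(e["role"]),
                sex=e.get("sex"),
                linked_embryo=e.get("linked_embryo"),
                affected=None if e.get("affected") is None else bool(e["affected"]),
            )
            for e in entries
        ]
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("sample_id", "role"):
            if name not in idx:
                raise FamilyValidationError(f"sample sheet missing column {name!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def get(col: str) -> str | None:
                v = f[idx[col]] if col in idx and idx[col] < len(f) else "."
                return None if v in (".", "") else v

            affected = get("affected")
            records.append(SampleRecord(
                sample_id=f[idx["sample_id"]],
                role=f[idx["role"]],
                sex=get("sex"),
                linked_embryo=get("linked_embryo"),
                affected=None if affected is None else affected == "1",
            ))
    return records


def _build_design(records: list[SampleRecord], mutation: MutationSpec) -> FamilyDesign:
    by_role: dict[str, list[SampleRecord]] = {}
    seen = set()
    for r in records:
        if r.sample_id in seen:
            raise FamilyValidationError(f"duplicate sample id {r.sample_id}")
        seen.add(r.sample_id)
        by_role.setdefault(r.role, []).append(r)
    for role in ("father", "mother"):
        if len(by_role.get(role, [])) != 1:
            raise FamilyValidationError(f"exactly one {role} required")
    embryos = [r.sample_id for r in by_role.get("embryo", [])]
    if not embryos:
        raise FamilyValidationError("at least one embryo required")
    proband = None
    probands = by_role.get("proband", [])
    if len(probands) > 1:
        raise FamilyValidationError("at most one proband supported")
    if probands:
        p = probands[0]
        proband = (p.sample_id, bool(p.affected) if p.affected is not None else True)
    sperm = [r.sample_id for r in by_role.get("sperm", [])]
    if sperm and mutation.carrier != "father":
        raise FamilyValidationError("sperm samples require a paternal carrier")
    pbs: dict[str, dict[str, str]] = {}
    for r in by_role.get("polar_body", []):
        if mutation.carrier != "mother":
            raise FamilyValidationError("polar bodies require a maternal carrier")
        if not r.linked_embryo:
            raise FamilyValidationError(f"polar body {r.sample_id} missing linked_embryo")
        order = "pb2" if r.sample_id.upper().endswith("PB2") else "pb1"
        pbs.setdefault(r.linked_embryo, {})[order] = r.sample_id
    sexes = {r.sample_id: r.sex for r in records if r.sex}
    return FamilyDesign(
        father_id=by_role["father"][0].sample_id,
        mother_id=by_role["mother"][0].sample_id,
        embryo_ids=embryos,
        proband=proband,
        polar_bodies=pbs,
        sperm_ids=sperm,
        sexes=sexes,
    )


def load_family(
    sample_sheet: str | Path,
    vcf_path: str | Path,
    mutation: MutationSpec,
    window_mb: float = 1.5,
) -> FamilyData:
    """Read the sample sheet and the VCF window around the mutation.

    Multi-allelic records are skipped (logged); the mutation record must
    match the specified alleles exactly.
    """
    if mutation.carrier == "both":
        raise FamilyValidationError(
            "carrier='both' (compound heterozygous couple): analyse each "
            "mutation separately with its own carrier, one per invocation"
        )
    records = _parse_sheet(sample_sheet)
    design = _build_design(records, mutation)

    vcf = pysam.VariantFile(str(vcf_path))
    vcf_samples = set(vcf.header.samples)
    missing = [r.sample_id for r in records if r.sample_id not in vcf_samples]
    if missing:
        raise FamilyValidationError(f"samples absent from VCF: {missing}")

    window = int(window_mb * 1e6)
    lo, hi = mutation.pos - window, mutation.pos + window
    sites: dict[int, SiteRecord] = {}
    mutation_site: SiteRecord | None = None
    sample_ids = [r.sample_id for r in records]
    for rec in vcf:
        if rec.chrom != mutation.chrom or not (lo <= rec.pos <= hi):
            continue
        if rec.alts is None or len(rec.alts) != 1:
            logger.info("skipping multi-allelic site %s:%d", rec.chrom, rec.pos)
            continue
        counts: dict[str, tuple[int, int, int]] = {}
        pls: dict[str, tuple[int, ...] | None] = {}
        for sid in sample_ids:
            s = rec.samples[sid]
            ad = s.get("AD")
            dp = s.get("DP")
            n_ref = int(ad[0]) if ad and ad[0] is not None else 0
            n_alt = int(ad[1]) if ad and len(ad) > 1 and ad[1] is not None else 0
            depth = int(dp) if dp is not None else n_ref + n_alt
            counts[sid] = (n_ref, n_alt, max(depth - n_ref - n_alt, 0))
            pl = s.get("PL")
            pls[sid] = tuple(int(v) for v in pl) if pl and pl[0] is not None else None
        site = SiteRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], counts, pls)
        if rec.pos == mutation.pos:
            if (rec.ref, rec.alts[0]) != (mutation.ref_allele, mutation.alt_allele):
                raise FamilyValidationError(
                    f"mutation record at {rec.chrom}:{rec.pos} has alleles "
                    f"{rec.ref}>{rec.alts[0]}, expected "
                    f"{mutation.ref_allele}>{mutation.alt_allele}"
                )
            mutation_site = site
        else:
            sites[rec.pos] = site
    if mutation_site is None:
        raise FamilyValidationError(
            f"no VCF record at the mutation position {mutation.chrom}:{mutation.pos}"
        )
    return FamilyData(design, mutation, sites, mutation_site)


# ---------------------------------------------------------------------------
# posterior computation
# ---------------------------------------------------------------------------

def _is_haploid(sid: str, data: FamilyData) -> bool:
    design, mut = data.design, data.mutation
    if sid in design.sperm_ids:
        return True
    if sid.upper().endswith("PB2"):
        return True
    if mut.inheritance == "x_linked":
        if sid == design.father_id:
            return True
        if design.sexes.get(sid) == "male" and sid != design.father_id:
            return True
    return False


def _sample_posterior_arrays(
    data: FamilyData, positions: list[int], config: AnalysisConfig, sid: str
) -> np.ndarray:
    """(S, 3) diploid or (S, 2) haploid posterior array for one sample."""
    amp = AmplificationModel(config.ado_rate, config.false_allele_rate)
    design = data.design
    bulk = {design.father_id, design.mother_id}
    if design.proband:
        bulk.add(design.proband[0])
    n_ref = np.array([data.sites[p].counts[sid][0] for p in positions])
    n_alt = np.array([data.sites[p].counts[sid][1] for p in positions])
    n_oth = np.array([data.sites[p].counts[sid][2] for p in positions])
    haploid = _is_haploid(sid, data)
    if sid in bulk:
        if haploid:
            post = genotype_model.haploid_posteriors_from_counts(
                n_ref, n_alt, n_oth, NO_AMPLIFICATION, config.base_error)
        else:
            post = genotype_model.posteriors_from_counts(
                n_ref, n_alt, n_oth, NO_AMPLIFICATION, config.base_error)
        # imported PL records win where present
        for i, p in enumerate(positions):
            pl = data.sites[p].pl.get(sid)
            if pl is not None and len(pl) == post.shape[1]:
                gp = genotype_model.posterior_from_pl(
                    sid, data.sites[p].chrom, p,
                    data.sites[p].ref, data.sites[p].alt, pl)
                post[i] = list(gp.probs.values())
        return post
    if haploid:
        return genotype_model.haploid_posteriors_from_counts(
            n_ref, n_alt, n_oth, amp, config.base_error)
    return genotype_model.posteriors_from_counts(
        n_ref, n_alt, n_oth, amp, config.base_error)


def _as_posterior_dict(
    data: FamilyData, positions: list[int], post: np.ndarray, sid: str
) -> dict[int, GenotypePosterior]:
    out = {}
    haploid = post.shape[1] == 2
    for i, p in enumerate(positions):
        site = data.sites[p]
        if haploid:
            gts = genotype_model.haploid_genotypes(site.ref, site.alt)
            ploidy = "haploid"
        else:
            gts = genotype_model.diploid_genotypes(site.ref, site.alt)
            ploidy = "diploid"
        probs = dict(zip(gts, (float(v) for v in post[i])))
        total = sum(probs.values())
        probs = {g: v / total for g, v in probs.items()}
        out[p] = GenotypePosterior(sid, site.chrom, p, probs, ploidy)
    return out


def _mutation_posterior(
    data: FamilyData, config: AnalysisConfig, sid: str
) -> GenotypePosterior:
    site = data.mutation_site
    amp = AmplificationModel(config.ado_rate, config.false_allele_rate)
    design = data.design
    bulk = {design.father_id, design.mother_id}
    if design.proband:
        bulk.add(design.proband[0])
    n_ref, n_alt, n_oth = site.counts[sid]
    arr = (np.array([n_ref]), np.array([n_alt]), np.array([n_oth]))
    haploid = _is_haploid(sid, data)
    model = NO_AMPLIFICATION if sid in bulk else amp
    if haploid:
        post = genotype_model.haploid_posteriors_from_counts(*arr, model, config.base_error)
        gts = genotype_model.haploid_genotypes(site.ref, site.alt)
        ploidy = "haploid"
    else:
        post = genotype_model.posteriors_from_counts(*arr, model, config.base_error)
        gts = genotype_model.diploid_genotypes(site.ref, site.alt)
        ploidy = "diploid"
    probs = dict(zip(gts, (float(v) for v in post[0])))
    total = sum(probs.values())
    return GenotypePosterior(sid, site.chrom, site.pos, {g: v / total for g, v in probs.items()}, ploidy)


def _carries_mutation(post: GenotypePosterior, alt: str, min_mass: float) -> bool | None:
    gt = post.mode(min_mass)
    if gt is None:
        return None
    return alt in gt


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _phase(
    data: FamilyData,
    config: AnalysisConfig,
    posts: dict[str, dict[int, GenotypePosterior]],
    mut_posts: dict[str, GenotypePosterior],
) -> tuple[phasing.ParentalHaplotypePair, dict[str, set[int]]]:
    design, mutation = data.design, data.mutation
    carrier_id, other_id = design.carrier_other(mutation)
    exclusions: dict[str, set[int]] = {}

    def transmitted(sid: str, kind: str) -> phasing.TransmittedAllele:
        return phasing.transmitted_from_posteriors(
            sid, posts[carrier_id],
            posts[other_id] if kind == "embryo" else None,
            posts[sid],
            min_mass=config.phase_mode_mass,
            inheritance=mutation.inheritance,
            sample_kind=kind,
            sample_sex=design.sexes.get(sid),
        )

    if config.mode in ("p_plus_10sites", "bayes_p_plus", "bayes_p_plus_pb"):
        if design.proband is None:
            raise FamilyValidationError(f"mode {config.mode} requires a proband sample")
        proband_id, affected = design.proband
        pair = phasing.phase_with_proband(
            posts[proband_id], posts[carrier_id], posts[other_id],
            "affected" if affected else "unaffected",
            carrier_id=carrier_id,
            min_mass=config.phase_mode_mass,
            inheritance=mutation.inheritance,
            proband_sex=design.sexes.get(proband_id),
        )
        if config.mode == "bayes_p_plus_pb":
            if mutation.carrier != "mother":
                raise FamilyValidationError("polar-body mode requires a maternal carrier")
            embryo_trans = {e: transmitted(e, "embryo") for e in design.embryo_ids}
            pb2_alleles: dict[str, dict[int, str | None]] = {}
            for embryo, pbs in design.polar_bodies.items():
                pb2 = pbs.get("pb2")
                if pb2 is None or pb2 not in posts:
                    continue
                pb2_alleles[embryo] = {
                    p: (gp.mode(config.phase_mode_mass) or (None,))[0]
                    for p, gp in posts[pb2].items()
                }
            pair, exclusions = phasing.augment_with_polar_bodies(
                pair, embryo_trans, pb2_alleles, carrier_role=mutation.carrier
            )
        return pair, exclusions

    if config.mode == "bayes_p_minus":
        sources = design.embryo_ids
        kinds = {s: "embryo" for s in sources}
    elif config.mode == "bayes_p_minus_sperm":
        if mutation.carrier != "father":
            raise FamilyValidationError("sperm phasing requires a paternal carrier")
        if not design.sperm_ids:
            raise FamilyValidationError("sperm phasing mode but no sperm samples in the design")
        sources = design.sperm_ids
        kinds = {s: "sperm" for s in sources}
    else:  # pragma: no cover - AnalysisConfig already validates
        raise FamilyValidationError(f"unknown mode {config.mode!r}")
    if len(sources) < config.min_phase_sources:
        raise FamilyValidationError(
            f"proband-free phasing needs at least {config.min_phase_sources} sources "
            f"(embryos or sperm); the design has {len(sources)}"
        )
    trans = [transmitted(s, kinds[s]) for s in sources]
    mut_evidence = {}
    for s in sources:
        carries = _carries_mutation(
            mut_posts[s], data.mutation_site.alt, config.phase_mode_mass)
        if carries is not None:
            mut_evidence[s] = carries
    carrier_gts = {}
    for pos, gp in posts[carrier_id].items():
        gt = gp.mode(config.phase_mode_mass)
        if gt is not None and len(gt) == 2 and gt[0] != gt[1]:
            carrier_gts[pos] = (gt[0], gt[1])
    pair = phasing.phase_without_proband(
        trans, mut_evidence,
        carrier_id=data.design.carrier_other(mutation)[0],
        min_sources=config.min_phase_sources,
        anchor_fraction=config.anchor_fraction,
        carrier_genotypes=carrier_gts,
    )
    return pair, exclusions


def run_analysis(
    data: FamilyData,
    config: AnalysisConfig,
    rmap: RecombinationMap,
) -> list[EmbryoCall]:
    """Run the selected analysis mode for every embryo in the design.

    Deterministic given inputs and configuration.
    """
    design, mutation = data.design, data.mutation
    carrier_id, other_id = design.carrier_other(mutation)
    positions = sorted(data.sites)

    needed = {carrier_id, other_id, *design.embryo_ids, *design.sperm_ids}
    if design.proband:
        needed.add(design.proband[0])
    for pbs in design.polar_bodies.values():
        needed.update(pbs.values())
    arrays = {sid: _sample_posterior_arrays(data, positions, config, sid) for sid in needed}
    posts = {sid: _as_posterior_dict(data, positions, arrays[sid], sid) for sid in needed}
    mut_posts = {sid: _mutation_posterior(data, config, sid) for sid in needed}

    pair, exclusions = _phase(data, config, posts, mut_posts)

    mut_alt_is_disease = True  # by definition the disease haplotype carries the mutant allele
    mut_phase = (data.mutation_site.alt, data.mutation_site.ref)
    carrier_arr = arrays[carrier_id]
    pos_index = {p: i for i, p in enumerate(positions)}

    calls: list[EmbryoCall] = []
    for embryo in design.embryo_ids:
        excl = exclusions.get(embryo, set())
        candidates = []
        for p in sorted(pair.phase):
            if p in excl or p not in pos_index:
                continue
            site = data.sites[p]
            depth = sum(site.counts[embryo])
            het_mass = float(carrier_arr[pos_index[p]][1]) if carrier_arr.shape[1] == 3 else 0.0
            candidates.append(LinkageSiteCandidate(
                site.chrom, p, depth, het_mass, phase_known=True,
                has_pl=site.pl.get(embryo) is not None,
            ))
        upstream_c, downstream_c = allele_origin.collect_linkage_sites(
            candidates, mutation.pos,
            window_mb=config.window_mb,
            min_reads=config.min_reads,
            carrier_het_floor=config.carrier_het_floor,
            whitelist=config.site_whitelist if config.mode == "p_plus_10sites" else None,
        )

        # X-linked families mix ploidies (hemizygous father, male embryos),
        # so they take the scalar evidence route; autosomal uses the
        # vectorised batch, which is numerically identical
        use_scalar = mutation.inheritance == "x_linked"

        def evidence_for(cands: list[LinkageSiteCandidate]) -> list[SiteEvidence]:
            if not cands:
                return []
            if use_scalar:
                return [
                    allele_origin.site_evidence(
                        posts[carrier_id][c.pos], posts[other_id][c.pos],
                        posts[embryo][c.pos], pair.phase[c.pos],
                        inheritance="x_linked",
                        embryo_sex=design.sexes.get(embryo))
                    for c in cands
                ]
            idx = [pos_index[c.pos] for c in cands]
            alt_is_disease = np.array(
                [pair.phase[c.pos][0] == data.sites[c.pos].alt for c in cands])
            p_d, p_n = allele_origin.site_evidence_batch(
                arrays[carrier_id][idx], arrays[other_id][idx],
                arrays[embryo][idx], alt_is_disease)
            return [
                SiteEvidence(embryo, c.chrom, c.pos, float(d), float(n))
                for c, d, n in zip(cands, p_d, p_n)
            ]

        def build_chain(cands: list[LinkageSiteCandidate]) -> LinkageChain:
            ev = evidence_for(cands)
            transitions = []
            prev = mutation.pos
            for c in cands:
                transitions.append(
                    recombination_probability(rmap, mutation.chrom, prev, c.pos))
                prev = c.pos
            return LinkageChain.from_evidence(embryo, ev, transitions)

        up_chain = build_chain(upstream_c)
        down_chain = build_chain(downstream_c)

        mut_ev = allele_origin.site_evidence(
            mut_posts[carrier_id], mut_posts[other_id], mut_posts[embryo],
            mut_phase,
            inheritance=mutation.inheritance,
            embryo_sex=design.sexes.get(embryo),
        )
        p = linkage_bayes.posterior_disease(up_chain, down_chain, mut_ev, config)
        category = linkage_bayes.classify(p, config)
        err = linkage_bayes.error_probability(p, category)
        used_pos = [c.pos for c in upstream_c + downstream_c] + [mutation.pos]
        audit = []
        for side, chain in (("upstream", up_chain), ("downstream", down_chain)):
            for s in chain.sites:
                audit.append({
                    "embryo_id": embryo, "side": side, "pos": s.pos,
                    "p_disease": s.p_disease, "p_normal": s.p_normal,
                    "r_to_prev": s.r_to_prev,
                })
        audit.append({
            "embryo_id": embryo, "side": "mutation", "pos": mutation.pos,
            "p_disease": mut_ev.p_disease, "p_normal": mut_ev.p_normal,
            "r_to_prev": 0.0,
        })
        calls.append(EmbryoCall(
            embryo_id=embryo,
            p_disease=p,
            category=category,
            error_probability=err,
            n_sites_used=len(used_pos),
            region_span_bp=max(used_pos) - min(used_pos),
            mode=config.mode,
            site_audit=audit,
        ))
    return calls


def write_reports(
    calls: list[EmbryoCall],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Write calls.tsv, calls.json, audit.tsv and a run log."""
    if not calls:
        raise ValueError("no calls to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "calls.tsv"
    cols = ("embryo_id", "mode", "p_disease", "category",
            "error_probability", "n_sites_used", "region_span_bp")
    with open(tsv, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            fh.write("\t".join([
                c.embryo_id, c.mode, f"{c.p_disease:.10g}", c.category,
                f"{c.error_probability:.10g}", str(c.n_sites_used),
                str(c.region_span_bp),
            ]) + "\n")
    js = out_dir / "calls.json"
    with open(js, "w") as fh:
        json.dump([
            {k: v for k, v in dataclasses.asdict(c).items() if k != "site_audit"}
            for c in calls
        ], fh, indent=1)
    audit = out_dir / "audit.tsv"
    with open(audit, "w") as fh:
        fh.write("embryo_id\tside\tpos\tp_disease\tp_normal\tr_to_prev\n")
        for c in calls:
            for row in c.site_audit:
                fh.write("\t".join([
                    row["embryo_id"], row["side"], str(row["pos"]),
                    f"{row['p_disease']:.10g}", f"{row['p_normal']:.10g}",
                    f"{row['r_to_prev']:.10g}",
                ]) + "\n")
    log = out_dir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write("pgtlink analysis log\n")
        if config is not None:
            for f_ in dataclasses.fields(config):
                fh.write(f"{f_.name} = {getattr(config, f_.name)}\n")
    return {"tsv": tsv, "json": js, "audit": audit, "log": log}
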