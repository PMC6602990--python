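"""Synthetic PGT-M families with known ground truth.

Generates a nuclear IVF family — carrier and non-carrier parent, biopsied
embryos, optionally a proband, sperm cells and polar bodies — over a
window of biallelic SNVs flanking a causal mutation, then pushes every
single-cell genome through a whole-genome-amplification noise channel
(allele dropout, spurious alleles) and a shallow-read sampler with
miscalls.  Outputs are the standard formats the analysis pipeline
consumes: a multi-sample VCF 4.2, a sample-sheet TSV, a recombination-map
TSV and a truth JSON.

Model choices: each meiosis places crossover breakpoints as a Poisson
process (no interference) at the map rate; the carrier parent is
heterozygous at every simulated linkage site (these are the candidate
informative sites); the other parent's genotypes are drawn with
heterozygosity ~0.5 so informative, ambiguous and uninformative
combinations all occur.  Parents and the proband are bulk DNA: deep
coverage, no amplification noise, Phred-scaled genotype likelihoods (PL)
included.  The causal-mutation site is covered deeply in every sample,
emulating targeted PCR of the mutation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "FamilyDataset",
    "CorruptionRecord",
    "simulate_family",
    "corrupt_sites",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationParams:
    """Stated world of the simulator; defaults emulate shallow (~2x)
    single-cell MALBAC sequencing around a causal mutation."""

    seed: int
    chrom: str = "chr11"
    mutation_pos: int = 5_000_000
    window_mb: float = 1.5           # each side of the mutation
    n_sites: int = 100               # candidate linkage sites in the window
    rate_per_mb: float = 0.01        # crossover probability per Mb (~1 cM/Mb)
    ado_rate: float = 0.2
    false_allele_rate: float = 0.01
    base_error: float = 0.01
    depth_min: int = 2
    depth_max: int = 5
    n_embryos: int = 6
    n_sperm: int = 0
    with_polar_bodies: bool = False
    with_proband: bool = True
    carrier: str = "mother"
    inheritance: str = "autosomal"
    other_het: float = 0.5           # heterozygosity of the non-carrier parent
    parent_depth: int = 30           # bulk DNA depth (parents, proband)
    mutation_depth: int = 50         # PCR-amplified depth at the mutation site
    embryo_sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("rate_per_mb", "ado_rate", "false_allele_rate", "base_error"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} {v} outside [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.carrier not in ("father", "mother"):
            raise ValueError("carrier must be father or mother")
        if self.inheritance not in ("autosomal", "x_linked"):
            raise ValueError("inheritance must be autosomal or x_linked")
        if self.inheritance == "x_linked" and self.carrier != "mother":
            raise ValueError("x-linked simulation models a carrier mother")
        if self.n_sperm and self.carrier != "father":
            raise ValueError("sperm samples require a paternal carrier")
        if self.with_polar_bodies and self.carrier != "mother":
            raise ValueError("polar bodies require a maternal carrier")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated family."""

    positions: list[int]                       # all sites incl. the mutation, sorted
    mutation_pos: int
    ref_alleles: dict[int, str]
    alt_alleles: dict[int, str]
    phase: dict[int, tuple[str, str]]          # carrier (disease, normal) allele per site
    origins: dict[str, dict[int, int]]         # carrier chromatid origin (1 = disease)
    true_genotypes: dict[str, dict[int, tuple[str, ...]]]
    breakpoints: dict[str, list[int]]
    disease_status: dict[str, bool]            # per embryo (and proband)
    embryo_sex: dict[str, str]


@dataclass
class FamilyDataset:
    vcf: Path
    sample_sheet: Path
    recomb_map: Path
    truth_json: Path
    truth: SimulationTruth
    params: SimulationParams


def _meiosis(rng, positions, hap_a, hap_b, rate_per_mb, win_start, win_end):
    """One meiotic product: allele vector, origin vector (1 = hap_a), breakpoints."""
    span_mb = (win_end - win_start) / 1e6
    n_break = rng.poisson(rate_per_mb * span_mb)
    breaks = np.sort(rng.integers(win_start, win_end, size=n_break))
    start_on_a = int(rng.integers(2)) == 0
    n_below = np.searchsorted(breaks, positions, side="right")
    on_a = (n_below % 2 == 0) == start_on_a
    alleles = np.where(on_a, hap_a, hap_b)
    return alleles, on_a.astype(int), [int(b) for b in breaks]


def _amplify(rng, gt, params):
    """WGA channel on genotype codes (0 hom-ref, 1 het, 2 hom-alt)."""
    out = gt.copy()
    u = rng.random(gt.shape)
    side = rng.integers(2, size=gt.shape)
    het = gt == 1
    dropout = het & (u < params.ado_rate)
    out[dropout] = np.where(side[dropout] == 0, 0, 2)
    hom = ~het
    gain = hom & (u < params.false_allele_rate)
    out[gain] = 1
    return out


def _read_pvals(base_error: float) -> np.ndarray:
    """(3, 3) read-class probabilities (ref, alt, other) per genotype code."""
    e = base_error
    return np.array([
        [1 - e, e / 3, 2 * e / 3],
        [0.5 * (1 - e) + 0.5 * e / 3, 0.5 * (1 - e) + 0.5 * e / 3, 2 * e / 3],
        [e / 3, 1 - e, 2 * e / 3],
    ])


def _sample_reads(rng, gt_codes, depths, base_error):
    """(S, 3) counts of (ref, alt, other) reads per site."""
    pvals = _read_pvals(base_error)[gt_codes]
    return rng.multinomial(depths, pvals)


def _pl_from_counts(counts: np.ndarray, base_error: float) -> np.ndarray:
    """GATK-style normalised Phred genotype likelihoods from read counts."""
    from .genotype_model import likelihoods_from_counts

    lik = likelihoods_from_counts(counts[:, 0], counts[:, 1], counts[:, 2], base_error)
    with np.errstate(divide="ignore"):
        phred = -10.0 * np.log10(lik)
    phred = phred - phred.min(axis=1, keepdims=True)
    # cap like typical callers; also keeps htslib from flagging extreme values
    return np.minimum(np.nan_to_num(np.rint(phred), posinf=990), 990).astype(int)


def simulate_family(params: SimulationParams, out_dir: str | Path) -> FamilyDataset:
    """Simulate one family and write its VCF, sample sheet, map and truth.

    Deterministic: identical parameters (including the seed) produce
    byte-identical output files.
    """
    rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    win = int(params.window_mb * 1e6)
    win_start, win_end = params.mutation_pos - win, params.mutation_pos + win
    # distinct linkage-site positions, never colliding with the mutation
    site_pos: set[int] = set()
    while len(site_pos) < params.n_sites:
        draw = rng.integers(win_start, win_end + 1, size=2 * params.n_sites)
        site_pos.update(int(p) for p in draw if p != params.mutation_pos)
    pool = np.array(sorted(site_pos))
    pick = rng.permutation(len(pool))[: params.n_sites]
    positions = np.sort(pool[pick])
    all_pos = np.sort(np.append(positions, params.mutation_pos))
    mut_idx = int(np.searchsorted(all_pos, params.mutation_pos))
    n_all = len(all_pos)

    # alleles: random distinct ref/alt base per site
    ref_idx = rng.integers(4, size=n_all)
    alt_off = rng.integers(1, 4, size=n_all)
    alt_idx = (ref_idx + alt_off) % 4
    ref = np.array(_BASES)[ref_idx]
    alt = np.array(_BASES)[alt_idx]

    # carrier haplotypes (codes 0=ref, 1=alt): heterozygous everywhere,
    # disease haplotype carries the mutation's alt allele
    disease_hap = rng.integers(2, size=n_all)
    disease_hap[mut_idx] = 1
    normal_hap = 1 - disease_hap

    # other parent: two haplotypes with ~other_het heterozygosity; hom-ref at
    # the mutation.  X-linked: the father has a single X haplotype.
    hemizygous_father = params.inheritance == "x_linked"
    other_h1 = (rng.random(n_all) < 0.5).astype(int)
    keep_hom = rng.random(n_all) >= params.other_het
    other_h2 = np.where(keep_hom, other_h1, 1 - other_h1)
    other_h1[mut_idx] = other_h2[mut_idx] = 0
    if hemizygous_father:
        other_h2 = other_h1

    carrier_id = "MOTHER" if params.carrier == "mother" else "FATHER"
    other_id = "FATHER" if params.carrier == "mother" else "MOTHER"

    truth = SimulationTruth(
        positions=[int(p) for p in all_pos],
        mutation_pos=params.mutation_pos,
        ref_alleles={int(p): str(r) for p, r in zip(all_pos, ref)},
        alt_alleles={int(p): str(a) for p, a in zip(all_pos, alt)},
        phase={
            int(p): (str(_allele(d, r, a)), str(_allele(n, r, a)))
            for p, d, n, r, a in zip(all_pos, disease_hap, normal_hap, ref, alt)
        },
        origins={},
        true_genotypes={},
        breakpoints={},
        disease_status={},
        embryo_sex={},
    )

    samples: list[tuple[str, str, str | None, str | None]] = []  # id, role, sex, linked
    gt_codes: dict[str, np.ndarray] = {}      # true genotype codes per sample
    ploidy: dict[str, int] = {}

    def add_diploid_truth(name: str, a1: np.ndarray, a2: np.ndarray) -> None:
        gt_codes[name] = a1 + a2
        ploidy[name] = 2
        truth.true_genotypes[name] = {
            int(p): tuple(sorted((_allele(x, r, al), _allele(y, r, al))))
            for p, x, y, r, al in zip(all_pos, a1, a2, ref, alt)
        }

    def add_haploid_truth(name: str, a1: np.ndarray) -> None:
        gt_codes[name] = a1 * 2  # code 0 or 2 for read sampling
        ploidy[name] = 1
        truth.true_genotypes[name] = {
            int(p): (_allele(x, r, al),) for p, x, r, al in zip(all_pos, a1, ref, alt)
        }

    add_diploid_truth(carrier_id, disease_hap, normal_hap)
    samples.append((carrier_id, params.carrier, "female" if params.carrier == "mother" else "male", None))
    if hemizygous_father and other_id == "FATHER":
        add_haploid_truth(other_id, other_h1)
    else:
        add_diploid_truth(other_id, other_h1, other_h2)
    samples.append((other_id, "father" if other_id == "FATHER" else "mother",
                    "male" if other_id == "FATHER" else "female", None))

    def carrier_meiosis():
        alleles, on_disease, breaks = _meiosis(
            rng, all_pos, disease_hap, normal_hap, params.rate_per_mb, win_start, win_end
        )
        return alleles, on_disease, breaks

    def other_meiosis():
        alleles, _, breaks = _meiosis(
            rng, all_pos, other_h1, other_h2, params.rate_per_mb, win_start, win_end
        )
        return alleles, breaks

    def make_child(name: str, role: str) -> None:
        sex = "male" if rng.random() < params.embryo_sex_ratio else "female"
        egg_or_carrier, on_disease, breaks = carrier_meiosis()
        truth.origins[name] = {int(p): int(o) for p, o in zip(all_pos, on_disease)}
        truth.breakpoints[name] = breaks
        truth.disease_status[name] = bool(on_disease[mut_idx])
        truth.embryo_sex[name] = sex
        if params.inheritance == "x_linked" and sex == "male":
            add_haploid_truth(name, egg_or_carrier)
        else:
            other_allele, _ = other_meiosis()
            add_diploid_truth(name, egg_or_carrier, other_allele)
        samples.append((name, role, sex, None))
        if params.with_polar_bodies and role == "embryo":
            # PB2: sister chromatid of the egg pronucleus (identical in the
            # window absent a crossover between sisters); PB1: the other
            # homolog pair, i.e. a heterozygous carrier-like genotype
            pb2 = f"{name}_PB2"
            add_haploid_truth(pb2, egg_or_carrier)
            truth.origins[pb2] = truth.origins[name]
            samples.append((pb2, "polar_body", None, name))
            pb1 = f"{name}_PB1"
            add_diploid_truth(pb1, disease_hap, normal_hap)
            samples.append((pb1, "polar_body", None, name))

    if params.with_proband:
        make_child("PROBAND", "proband")
    for i in range(params.n_embryos):
        make_child(f"E{i + 1}", "embryo")
    for i in range(params.n_sperm):
        name = f"S{i + 1}"
        alleles, on_disease, breaks = carrier_meiosis()
        truth.origins[name] = {int(p): int(o) for p, o in zip(all_pos, on_disease)}
        truth.breakpoints[name] = breaks
        truth.disease_status[name] = bool(on_disease[mut_idx])
        add_haploid_truth(name, alleles)
        samples.append((name, "sperm", None, None))

    bulk = {carrier_id, other_id} | ({"PROBAND"} if params.with_proband else set())

    # amplification + read sampling
    counts: dict[str, np.ndarray] = {}
    amp_codes: dict[str, np.ndarray] = {}
    pls: dict[str, np.ndarray] = {}
    for name, role, sex, linked in samples:
        codes = gt_codes[name]
        if name in bulk:
            amp = codes
            depths = np.full(n_all, params.parent_depth)
        else:
            amp = _amplify(rng, codes, params)
            depths = rng.integers(params.depth_min, params.depth_max + 1, size=n_all)
        depths = depths.copy()
        depths[mut_idx] = params.mutation_depth
        amp_codes[name] = amp
        counts[name] = _sample_reads(rng, amp, depths, params.base_error)
        if name in bulk:
            pls[name] = _pl_from_counts(counts[name], params.base_error)

    vcf_path = out_dir / "family.vcf"
    _write_vcf(vcf_path, params, samples, all_pos, ref, alt,
               amp_codes, counts, pls, ploidy)

    sheet_path = out_dir / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\trole\tsex\tlinked_embryo\taffected\n")
        for name, role, sex, linked in samples:
            affected = ""
            if role == "proband":
                affected = "1" if truth.disease_status[name] else "0"
            fh.write(f"{name}\t{role}\t{sex or '.'}\t{linked or '.'}\t{affected or '.'}\n")

    map_path = out_dir / "recomb_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("chrom\tstart\tend\trate\n")
        fh.write(f"{params.chrom}\t{win_start}\t{win_end}\t{params.rate_per_mb * 100:.6g}\n")

    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)

    return FamilyDataset(vcf_path, sheet_path, map_path, truth_path, truth, params)


def _allele(code: int, ref: str, alt: str) -> str:
    return alt if code else ref


def _gt_string(amp_code: int, ploid: int) -> str:
    if ploid == 1:
        return "1" if amp_code >= 1 else "0"
    return {0: "0/0", 1: "0/1", 2: "1/1"}[amp_code]


def _write_vcf(path, params, samples, all_pos, ref, alt, amp_codes, counts, pls, ploidy):
    names = [s[0] for s in samples]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={params.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred genotype likelihoods">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names),
    ]
    for i, pos in enumerate(all_pos):
        fields = [params.chrom, str(int(pos)), ".", str(ref[i]), str(alt[i]),
                  ".", "PASS", ".", "GT:AD:DP:PL"]
        for name in names:
            c = counts[name][i]
            dp = int(c.sum())
            ad = f"{int(c[0])},{int(c[1])}"
            gt = _gt_string(int(amp_codes[name][i]), ploidy[name])
            if name in pls:
                pl_row = pls[name][i]
                pl = ",".join(str(int(v)) for v in (pl_row if ploidy[name] == 2 else pl_row[[0, 2]]))
            else:
                pl = "."
            fields.append(f"{gt}:{ad}:{dp}:{pl}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _truth_to_json(truth: SimulationTruth) -> dict:
    d = asdict(truth)
    # JSON keys must be strings
    for key in ("ref_alleles", "alt_alleles", "phase"):
        d[key] = {str(k): v for k, v in d[key].items()}
    d["origins"] = {s: {str(k): v for k, v in m.items()} for s, m in d["origins"].items()}
    d["true_genotypes"] = {
        s: {str(k): list(v) for k, v in m.items()} for s, m in d["true_genotypes"].items()
    }
    return d


@dataclass(frozen=True)
class CorruptionRecord:
    chrom: str
    pos: int
    sample_id: str
    old_gt: str
    new_gt: str


def corrupt_sites(
    vcf_path: str | Path,
    fraction: float,
    seed: int,
    out_path: str | Path,
    samples: list[str] | None = None,
    exclude_pos: set[int] | None = None,
) -> list[CorruptionRecord]:
    """Flip the genotype of a random site subset, one random sample each.

    The flipped sample gets a confidently wrong genotype (clean allele
    depths at the same coverage), emulating the mapping/repeat-region
    genotype errors that the discordance filters must catch.  Returns the
    corruption records.
    """
    if not (0.0 <= fraction <= 0.5):
        raise ValueError("fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    with open(vcf_path) as fh:
        lines = fh.read().splitlines()
    header = [l for l in lines if l.startswith("#")]
    body = [l for l in lines if not l.startswith("#")]
    names = header[-1].split("\t")[9:]
    pool = samples if samples is not None else names
    pool_idx = [names.index(s) for s in pool]

    eligible = []
    for row_i, line in enumerate(body):
        pos = int(line.split("\t", 2)[1])
        if exclude_pos and pos in exclude_pos:
            continue
        eligible.append(row_i)
    n_corrupt = int(round(fraction * len(eligible)))
    records: list[CorruptionRecord] = []
    if n_corrupt == 0:
        Path(out_path).write_text("\n".join(header + body) + "\n")
        return records
    chosen = rng.choice(len(eligible), size=n_corrupt, replace=False)
    for k in sorted(int(c) for c in chosen):
        row_i = eligible[k]
        fields = body[row_i].split("\t")
        si = pool_idx[int(rng.integers(len(pool_idx)))]
        sample_field = fields[9 + si].split(":")
        old_gt = sample_field[0]
        haploid = "/" not in old_gt and "|" not in old_gt
        options = ["0", "1"] if haploid else ["0/0", "0/1", "1/1"]
        options = [g for g in options if g != old_gt]
        new_gt = options[int(rng.integers(len(options)))]
        dp = int(sample_field[2]) if sample_field[2] != "." else 5
        dp = max(dp, 4)
        if new_gt in ("0", "0/0"):
            ad = (dp, 0)
        elif new_gt in ("1", "1/1"):
            ad = (0, dp)
        else:
            ad = (dp - dp // 2, dp // 2)
        sample_field[0] = new_gt
        sample_field[1] = f"{ad[0]},{ad[1]}"
        sample_field[2] = str(dp)
        if len(sample_field) > 3 and sample_field[3] != ".":
            n_pl = len(sample_field[3].split(","))
            idx = {"0/0": 0, "0/1": 1, "1/1": 2, "0": 0, "1": n_pl - 1}[new_gt]
            pl = ["255"] * n_pl
            pl[idx] = "0"
            sample_field[3] = ",".join(pl)
        fields[9 + si] = ":".join(sample_field)
        body[row_i] = "\t".join(fields)
        records.append(
            CorruptionRecord(fields[0], int(fields[1]), names[si], old_gt, new_gt)
        )
    Path(out_path).write_text("\n".join(header + body) + "\n")
    return records
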