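# Methods

## Model overview

pgtlink computes, for each IVF embryo, the posterior probability that it
inherited the disease-carrying haplotype of a known carrier parent. The
computation has four layers:

1. **Genotype layer** — per-sample, per-site posteriors over
   {hom-ref, het, hom-alt} (or {ref, alt} for hemizygous samples) given
   read observations, under a whole-genome-amplification error model.
2. **Evidence layer** — per-embryo, per-site probability pair
   (p_disease, p_normal) that the carrier-transmitted allele at that site
   lies on the disease vs the normal haplotype, obtained by enumerating
   all genotype combinations of carrier, other parent and embryo.
3. **Chain layer** — a two-state (disease/normal origin) chain over the
   linkage sites of each flank, with recombination probabilities as
   transitions and the evidence pairs as emissions, anchored at the
   mutation; Bayes' theorem with a 0.5/0.5 prior yields P(disease).
4. **Decision layer** — five categories at fixed bounds
   (1e-4, 0.1, 0.6, 0.9) and an error probability (p for normal-side
   calls, 1−p for disease-side calls, min(p, 1−p) for the indeterminate
   "risk" band, which is additionally flagged).

### Assumptions

- Recombination events in non-overlapping intervals are independent
  (Poisson crossovers, no interference); the linear rate×distance formula
  is used only in its small-distance regime and clamped to [0, 0.5].
- Linkage sites are biallelic SNVs; alleles are symbolic labels, so indels
  are handled as atomic alleles but multi-allelic records are skipped.
- Read errors are uniform substitutions (base_error/3 to each other base)
  with a single global base-error rate; no per-read base qualities.
- The amplification channel acts per site and per cell independently:
  het → either hom at ado_rate/2 each; hom (or hemizygous allele) → het at
  false_allele_rate.
- Each flank's sites are conditionally independent given the origin chain;
  the two flanks are independent given the origin at the mutation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_mb` | 1.5 | analysis window on each side of the mutation (Mb) |
| `min_reads` | 2 | minimum embryo depth for a linkage site |
| `ado_rate` | 0.2 | allele-dropout probability of a single-cell het |
| `false_allele_rate` | 0.01 | spurious-allele probability of a single-cell hom |
| `base_error` | 0.01 | per-read miscall probability |
| `prior_disease` | 0.5 | Mendelian transmission prior |
| `thresholds` | (1e-4, 0.1, 0.6, 0.9) | category bounds on P(disease) |
| `carrier_het_floor` | 0.5 | het posterior mass for a site to count as informative |
| `phase_mode_mass` | 0.5 | posterior mass needed for a phasing point call |
| `min_phase_sources` | 4 | minimum embryos/sperm for proband-free phasing |
| `anchor_fraction` | 0.75 | fraction of sources that must resolve an anchor site |
| map `default_rate` | 0.01/Mb | genome-average rate (≈1 cM/Mb) where the map is silent |

Analysis modes differ only in how sites are selected and how the phase is
obtained (`p_plus_10sites` whitelist; `bayes_p_plus` proband;
`bayes_p_plus_pb` proband + polar-body filtering; `bayes_p_minus` embryos;
`bayes_p_minus_sperm` sperm); the chain arithmetic is identical in all.

## Design choices

- **Log-space chain.** All chain recursion and the final Bayes step run in
  log space with pairwise log-sum-exp, keeping posteriors at the 1e-8
  scale accurate to relative precision. An exhaustive 2^N path-enumeration
  oracle defines ground truth for the chain semantics, and the recursion
  is tested against it to 1e-12 relative error.
- **Neutral class absorbs inconsistency.** Mendelian-impossible genotype
  combinations are pooled into the neutral class (half weight to each
  side) rather than zeroed out: an impossible combination signals a
  genotyping error, and the half-half split is exactly the "cannot decide"
  treatment. The evidence pair is normalised to sum to 1 so the chain can
  treat it as a two-state emission.
- **Phasing point calls at majority mass.** Phasing uses posterior-mode
  genotypes accepted at ≥ 0.5 mass (a majority-mass call, the behaviour of
  a standard caller's point calls). A stricter 0.9 floor was tried first
  and starves the anchor-site selection at 2–5× single-cell depth with 20%
  ADO: almost no site resolves in 75% of sources, and proband-free phasing
  becomes impossible. Confidently wrong calls produced by the looser floor
  are exactly what the discordance filter (discard sites with more than
  one discordant sample) is there to remove; measured on simulated
  families, retained-site phase accuracy exceeds 99%.
- **Haplotype-class labelling by majority.** The class whose members carry
  the causal mutation is the disease haplotype. A single recombinant
  source (crossover between the linkage region and the mutation) or a
  mutation-site genotyping error would make a strict "carriers in exactly
  one class" rule abort ~3% of families per source; labelling follows the
  per-class majority of mutation-site genotypes instead, with hard errors
  only when the majorities tie or both classes are majority-carriers.
- **One-class families.** With 4 embryos there is a ~12.5% chance all of
  them inherited the same carrier haplotype, so no second class can form.
  The second haplotype is then reconstructed as the carrier's
  complementary allele at each heterozygous site.
- **Genotype sources.** Bulk samples (parents, proband) use imported
  Phred-scaled likelihoods (PL) where present, otherwise allele-depth read
  counts with a noiseless channel; single cells always go through the
  amplification model over their read counts — applying a bulk PL to a
  single cell would discard exactly the error structure the model exists
  to capture.
- **Boundary ties** at a classification threshold resolve toward the more
  cautious (more "risk") category, making the five categories a partition
  of [0, 1].
- **Rate lookup at the midpoint** of a site pair; one rate per region,
  no distance-weighted averaging across intervals.
- **X-linked families** run the scalar evidence route (hemizygous father
  and male embryos mix ploidies); autosomal families use a vectorised
  route that is tested to be numerically identical to the scalar one.

## Synthetic data: what it does and does not emulate

`simulate_family` draws a carrier parent heterozygous at every candidate
linkage site (these are, by construction, the informative sites an
analyst would keep), an other parent with ~0.5 heterozygosity, and
meioses with Poisson crossovers at the map rate. Single cells (embryos,
sperm, polar bodies) pass through the ADO/spurious-allele channel and a
shallow-read sampler (2–5 reads/site, 1% miscalls); parents and proband
are bulk DNA at 30× with PL fields; the mutation site is covered at 50×
in every sample, emulating targeted PCR. The second polar body is
modelled as an identical copy of the egg chromatid — exact unless a
crossover fell inside the 3 Mb window (~3% of meioses), whose
sister-chromatid divergence is not modelled.

Not emulated: genome-wide amplification bias profiles, mapping artefacts
and repeat-region error clustering (injected separately via
`corrupt_sites`), realistic allele-frequency spectra, aneuploidy, and
per-base quality variation. A green end-to-end test therefore establishes
that the inference machinery is correct under the stated noise model, not
that the noise model captures every failure mode of real single-cell
data; the discordance-filter tests probe the mapping-error failure mode
explicitly through injected corruptions.

## Numerical notes

- Evidence pairs and genotype posteriors are renormalised after each
  construction step; degenerate inputs (no reads) return the prior.
- Zero read counts contribute exactly zero against log(0) likelihood
  terms, so a zero base-error model is handled exactly.
- Simulated PL values are capped at 990 (caller-style capping; also keeps
  downstream VCF parsers from flagging extreme values).
- `simulate_family` is fully deterministic per seed, to the byte, and
  re-running an analysis on identical inputs reproduces identical reports.

## Known limitations

- The error probability is calibrated under the model's own assumptions;
  systematic errors shared across embryos (e.g. a mis-specified phase at
  many sites) are not reflected in it.
- Polar bodies only remove conflicting sites from an embryo's evidence;
  no joint egg/polar-body likelihood is attempted.
- Compound-heterozygous cases run one carrier parent per invocation; the
  two analyses are not combined.
- Sex-specific recombination maps are not implemented; the map is assumed
  sex-averaged.
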