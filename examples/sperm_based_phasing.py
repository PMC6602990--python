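"""Phase a paternal carrier from single sperm cells.

Proband-free phasing needs at least four embryos; when fewer are
available and the father carries the mutation, single sperm cells stand in
as haploid phasing sources: each sperm IS one paternal meiotic product, so
its allele directly reads out the transmitted haplotype.
"""

import tempfile

from pgtlink import AnalysisConfig, MutationSpec, load_family, load_map, run_analysis
from pgtlink.synthetic_data import SimulationParams, simulate_family

workdir = tempfile.mkdtemp()
ds = simulate_family(
    SimulationParams(seed=5, n_embryos=2, n_sperm=7, carrier="father",
                     with_proband=False, n_sites=100),
    workdir,
)
t = ds.truth

mutation = MutationSpec("chr11", t.mutation_pos,
                        t.ref_alleles[t.mutation_pos], t.alt_alleles[t.mutation_pos],
                        carrier="father")
data = load_family(ds.sample_sheet, ds.vcf, mutation)
rmap = load_map(ds.recomb_map)

calls = run_analysis(data, AnalysisConfig(mode="bayes_p_minus_sperm"), rmap)

for c in calls:
    truth = "disease" if t.disease_status[c.embryo_id] else "normal"
    print(f"{c.embryo_id}: P(disease)={c.p_disease:.3e}  {c.category:>12}  "
          f"(error {c.error_probability:.2e}, truth {truth})")

# with only two embryos, embryo-based grouping would be impossible; the
# seven sperm cells phase the father's haplotypes instead and the embryos
# are then classified against that phase.
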