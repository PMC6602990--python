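import pytest

from pgtlink.family_io import MutationSpec, load_family
from pgtlink.recomb_map import load_map
from pgtlink.synthetic_data import SimulationParams, simulate_family

MUT_POS = 5_000_000


def mutation_for(ds, **kw):
    """MutationSpec matching a simulated dataset's causal site."""
    t = ds.truth
    return MutationSpec(
        ds.params.chrom, t.mutation_pos,
        t.ref_alleles[t.mutation_pos], t.alt_alleles[t.mutation_pos], **kw
    )


@pytest.fixture(scope="session")
def default_family(tmp_path_factory):
    """One simulated family at default noise, loaded and ready to analyse."""
    d = tmp_path_factory.mktemp("fam")
    ds = simulate_family(SimulationParams(seed=1, n_embryos=6, n_sites=60), d)
    mut = mutation_for(ds)
    data = load_family(ds.sample_sheet, ds.vcf, mut)
    rmap = load_map(ds.recomb_map)
    return ds, data, rmap


@pytest.fixture(scope="session")
def noiseless_family(tmp_path_factory):
    """A family with every noise channel off: genotypes are exact."""
    d = tmp_path_factory.mktemp("fam0")
    params = SimulationParams(
        seed=7, n_embryos=5, n_sites=40,
        ado_rate=0.0, false_allele_rate=0.0, base_error=0.0,
        depth_min=8, depth_max=10,
    )
    ds = simulate_family(params, d)
    mut = mutation_for(ds)
    data = load_family(ds.sample_sheet, ds.vcf, mut)
    rmap = load_map(ds.recomb_map)
    return ds, data, rmap
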