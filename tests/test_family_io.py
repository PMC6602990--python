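import json

import pytest

from pgtlink.family_io import (
    FamilyValidationError,
    MutationSpec,
    load_family,
    run_analysis,
    write_reports,
)
from pgtlink.linkage_bayes import AnalysisConfig
from pgtlink.recomb_map import load_map
from pgtlink.synthetic_data import SimulationParams, simulate_family
from conftest import mutation_for


class TestLoadFamily:
    def test_valid_design(self, default_family):
        ds, data, _ = default_family
        assert data.design.mother_id == "MOTHER"
        assert len(data.design.embryo_ids) == 6
        assert data.design.proband == ("PROBAND", True) or \
            data.design.proband == ("PROBAND", False)
        assert data.mutation_site.pos == ds.truth.mutation_pos

    def test_missing_sample_in_vcf(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=21, n_sites=10), tmp_path)
        sheet = tmp_path / "bad.tsv"
        sheet.write_text(ds.sample_sheet.read_text()
                         + "GHOST\tembryo\t.\t.\t.\n")
        with pytest.raises(FamilyValidationError, match="GHOST"):
            load_family(sheet, ds.vcf, mutation_for(ds))

    def test_sperm_with_maternal_carrier_rejected(self, tmp_path):
        ds = simulate_family(
            SimulationParams(seed=22, n_sites=10, carrier="father", n_sperm=4,
                             with_proband=False, n_embryos=2),
            tmp_path)
        with pytest.raises(FamilyValidationError, match="paternal"):
            load_family(ds.sample_sheet, ds.vcf, mutation_for(ds, carrier="mother"))

    def test_zero_embryos_rejected(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=23, n_sites=10), tmp_path)
        lines = [l for l in ds.sample_sheet.read_text().splitlines()
                 if "\tembryo\t" not in l]
        sheet = tmp_path / "noembryo.tsv"
        sheet.write_text("\n".join(lines) + "\n")
        with pytest.raises(FamilyValidationError, match="embryo"):
            load_family(sheet, ds.vcf, mutation_for(ds))

    def test_mutation_allele_mismatch(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=24, n_sites=10), tmp_path)
        t = ds.truth
        wrong = MutationSpec(ds.params.chrom, t.mutation_pos,
                             t.alt_alleles[t.mutation_pos],
                             t.ref_alleles[t.mutation_pos])
        with pytest.raises(FamilyValidationError, match="alleles"):
            load_family(ds.sample_sheet, ds.vcf, wrong)

    def test_yaml_sample_sheet(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=29, n_sites=10), tmp_path)
        rows = [l.split("\t") for l in
                ds.sample_sheet.read_text().splitlines()[1:]]
        sheet = tmp_path / "samples.yaml"
        entries = []
        for sid, role, sex, linked, affected in rows:
            e = {"sample_id": sid, "role": role}
            if sex != ".":
                e["sex"] = sex
            if linked != ".":
                e["linked_embryo"] = linked
            if affected != ".":
                e["affected"] = affected == "1"
            entries.append(e)
        import yaml
        sheet.write_text(yaml.safe_dump(entries))
        data = load_family(sheet, ds.vcf, mutation_for(ds))
        assert len(data.design.embryo_ids) == 6

    def test_carrier_both_must_be_split(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=30, n_sites=10), tmp_path)
        with pytest.raises(FamilyValidationError, match="separately"):
            load_family(ds.sample_sheet, ds.vcf, mutation_for(ds, carrier="both"))

    def test_missing_mutation_record(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=25, n_sites=10), tmp_path)
        spec = MutationSpec(ds.params.chrom, ds.truth.mutation_pos + 17, "A", "G")
        with pytest.raises(FamilyValidationError, match="mutation position"):
            load_family(ds.sample_sheet, ds.vcf, spec)


class TestRunAnalysis:
    def test_noiseless_pipeline_is_definitive(self, noiseless_family):
        """With every noise channel off, posteriors collapse to 0/1 and all
        categories match the simulation truth."""
        ds, data, rmap = noiseless_family
        for mode in ("bayes_p_plus", "bayes_p_minus"):
            cfg = AnalysisConfig(mode=mode, ado_rate=0.0,
                                 false_allele_rate=0.0, base_error=0.0)
            try:
                calls = run_analysis(data, cfg, rmap)
            except Exception as e:  # p_minus can fail only if < 4 usable
                raise AssertionError(f"{mode} failed: {e}")
            for c in calls:
                truth = ds.truth.disease_status[c.embryo_id]
                assert c.p_disease == pytest.approx(1.0 if truth else 0.0, abs=1e-9)
                assert (c.category == "disease") == truth

    def test_default_noise_categories_match_truth(self, default_family):
        ds, data, rmap = default_family
        calls = run_analysis(data, AnalysisConfig(mode="bayes_p_plus"), rmap)
        assert len(calls) == len(data.design.embryo_ids)
        for c in calls:
            truth = ds.truth.disease_status[c.embryo_id]
            assert (c.p_disease > 0.5) == truth

    def test_whitelist_mode_uses_exactly_those_sites(self, default_family):
        ds, data, rmap = default_family
        phased = run_analysis(data, AnalysisConfig(mode="bayes_p_plus"), rmap)
        all_used = sorted({r["pos"] for c in phased for r in c.site_audit
                           if r["side"] != "mutation"})
        wl = tuple(all_used[:10])
        cfg = AnalysisConfig(mode="p_plus_10sites", site_whitelist=wl)
        calls = run_analysis(data, cfg, rmap)
        for c in calls:
            assert c.n_sites_used == len(wl) + 1  # whitelist + mutation site
            used = {r["pos"] for r in c.site_audit if r["side"] != "mutation"}
            assert used == set(wl)

    def test_proband_free_minimum_embryos(self, tmp_path):
        ds = simulate_family(SimulationParams(seed=26, n_embryos=3, n_sites=20),
                             tmp_path)
        data = load_family(ds.sample_sheet, ds.vcf, mutation_for(ds))
        rmap = load_map(ds.recomb_map)
        with pytest.raises(FamilyValidationError, match="4"):
            run_analysis(data, AnalysisConfig(mode="bayes_p_minus"), rmap)

    def test_proband_required_for_p_plus(self, tmp_path):
        ds = simulate_family(
            SimulationParams(seed=27, n_embryos=4, n_sites=20, with_proband=False),
            tmp_path)
        data = load_family(ds.sample_sheet, ds.vcf, mutation_for(ds))
        rmap = load_map(ds.recomb_map)
        with pytest.raises(FamilyValidationError, match="proband"):
            run_analysis(data, AnalysisConfig(mode="bayes_p_plus"), rmap)

    def test_deterministic_rerun(self, default_family):
        _, data, rmap = default_family
        cfg = AnalysisConfig(mode="bayes_p_plus")
        a = run_analysis(data, cfg, rmap)
        b = run_analysis(data, cfg, rmap)
        assert [(c.embryo_id, c.p_disease, c.category) for c in a] == \
            [(c.embryo_id, c.p_disease, c.category) for c in b]

    def test_x_linked_family(self, tmp_path):
        ds = simulate_family(
            SimulationParams(seed=28, n_embryos=5, n_sites=30,
                             inheritance="x_linked", chrom="chrX"),
            tmp_path)
        data = load_family(ds.sample_sheet, ds.vcf,
                           mutation_for(ds, inheritance="x_linked"))
        rmap = load_map(ds.recomb_map)
        calls = run_analysis(data, AnalysisConfig(mode="bayes_p_plus"), rmap)
        for c in calls:
            assert (c.p_disease > 0.5) == ds.truth.disease_status[c.embryo_id]


class TestWriteReports:
    def test_report_files_and_roundtrip(self, default_family, tmp_path):
        _, data, rmap = default_family
        calls = run_analysis(data, AnalysisConfig(mode="bayes_p_plus"), rmap)
        cfg = AnalysisConfig(mode="bayes_p_plus")
        paths = write_reports(calls, tmp_path / "out", cfg)
        tsv_rows = (tmp_path / "out" / "calls.tsv").read_text().splitlines()
        assert len(tsv_rows) == len(calls) + 1  # header + one row per embryo
        loaded = json.loads((tmp_path / "out" / "calls.json").read_text())
        assert [(d["embryo_id"], d["category"]) for d in loaded] == \
            [(c.embryo_id, c.category) for c in calls]
        audit_rows = (tmp_path / "out" / "audit.tsv").read_text().splitlines()[1:]
        assert len(audit_rows) == sum(c.n_sites_used for c in calls)

    def test_byte_identical_on_rerun(self, default_family, tmp_path):
        _, data, rmap = default_family
        cfg = AnalysisConfig(mode="bayes_p_plus")
        calls = run_analysis(data, cfg, rmap)
        write_reports(calls, tmp_path / "r1", cfg)
        write_reports(run_analysis(data, cfg, rmap), tmp_path / "r2", cfg)
        assert (tmp_path / "r1" / "calls.tsv").read_bytes() == \
            (tmp_path / "r2" / "calls.tsv").read_bytes()

    def test_empty_calls_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_reports([], tmp_path)
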