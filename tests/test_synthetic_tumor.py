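import filecmp

import numpy as np
import pytest

from immunoprofiler import io_formats
from immunoprofiler import synthetic_tumor as st
from immunoprofiler.pipeline import RunConfig, run_characterization
from immunoprofiler.somatic_filters import consensus_calls


class TestGenome:
    def test_all_diploid_config(self):
        cfg = st.SimulationConfig(seed=1, n_genes=200, cn_states={2: 1.0})
        _genes, cn = st.simulate_genome(cfg)
        assert set(cn.values()) == {2}

    def test_state_frequencies_match_configured_proportions(self):
        cfg = st.SimulationConfig(seed=2, n_genes=5000)
        _genes, cn = st.simulate_genome(cfg)
        vals = np.array(list(cn.values()))
        for state, prop in cfg.cn_states.items():
            freq = (vals == state).mean()
            assert abs(freq - prop) <= 0.02

    def test_deterministic_for_fixed_seed(self):
        cfg = st.SimulationConfig(seed=5, n_genes=300)
        a = st.simulate_genome(cfg)
        b = st.simulate_genome(cfg)
        assert a == b

    def test_segmental_structure(self):
        cfg = st.SimulationConfig(seed=3, n_genes=2000)
        genes, cn = st.simulate_genome(cfg)
        runs = 1
        ordered = [cn[g.gene_id] for g in genes]
        for prev, cur in zip(ordered, ordered[1:]):
            runs += prev != cur
        # far fewer state changes than genes: contiguous segments share c
        assert runs < len(genes) / 10


class TestExomeCounts:
    def test_diploid_genome_has_unit_ratio(self):
        cfg = st.SimulationConfig(seed=4, n_genes=500, cn_states={2: 1.0})
        genes, cn = st.simulate_genome(cfg)
        counts = st.simulate_exome_counts(genes, cn, cfg)
        t = sum(sum(counts[f"T{r}"].values()) for r in (1, 2, 3))
        n = sum(sum(counts[f"N{r}"].values()) for r in (1, 2, 3))
        assert t / n == pytest.approx(1.0, rel=0.02)

    def test_ratio_estimator_unbiased_over_seeds(self):
        errs = []
        for seed in range(30):
            cfg = st.SimulationConfig(seed=seed, n_genes=100)
            genes, cn = st.simulate_genome(cfg)
            counts = st.simulate_exome_counts(genes, cn, cfg)
            mean_ploidy = np.mean(list(cn.values()))
            for g in genes[:10]:
                t = sum(counts[f"T{r}"][g.gene_id] for r in (1, 2, 3))
                n = sum(counts[f"N{r}"][g.gene_id] for r in (1, 2, 3))
                if n:
                    errs.append(t / n - cn[g.gene_id] / mean_ploidy)
        assert abs(np.mean(errs)) < 0.01

    def test_zero_depth_gives_all_zero_tables(self):
        cfg = st.SimulationConfig(seed=5, n_genes=50, mean_depth=0.0)
        genes, cn = st.simulate_genome(cfg)
        counts = st.simulate_exome_counts(genes, cn, cfg)
        assert all(v == 0 for col in counts.values() for v in col.values())


class TestVariants:
    def test_zero_artifacts_consensus_equals_truth(self):
        cfg = st.SimulationConfig(seed=6, n_genes=200, snv_count=40, error_site_count=0)
        genes, cn = st.simulate_genome(cfg)
        variants, call_sets, truth = st.simulate_variants(genes, cn, cfg)
        somatic = {k for k, info in truth.variants.items() if info["somatic"]}
        assert consensus_calls(call_sets) == somatic == {v.key for v in variants}

    def test_vafs_concentrate_near_discrete_states(self, small_sim):
        truth = small_sim["truth"]
        devs = []
        for v in small_sim["variants"]:
            info = truth.variants[v.key]
            if not info["somatic"]:
                continue
            r, a = v.pooled_depth("T")
            devs.append(abs(a / (r + a) - info["m"] / info["c"]))
        assert np.mean(devs) < 0.05

    def test_artifact_sites_have_near_zero_vaf(self, small_sim):
        truth = small_sim["truth"]
        for v in small_sim["variants"]:
            if truth.variants[v.key]["somatic"]:
                continue
            r, a = v.pooled_depth("T")
            assert a / (r + a) < 0.05


class TestExpressionProteome:
    def test_full_zero_inflation_empties_expressed_tier(self):
        cfg = st.SimulationConfig(
            seed=7, n_genes=100, snv_count=20, error_site_count=0, zero_inflation=1.0
        )
        genes, cn = st.simulate_genome(cfg)
        variants, _cs, truth = st.simulate_variants(genes, cn, cfg)
        st.simulate_expression_and_proteome(variants, truth, cfg)
        assert truth.tiers["expressed"] == frozenset()

    def test_ten_rpkm_near_80th_percentile(self):
        from immunoprofiler.expression import expression_percentile

        cfg = st.SimulationConfig(seed=8, n_genes=4000, snv_count=10, error_site_count=0)
        genes, cn = st.simulate_genome(cfg)
        variants, _cs, truth = st.simulate_variants(genes, cn, cfg)
        st.simulate_expression_and_proteome(variants, truth, cfg)
        pct = expression_percentile(list(truth.rpkm.values()), 10.0)
        assert pct == pytest.approx(80.0, abs=3.0)

    def test_aa_changes_consistent_with_proteins(self, small_sim):
        expr = small_sim["expression"]
        for key, gid, pid, pos, wt, mut in expr["mutations"]:
            prot = expr["proteins"][gid]
            assert prot.protein_id == pid
            assert prot.sequence[pos - 1] == wt != mut


class TestEmittedFiles:
    def test_every_file_parses_through_io_formats(self, small_sim_dir):
        outdir, paths = small_sim_dir
        genes = io_formats.read_gene_table(paths["genes"])
        assert len(genes) == 400
        counts = io_formats.read_count_table(paths["counts"])
        assert set(counts) == {f"{s}{r}" for s in "TN" for r in (1, 2, 3)}
        variants = io_formats.read_variants(paths["variants"], dialect="tsv")
        assert len(variants) == 80
        for caller in st.CALLERS:
            io_formats.read_variants(paths[f"calls_{caller}_1"], dialect="tsv")
        io_formats.read_fasta(paths["proteins"])
        io_formats.read_fasta(paths["mhc_reference"])
        io_formats.read_fasta(paths["mhc_reads"])

    def test_rerun_is_byte_identical(self, small_sim, tmp_path):
        cfg = small_sim["config"]
        a = st.write_simulation(st.simulate_all(cfg), tmp_path / "a")
        b = st.write_simulation(st.simulate_all(cfg), tmp_path / "b")
        for name in a:
            assert filecmp.cmp(a[name], b[name], shallow=False), name


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_truth(self, small_sim, small_sim_dir, tmp_path):
        outdir, paths = small_sim_dir
        report = run_characterization(
            RunConfig(
                outdir=tmp_path / "rep",
                genes=paths["genes"],
                counts=paths["counts"],
                variants=paths["variants"],
                calls_dir=outdir,
                expression=paths["expression"],
                proteins=paths["proteins"],
                protein_mutations=paths["mutations"],
                mhc_reference=paths["mhc_reference"],
                mhc_reads=paths["mhc_reads"],
            )
        )
        truth = small_sim["truth"]
        # copy number recovery >= 95%
        calls = {}
        for line in open(report["outputs"]["copy_number"]):
            if line.startswith("#"):
                continue
            gid, c, *_ = line.split("\t")
            calls[gid] = int(c) if c else None
        acc = np.mean([calls[g] == c for g, c in truth.gene_cn.items()])
        assert acc >= 0.95
        # genotype and tiers recovered exactly
        assert report["mhc_profile"].genotype == truth.mhc_genotype
        assert {k: t.members for k, t in report["tiers"].items()} == truth.tiers

    def test_variants_only_config_skips_downstream(self, small_sim_dir, tmp_path):
        outdir, paths = small_sim_dir
        report = run_characterization(
            RunConfig(
                outdir=tmp_path / "rep2",
                variants=paths["variants"],
                calls_dir=outdir,
            )
        )
        for stage in ("copy_number", "expression", "mhc_quant", "neoepitope"):
            assert stage in report["skipped"]
        assert any("skipped" in line for line in report["summary_lines"])
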