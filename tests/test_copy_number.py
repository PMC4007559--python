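import numpy as np
import pytest
from scipy import stats

from immunoprofiler import copy_number as cnmod
from immunoprofiler import synthetic_tumor as st
from immunoprofiler.copy_number import (
    DepthRatio,
    PloidyModel,
    cn_summary,
    fit_ploidy_model,
    infer_copy_number,
    infer_zygosity,
    normalized_ratio,
)
from immunoprofiler.io_formats import VariantRecord


def _variant(gene="g1"):
    return VariantRecord(chrom="chr1", pos=100, ref="A", alt="G", gene_id=gene)


class TestNormalizedRatio:
    def test_identical_count_maps_give_unity(self):
        counts = {f"g{i}": 100 + i for i in range(50)}
        for dr in normalized_ratio(counts, dict(counts)):
            assert dr.r == pytest.approx(1.0)

    def test_doubled_gene_has_ratio_two(self):
        rng = np.random.default_rng(0)
        normal = {f"g{i}": int(rng.integers(500, 1500)) for i in range(1000)}
        tumor = dict(normal)
        tumor["g0"] = 2 * normal["g0"]
        # direct arithmetic oracle
        T, N = sum(tumor.values()), sum(normal.values())
        expected = (tumor["g0"] / T) / (normal["g0"] / N)
        got = {dr.gene_id: dr.r for dr in normalized_ratio(tumor, normal)}
        assert got["g0"] == pytest.approx(expected)
        assert got["g0"] == pytest.approx(2.0, rel=0.01)

    def test_zero_normal_count_flagged_not_infinite(self):
        drs = {
            dr.gene_id: dr
            for dr in normalized_ratio({"a": 10, "b": 10}, {"a": 0, "b": 10})
        }
        assert drs["a"].flagged and not drs["b"].flagged

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalized_ratio({}, {})


class TestInferCopyNumber:
    @pytest.mark.parametrize(
        "r,s,expected",
        [
            (1.0, 1.0, 2),
            (1.5, 1.0, 3),
            (1.75, 1.0, 3),  # exact tie between c=3 and c=4 -> lower c
            (0.5, 1.0, 1),
            (0.05, 1.0, 0),  # below the deletion threshold 0.25*s
            (0.3, 1.0, 1),   # nearest is c=1 anyway
        ],
    )
    def test_rounding_and_ties(self, r, s, expected):
        call = infer_copy_number(DepthRatio("g", r), PloidyModel(s=s))
        assert call.c == expected

    def test_deletion_guard_blocks_noisy_zero(self):
        # nearest integer state is 0 but ratio is above the deletion cutoff
        call = infer_copy_number(DepthRatio("g", 0.26), PloidyModel(s=1.04))
        assert call.c == 1

    def test_flagged_ratio_gives_unavailable_call(self):
        call = infer_copy_number(DepthRatio("g", 0.0, flagged=True), PloidyModel(s=1.0))
        assert call.c is None

    def test_amplification_beyond_model_flagged(self):
        call = infer_copy_number(DepthRatio("g", 9.0), PloidyModel(s=1.0, c_max=8))
        assert call.c == 8 and call.amplified_beyond_model


class TestFitPloidyModel:
    def test_all_unity_ratios_resolve_to_diploid(self):
        ratios = [DepthRatio(f"g{i}", 1.0) for i in range(100)]
        model = fit_ploidy_model(ratios)
        assert model.s == pytest.approx(1.0)

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_ploidy_model([DepthRatio(f"g{i}", 0.0) for i in range(60)])

    def test_exhaustive_grid_oracle_matches_objective(self):
        # brute force over (s, c per gene, m per variant) on a tiny fixture
        rng = np.random.default_rng(42)
        c_true = [3] * 10 + [4] * 10
        s_true = 2.0 / np.mean(c_true)
        ratios = [
            DepthRatio(f"g{i}", c * s_true / 2 + rng.normal(0, 0.02))
            for i, c in enumerate(c_true)
        ]
        variants = []
        for i, c in enumerate(c_true[:8]):
            m = int(rng.integers(1, c + 1))
            d = 150
            a = int(rng.binomial(d, m / c))
            variants.append((a, d, f"g{i}"))

        c_max = 4
        s_grid = np.arange(0.2, 3.0 + 1e-9, 0.01)
        model = fit_ploidy_model(ratios, variants, c_max=c_max, s_grid=s_grid)

        def oracle_objective(s):
            total = 0.0
            c_of = {}
            for dr in ratios:
                best = min(range(c_max + 1), key=lambda c: (dr.r - c * s / 2) ** 2)
                c_of[dr.gene_id] = best
                total += (dr.r - best * s / 2) ** 2
            for a, d, g in variants:
                c = max(c_of[g], 1)
                total += min(
                    -stats.binom.logpmf(a, d, min(max(m / c, 1e-3), 1 - 1e-3))
                    for m in range(1, c + 1)
                )
            return total

        best_oracle = min(oracle_objective(s) for s in s_grid)
        assert model.objective == pytest.approx(best_oracle, abs=1e-9)

    def test_scale_recovery_battery(self):
        # triploid/tetraploid-heavy genome at 170x: the fitted scale lands
        # within one grid step of truth and >=95% of genes get their true c
        hits = []
        for seed in range(10):
            cfg = st.SimulationConfig(
                seed=100 + seed, n_genes=500, snv_count=60, error_site_count=0
            )
            genes, cn = st.simulate_genome(cfg)
            counts = st.simulate_exome_counts(genes, cn, cfg)
            tumor = {
                g.gene_id: sum(counts[f"T{r}"][g.gene_id] for r in (1, 2, 3))
                for g in genes
            }
            normal = {
                g.gene_id: sum(counts[f"N{r}"][g.gene_id] for r in (1, 2, 3))
                for g in genes
            }
            ratios = normalized_ratio(tumor, normal)
            variants, _, truth = st.simulate_variants(genes, cn, cfg)
            vafs = [
                (v.pooled_depth("T")[1], sum(v.pooled_depth("T")), v.gene_id)
                for v in variants
            ]
            model = fit_ploidy_model(ratios, vafs)
            s_true = 2.0 / truth.mean_ploidy
            assert abs(model.s - s_true) <= 0.011
            calls = [infer_copy_number(dr, model) for dr in ratios]
            acc = np.mean([c.c == cn[c.gene_id] for c in calls])
            hits.append(acc >= 0.95)
        assert all(hits)

    def test_scale_equivariance_of_calls(self):
        rng = np.random.default_rng(1)
        normal = {f"g{i}": int(rng.integers(800, 1200)) for i in range(300)}
        tumor = {g: int(v * rng.choice([1, 1.5, 2])) for g, v in normal.items()}
        model = PloidyModel(s=1.0)
        base = [
            infer_copy_number(dr, model) for dr in normalized_ratio(tumor, normal)
        ]
        scaled_tumor = {g: 7 * v for g, v in tumor.items()}
        scaled = [
            infer_copy_number(dr, model)
            for dr in normalized_ratio(scaled_tumor, normal)
        ]
        assert [c.c for c in base] == [c.c for c in scaled]


class TestInferZygosity:
    def test_balanced_het_in_diploid(self):
        z = infer_zygosity(_variant(), 2, 50, 100)
        assert (z.m, z.zygosity) == (1, "heterozygous")

    def test_near_full_vaf_in_tetraploid_is_homozygous(self):
        # binomial likelihood across m in 1..4 peaks at m=4
        z = infer_zygosity(_variant(), 4, 98, 100)
        assert (z.m, z.zygosity) == (4, "homozygous")

    @pytest.mark.parametrize("c", [1, 2, 3, 4, 5, 6])
    def test_full_vaf_always_homozygous(self, c):
        z = infer_zygosity(_variant(), c, 200, 200)
        assert z.zygosity == "homozygous" and z.m == c

    def test_deleted_region_rejected(self):
        with pytest.raises(ValueError, match="deleted"):
            infer_zygosity(_variant(), 0, 10, 20)

    def test_multiplicity_recovery_simulated(self):
        rng = np.random.default_rng(7)
        ok = n = 0
        for _ in range(500):
            c = int(rng.integers(1, 5))
            m = int(rng.integers(1, c + 1))
            d = int(rng.integers(100, 300))
            a = int(rng.binomial(d, m / c))
            z = infer_zygosity(_variant(), c, a, d)
            ok += z.m == m
            n += 1
        assert ok / n >= 0.90

    def test_purity_scales_expected_vaf(self):
        model = PloidyModel(s=1.0, purity=0.5)
        # m=c=2 at purity 0.5: expected VAF = 2*0.5 / (0.5*2 + 2*0.5) = 0.5
        assert model.expected_vaf(2, 2) == pytest.approx(0.5)
        z = infer_zygosity(_variant(), 2, 100, 200, model=model)
        assert z.zygosity == "homozygous"


class TestCnSummary:
    def test_uniform_diploid(self):
        calls = [cnmod.CopyNumberCall(f"g{i}", 2) for i in range(10)]
        summ = cn_summary(calls)
        assert summ["median"] == 2 and summ["mean"] == 2.0
        assert summ["histogram"] == {2: 10}

    def test_histogram_matches_generator_truth(self, small_sim):
        truth = small_sim["truth"].gene_cn
        calls = [cnmod.CopyNumberCall(g, c) for g, c in truth.items()]
        summ = cn_summary(calls)
        expected = {}
        for c in truth.values():
            expected[c] = expected.get(c, 0) + 1
        assert summ["histogram"] == dict(sorted(expected.items()))
        assert sum(summ["histogram"].values()) == summ["n"]
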