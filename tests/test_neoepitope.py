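import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from immunoprofiler.io_formats import ProteinRecord
from immunoprofiler.neoepitope import (
    AMINO_ACIDS,
    NeoepitopeCandidate,
    TablePredictor,
    ToyPwmPredictor,
    best_epitope,
    enumerate_mutant_peptides,
    peptide_window_count,
    prioritize_cascade,
)


def _protein(seq, pid="p1", gid="g1"):
    return ProteinRecord(protein_id=pid, sequence=seq, gene_id=gid)


def _rand_protein(rng, n):
    return _protein("".join(rng.choice(list(AMINO_ACIDS), size=n)))


class TestEnumeration:
    def test_interior_mutation_yields_38_windows(self):
        rng = np.random.default_rng(0)
        prot = _rand_protein(rng, 40)
        mut_aa = "K" if prot.sequence[19] != "K" else "R"
        cands = enumerate_mutant_peptides(prot, 20, mut_aa)
        assert len(cands) == 8 + 9 + 10 + 11 == 38

    def test_length_eight_protein_single_window(self):
        prot = _protein("ACDEFGHI")
        for pos in (1, 4, 8):
            cands = enumerate_mutant_peptides(prot, pos, "W")
            assert len(cands) == 1 and len(cands[0][0]) == 8

    def test_windows_contain_mutant_residue_and_pair_correctly(self):
        rng = np.random.default_rng(1)
        prot = _rand_protein(rng, 60)
        pos = 31
        mut = "M" if prot.sequence[pos - 1] != "M" else "V"
        for pep, wt, off in enumerate_mutant_peptides(prot, pos, mut):
            assert pep[off] == mut
            assert wt[off] == prot.sequence[pos - 1]
            diffs = [i for i, (a, b) in enumerate(zip(pep, wt)) if a != b]
            assert diffs == [off]

    def test_count_matches_closed_form_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            n = int(rng.integers(8, 80))
            pos = int(rng.integers(1, n + 1))
            prot = _rand_protein(rng, n)
            mut = "W" if prot.sequence[pos - 1] != "W" else "Y"
            cands = enumerate_mutant_peptides(prot, pos, mut)
            assert len(cands) == peptide_window_count(n, pos)

    def test_known_epitope_appears_among_candidates(self):
        # N->K at protein position 42 with local context VGPNFRVGKK
        # produces the 10-mer VGPKFRVGKK with the mutant K at offset 3
        seq = "A" * 38 + "VGPNFRVGKK" + "A" * 20
        prot = _protein(seq)
        cands = enumerate_mutant_peptides(prot, 42, "K")
        peptides = {pep for pep, _wt, _off in cands}
        assert "VGPKFRVGKK" in peptides
        (off,) = {off for pep, _wt, off in cands if pep == "VGPKFRVGKK"}
        assert off == 3

    def test_stop_gain_not_enumerable(self):
        prot = _protein("ACDEFGHIKLMNP")
        with pytest.raises(ValueError, match="enumerable"):
            enumerate_mutant_peptides(prot, 5, "*")

    def test_short_protein_has_no_windows(self):
        assert enumerate_mutant_peptides(_protein("ACDEFGH"), 3, "W") == []
        assert peptide_window_count(7, 3) == 0


class TestToyPredictor:
    def test_deterministic_across_instances(self):
        s1 = ToyPwmPredictor().score("SIINFEKL", "H-2Kb")
        s2 = ToyPwmPredictor().score("SIINFEKL", "H-2Kb")
        assert s1 == s2

    def test_percentile_in_range_and_allele_specific(self):
        pred = ToyPwmPredictor()
        ic50, rank = pred.score("SIINFEKL", "H-2Kb")
        assert 0 <= rank <= 100 and ic50 > 0
        assert pred.score("SIINFEKL", "H-2Kb") != pred.score("SIINFEKL", "H-2Dd")

    def test_table_predictor_roundtrip(self, tmp_path):
        path = tmp_path / "pred.tsv"
        path.write_text(
            "#peptide\tallele\tic50_nm\tpercentile_rank\n"
            "SIINFEKL\tH-2Kb\t35.0\t0.2\n"
        )
        pred = TablePredictor.from_tsv(path)
        assert pred.score("SIINFEKL", "H-2Kb") == (35.0, 0.2)
        with pytest.raises(KeyError):
            pred.score("AAAAAAAA", "H-2Kb")


class TestBestEpitope:
    def _candidates(self, seed=3, n_prot=40, pos=20):
        rng = np.random.default_rng(seed)
        prot = _rand_protein(rng, n_prot)
        mut = "K" if prot.sequence[pos - 1] != "K" else "R"
        return [
            NeoepitopeCandidate(
                gene_id="g1", aa_change=f"X{pos}{mut}", peptide=p,
                wildtype_peptide=w, mut_offset=off,
            )
            for p, w, off in enumerate_mutant_peptides(prot, pos, mut)
        ]

    def test_single_candidate_returned(self):
        cand = self._candidates()[0]
        pred = ToyPwmPredictor()
        best = best_epitope([cand], ["H-2Dd"], pred)
        assert best.peptide == cand.peptide and best.allele == "H-2Dd"

    def test_matches_brute_force_argmin(self):
        cands = self._candidates()
        alleles = ["H-2Dd", "H-2Kd", "H-2Ld"]
        pred = ToyPwmPredictor()
        best = best_epitope(cands, alleles, pred)
        grid = [
            (pred.score(c.peptide, a), c.peptide, a)
            for c in cands
            for a in alleles
        ]
        exp_rank = min(s[1] for (s, _p, _a) in [(g[0], g[1], g[2]) for g in grid])
        assert best.percentile_rank == exp_rank
        brute = min(grid, key=lambda g: (g[0][1], g[0][0], g[1], g[2]))
        assert (best.peptide, best.allele) == (brute[1], brute[2])

    def test_invariant_to_candidate_ordering(self):
        cands = self._candidates(seed=4)
        pred = ToyPwmPredictor()
        alleles = ["H-2Dd", "H-2Kd"]
        a = best_epitope(cands, alleles, pred)
        b = best_epitope(list(reversed(cands)), alleles, pred)
        assert a == b

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            best_epitope([], ["H-2Dd"], ToyPwmPredictor())
        with pytest.raises(ValueError):
            best_epitope(self._candidates(), [], ToyPwmPredictor())


class TestCascade:
    def test_empty_input_empty_tiers(self):
        tiers = prioritize_cascade([], {}, {}, {})
        assert all(len(t.members) == 0 for t in tiers.values())

    @given(
        data=hst.lists(
            hst.tuples(
                hst.floats(0, 100),  # rpkm
                hst.floats(0, 100),  # best rank
            ),
            max_size=60,
        ),
        rank_a=hst.floats(0.1, 50),
        rank_b=hst.floats(0.1, 50),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nesting_and_rank_monotonicity(self, data, rank_a, rank_b):
        keys = list(range(len(data)))
        gene_of = {k: f"g{k}" for k in keys}
        expr = {f"g{k}": data[k][0] for k in keys}
        ranks = {k: data[k][1] for k in keys}
        lo, hi = sorted([rank_a, rank_b])
        t_lo = prioritize_cascade(keys, gene_of, expr, ranks, rank_max=lo)
        t_hi = prioritize_cascade(keys, gene_of, expr, ranks, rank_max=hi)
        for t in (t_lo, t_hi):
            assert t["high_expression_binder"].members <= t["binder"].members
            assert t["binder"].members <= t["expressed"].members
            assert t["expressed"].members <= t["all"].members
        # raising the rank threshold never shrinks any tier
        for name in ("binder", "high_expression_binder"):
            assert t_lo[name].members <= t_hi[name].members

    def test_missing_expression_treated_as_zero(self):
        tiers = prioritize_cascade([1], {1: "gX"}, {}, {1: 0.5})
        assert tiers["expressed"].members == frozenset()

    def test_planted_memberships_recovered(self, small_sim):
        truth = small_sim["truth"]
        expr = small_sim["expression"]
        tiers = prioritize_cascade(
            sorted(truth.tiers["all"]),
            {k: truth.variants[k]["gene_id"] for k in truth.tiers["all"]},
            truth.rpkm,
            expr["best_ranks"],
        )
        for name, members in truth.tiers.items():
            assert tiers[name].members == members


class TestCandidateInvariants:
    def test_wildtype_must_differ_exactly_at_offset(self):
        with pytest.raises(ValueError):
            NeoepitopeCandidate(
                gene_id="g", aa_change="A1K", peptide="KAAAAAAA",
                wildtype_peptide="KAAAAAAA", mut_offset=0,
            )
        with pytest.raises(ValueError):
            NeoepitopeCandidate(
                gene_id="g", aa_change="A1K", peptide="KAAAAAAA",
                wildtype_peptide="AAAAAAAK", mut_offset=0,
            )
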