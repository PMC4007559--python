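"""Neoepitope enumeration, binding prediction and prioritization.

For every missense mutation, all 8-, 9-, 10- and 11-mer peptides that
contain the mutated residue are enumerated together with their wild-type
counterparts.  A pluggable binding predictor scores each (peptide, allele)
pair with an IC50 (nM) and a consensus-style percentile rank; the best
epitope-allele pair per mutation is the one with the lowest percentile
rank.  Mutations are then prioritized through a nested cascade:

    all  ⊇  expressed (gene RPKM > 0)
         ⊇  binder (percentile rank <= 1%)
         ⊇  high_expression_binder (gene RPKM >= 10)

The shipping predictor is a deterministic toy position-weight-matrix
scorer with a fixed background peptide set per (allele, length); it is a
stand-in for external consensus predictors, stable across runs and
platforms, and exists so the whole cascade is reproducible without network
services.  Real predictions can be plugged in via :class:`TablePredictor`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .io_formats import ProteinRecord

__all__ = [
    "NeoepitopeCandidate",
    "BindingPredictor",
    "ToyPwmPredictor",
    "TablePredictor",
    "CascadeTier",
    "enumerate_mutant_peptides",
    "peptide_window_count",
    "best_epitope",
    "prioritize_cascade",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class NeoepitopeCandidate:
    gene_id: str
    aa_change: str  # e.g. "N42K"
    peptide: str
    wildtype_peptide: str
    mut_offset: int  # 0-based position of the mutant residue in peptide
    allele: str = ""
    ic50_nm: float = float("nan")
    percentile_rank: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.peptide) not in DEFAULT_LENGTHS:
            raise ValueError(f"peptide length {len(self.peptide)} not in 8..11")
        if len(self.peptide) != len(self.wildtype_peptide):
            raise ValueError("wild-type peptide length mismatch")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.peptide, self.wildtype_peptide))
            if a != b
        ]
        if diffs != [self.mut_offset]:
            raise ValueError(
                "peptide must differ from wild type at exactly the mutant offset"
            )


class BindingPredictor(Protocol):
    """Deterministic (peptide, allele) -> (ic50_nm, percentile_rank) scorer."""

    def score(self, peptide: str, allele: str) -> tuple[float, float]: ...


def _stable_seed(*parts: str) -> int:
    h = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(h[:4], "big")


class ToyPwmPredictor:
    """Deterministic toy predictor: per-allele PWM + background percentile.

    Each (allele, length) gets a position-weight matrix drawn from a RNG
    seeded by a hash of the allele name, plus a fixed background set of
    ``n_background`` random peptides.  The percentile rank of a peptide is
    the percentage of background peptides that score at least as well
    (lower = stronger binder, mirroring consensus-rank conventions); IC50
    is a fixed monotone transform of the PWM score.  Version tag ``v1``:
    scores are stable across runs and platforms.
    """

    version = "v1"

    def __init__(self, n_background: int = 1000):
        self.n_background = n_background
        self._pwm_cache: dict[tuple[str, int], np.ndarray] = {}
        self._bg_cache: dict[tuple[str, int], np.ndarray] = {}

    def _pwm(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self._pwm_cache:
            rng = np.random.default_rng(_stable_seed("pwm", self.version, allele, str(length)))
            self._pwm_cache[key] = rng.normal(0.0, 1.0, size=(length, len(AMINO_ACIDS)))
        return self._pwm_cache[key]

    def _raw_score(self, peptide: str, allele: str) -> float:
        pwm = self._pwm(allele, len(peptide))
        idx = [AMINO_ACIDS.index(a) for a in peptide]
        return float(pwm[np.arange(len(peptide)), idx].sum())

    def _background(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self._bg_cache:
            rng = np.random.default_rng(_stable_seed("bg", self.version, allele, str(length)))
            peps = rng.integers(0, len(AMINO_ACIDS), size=(self.n_background, length))
            pwm = self._pwm(allele, length)
            self._bg_cache[key] = np.sort(
                pwm[np.arange(length)[None, :], peps].sum(axis=1)
            )
        return self._bg_cache[key]

    def score(self, peptide: str, allele: str) -> tuple[float, float]:
        s = self._raw_score(peptide, allele)
        bg = self._background(allele, len(peptide))
        # percentile rank: share of background scoring >= this peptide
        rank = 100.0 * (bg.size - np.searchsorted(bg, s, side="left")) / bg.size
        ic50 = float(50000.0 * np.exp(-0.5 * s))  # monotone: higher score, lower IC50
        return (ic50, float(rank))


class TablePredictor:
    """Adapter for precomputed predictions, e.g. exported consensus scores.

    Expects a mapping or a TSV with columns
    ``peptide  allele  ic50_nm  percentile_rank``.  Unknown pairs raise.
    """

    def __init__(self, table: dict[tuple[str, str], tuple[float, float]]):
        self.table = dict(table)

    @classmethod
    def from_tsv(cls, path) -> "TablePredictor":
        table = {}
        with open(path, encoding="utf-8") as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if header is None:
                    header = line.lstrip("#").split("\t")
                    continue
                row = dict(zip(header, line.split("\t")))
                table[(row["peptide"], row["allele"])] = (
                    float(row["ic50_nm"]),
                    float(row["percentile_rank"]),
                )
        return cls(table)

    def score(self, peptide: str, allele: str) -> tuple[float, float]:
        try:
            return self.table[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no precomputed prediction for ({peptide}, {allele})")


def enumerate_mutant_peptides(
    protein: ProteinRecord,
    mut_pos: int,
    mut_aa: str,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
) -> list[tuple[str, str, int]]:
    """All peptide windows of the given lengths covering a missense site.

    ``mut_pos`` is 1-based in the protein; ``protein.sequence`` is the
    wild-type sequence and ``mut_aa`` the substituting residue.  Returns
    ``(mutant_peptide, wildtype_peptide, offset)`` triples where ``offset``
    is the 0-based position of the mutant residue within the peptide.
    Stop-gain substitutions are not enumerable.
    """
    seq = protein.sequence.rstrip("*")
    n = len(seq)
    if not 1 <= mut_pos <= n:
        raise ValueError(f"mutation position {mut_pos} outside protein 1..{n}")
    if mut_aa == "*" or mut_aa not in AMINO_ACIDS:
        raise ValueError(
            f"mutant residue {mut_aa!r} is not enumerable (stop-gain/frameshift "
            "mutations have no fixed-length mutant peptide set)"
        )
    if seq[mut_pos - 1] == mut_aa:
        raise ValueError("mutant residue equals the wild-type residue")
    mutant = seq[: mut_pos - 1] + mut_aa + seq[mut_pos:]
    out = []
    for L in lengths:
        lo = max(0, mut_pos - L)  # 0-based window starts
        hi = min(mut_pos - 1, n - L)
        for start in range(lo, hi + 1):
            out.append(
                (mutant[start : start + L], seq[start : start + L], mut_pos - 1 - start)
            )
    return out


def peptide_window_count(
    protein_len: int, mut_pos: int, lengths: tuple[int, ...] = DEFAULT_LENGTHS
) -> int:
    """Closed-form count of windows covering position ``mut_pos`` (1-based).

    Per length L: [min(mut_pos, protein_len - L + 1) - max(1, mut_pos - L + 1) + 1]+
    An interior mutation with >= 10 flanking residues on both sides yields
    8 + 9 + 10 + 11 = 38 windows.
    """
    total = 0
    for L in lengths:
        lo = max(1, mut_pos - L + 1)
        hi = min(mut_pos, protein_len - L + 1)
        total += max(0, hi - lo + 1)
    return total


def best_epitope(
    candidates: list[NeoepitopeCandidate],
    alleles: list[str],
    predictor: BindingPredictor,
) -> NeoepitopeCandidate:
    """Strongest-binding (peptide, allele) pair for one mutation.

    Minimizes percentile rank over the full peptide x allele grid; ties are
    broken by lower IC50, then lexicographic peptide, then allele name, so
    the result is independent of input ordering.
    """
    if not candidates:
        raise ValueError("no candidate peptides")
    if not alleles:
        raise ValueError("no alleles")
    best: tuple | None = None
    for cand in candidates:
        for allele in alleles:
            ic50, rank = predictor.score(cand.peptide, allele)
            key = (rank, ic50, cand.peptide, allele)
            if best is None or key < best[0]:
                scored = NeoepitopeCandidate(
                    gene_id=cand.gene_id,
                    aa_change=cand.aa_change,
                    peptide=cand.peptide,
                    wildtype_peptide=cand.wildtype_peptide,
                    mut_offset=cand.mut_offset,
                    allele=allele,
                    ic50_nm=ic50,
                    percentile_rank=rank,
                )
                best = (key, scored)
    return best[1]


@dataclass(frozen=True)
class CascadeTier:
    tier: str  # all | expressed | binder | high_expression_binder
    members: frozenset


def prioritize_cascade(
    variant_keys: list,
    gene_of: dict,
    expression: dict[str, float],
    best_ranks: dict,
    *,
    rank_max: float = 1.0,
    expr_min: float = 0.0,
    high_expr: float = 10.0,
) -> dict[str, CascadeTier]:
    """Nested prioritization of mutations by expression and predicted binding.

    ``expression`` maps gene_id -> RPKM (missing genes count as 0);
    ``best_ranks`` maps variant key -> best percentile rank (missing means
    no enumerable epitope, never a binder).  Tiers are nested by
    construction: expressed requires RPKM > expr_min (strict), binder
    additionally requires rank <= rank_max, high_expression_binder
    additionally requires RPKM >= high_expr.
    """
    all_set = frozenset(variant_keys)
    expressed = frozenset(
        k for k in all_set if expression.get(gene_of.get(k), 0.0) > expr_min
    )
    binder = frozenset(
        k for k in expressed if best_ranks.get(k, float("inf")) <= rank_max
    )
    high = frozenset(
        k for k in binder if expression.get(gene_of.get(k), 0.0) >= high_expr
    )
    return {
        "all": CascadeTier("all", all_set),
        "expressed": CascadeTier("expressed", expressed),
        "binder": CascadeTier("binder", binder),
        "high_expression_binder": CascadeTier("high_expression_binder", high),
    }
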