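"""RPKM quantification, expression percentiles and tumor-antigen filtering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpressionRecord",
    "rpkm",
    "expression_table",
    "mean_replicate_rpkm",
    "expression_percentile",
    "ct_antigen_filter",
]


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    count: int
    rpkm: float

    def __post_init__(self) -> None:
        if self.count < 0 or self.rpkm < 0:
            raise ValueError(f"{self.gene_id}: negative count or rpkm")
        if (self.count == 0) != (self.rpkm == 0.0):
            raise ValueError(f"{self.gene_id}: rpkm must be 0 exactly when count is 0")


def rpkm(count: int, exonic_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = count / ((exonic_length_nt / 1000) * (total_mapped / 1e6)).
    """
    if exonic_length_nt <= 0:
        raise ValueError("exonic length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / ((exonic_length_nt / 1000.0) * (total_mapped / 1e6))


def expression_table(
    counts: dict[str, int], lengths: dict[str, int], total_mapped: int | None = None
) -> list[ExpressionRecord]:
    """Quantify a whole count table; library size defaults to the count sum."""
    if not counts:
        raise ValueError("empty count table")
    if total_mapped is None:
        total_mapped = sum(counts.values())
    return [
        ExpressionRecord(g, c, rpkm(c, lengths[g], total_mapped))
        for g, c in counts.items()
    ]


def mean_replicate_rpkm(tables: list[dict[str, float]]) -> dict[str, float]:
    """Mean per-gene RPKM over replicate quantifications."""
    if not tables:
        raise ValueError("no replicate tables")
    genes = set(tables[0])
    for t in tables[1:]:
        if set(t) != genes:
            raise ValueError("replicate tables disagree on gene ids")
    return {g: float(np.mean([t[g] for t in tables])) for g in genes}


def expression_percentile(rpkms: list[float] | np.ndarray, value: float) -> float:
    """Percent of expression values strictly below ``value``.

    With a log-normal-like expression distribution a threshold of 10 RPKM
    typically sits near the 80th percentile of all genes.
    """
    arr = np.asarray(rpkms, dtype=float)
    if arr.size == 0:
        raise ValueError("empty expression table")
    return float((arr < value).mean() * 100.0)


def ct_antigen_filter(
    expr_tumor: dict[str, float],
    expr_normal: dict[str, float],
    antigen_list: list[str],
    hi: float = 10.0,
    lo: float = 10.0,
) -> list[str]:
    """Cancer-testis antigens expressed in tumor but silent in normal tissue.

    A gene is selected iff it is on the antigen list, tumor RPKM > ``hi``
    and normal RPKM < ``lo`` (both strict).  Antigens absent from either
    table are skipped with a warning.
    """
    selected = []
    for gene in antigen_list:
        if gene not in expr_tumor or gene not in expr_normal:
            warnings.warn(f"antigen {gene!r} missing from expression tables; skipped")
            continue
        if expr_tumor[gene] > hi and expr_normal[gene] < lo:
            selected.append(gene)
    return selected
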