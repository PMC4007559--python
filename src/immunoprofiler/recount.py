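"""Recount headline statistics from externally produced annotation tables.

These loaders consume per-variant and per-gene annotation tables (plain
TSV exports of a full characterization, e.g. from a published supplement)
and recompute the summary counts from the rows: SNV totals, transition
counts, expression/binding cascade sizes, and copy-number summaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mutation_spectrum import TRANSITIONS, substitution_class

__all__ = ["recount_snv_table", "recount_copy_number_table"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def recount_snv_table(path: str | Path) -> dict:
    """Recompute SNV headline counts from a per-variant annotation TSV.

    Expected columns: ``ref``, ``alt`` (single bases), ``mean_rpkm``
    (gene expression), ``best_percentile_rank`` (best class I consensus
    rank of the variant's mutant peptides; blank when not applicable).
    """
    df = _read_tsv(path)
    n = len(df)
    classes = [
        substitution_class(r, a, "A", "A").pyrimidine_class
        for r, a in zip(df["ref"], df["alt"])
    ]
    transitions = sum(c in TRANSITIONS for c in classes)
    rpkm = pd.to_numeric(df["mean_rpkm"], errors="coerce").fillna(0.0)
    rank = pd.to_numeric(df["best_percentile_rank"], errors="coerce")
    expressed = rpkm > 0
    binder = expressed & (rank <= 1.0)
    high = binder & (rpkm >= 10.0)
    return {
        "n_snvs": n,
        "n_transitions": int(transitions),
        "n_expressed": int(expressed.sum()),
        "n_strong_binders": int(binder.sum()),
        "n_high_expression_binders": int(high.sum()),
    }


def recount_copy_number_table(path: str | Path) -> dict:
    """Recompute copy-number summaries from a per-gene TSV.

    Expected columns: ``gene``, ``copy_number``.
    """
    df = _read_tsv(path)
    c = pd.to_numeric(df["copy_number"], errors="coerce").dropna()
    return {
        "n_genes": int(c.size),
        "median_copy_number": float(np.median(c)),
        "mean_copy_number": float(c.mean()),
        "n_triploid": int((c == 3).sum()),
        "n_tetraploid": int((c == 4).sum()),
    }
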