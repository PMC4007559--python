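"""Joint absolute copy-number and zygosity inference from exome depth ratios.

The model rests on two assumptions about a (near-)pure tumor sample:

1. the library-normalized tumor/normal read-count ratio at a gene is
   proportional to the locus copy number ``c``: ``E[r] = c * s / 2`` for a
   global scale ``s`` (``s = 1`` means ratio 1.0 is diploid);
2. the variant allele fraction of a somatic mutation can take only the
   discrete values ``m / c`` for an integer allele multiplicity
   ``1 <= m <= c``.

The scale ``s`` is not identifiable from ratios alone (a genome-wide
triploid state looks like a diploid one at 1.5x the scale), so the fitter
scores each candidate ``s`` with the depth residuals plus a binomial
likelihood term for observed VAFs and breaks remaining ties toward the
scale closest to 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import VariantRecord

__all__ = [
    "DepthRatio",
    "CopyNumberCall",
    "ZygosityCall",
    "PloidyModel",
    "normalized_ratio",
    "fit_ploidy_model",
    "infer_copy_number",
    "infer_zygosity",
    "cn_summary",
]


@dataclass(frozen=True)
class DepthRatio:
    """Library-normalized tumor/normal depth ratio for one gene.

    ``flagged`` marks genes whose normal count is zero: the ratio is
    undefined there and the gene is excluded from fitting and calling.
    """

    gene_id: str
    r: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.flagged and self.r < 0:
            raise ValueError(f"{self.gene_id}: negative ratio")


@dataclass(frozen=True)
class CopyNumberCall:
    gene_id: str
    c: int | None  # None when the ratio was flagged (normal count 0)
    fit_residual: float = 0.0
    amplified_beyond_model: bool = False


@dataclass(frozen=True)
class ZygosityCall:
    variant: VariantRecord
    c: int
    m: int
    vaf: float
    zygosity: str  # "homozygous" | "heterozygous"

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.c:
            raise ValueError(f"m={self.m} outside [1, c={self.c}]")
        expect = "homozygous" if self.m == self.c else "heterozygous"
        if self.zygosity != expect:
            raise ValueError("zygosity label inconsistent with m == c rule")


@dataclass(frozen=True)
class PloidyModel:
    """Global scale ``s`` mapping ratio 1.0 to copy number ``2/s``."""

    s: float
    c_max: int = 8
    purity: float = 1.0
    objective: float = float("nan")

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")

    def expected_vaf(self, m: int, c: int) -> float:
        """Expected VAF of a variant at multiplicity m in a copy-c locus.

        With tumor purity ``p`` the sample mixes ``p`` tumor copies with
        ``2(1-p)`` diploid normal copies: VAF = m*p / (p*c + 2*(1-p)).
        """
        p = self.purity
        return m * p / (p * c + 2.0 * (1.0 - p))


def normalized_ratio(
    tumor_counts: dict[str, int], normal_counts: dict[str, int]
) -> list[DepthRatio]:
    """Per-gene ratio r_g = (t_g / T) / (n_g / N) for shared gene ids.

    T and N are the total mapped counts of each library, so a uniform
    rescaling of either library cancels.  Genes with a zero normal count
    are returned flagged rather than as infinite ratios.
    """
    if not tumor_counts or not normal_counts:
        raise ValueError("empty count table")
    shared = [g for g in tumor_counts if g in normal_counts]
    if not shared:
        raise ValueError("tumor and normal tables share no gene ids")
    total_t = float(sum(tumor_counts[g] for g in shared))
    total_n = float(sum(normal_counts[g] for g in shared))
    if total_t <= 0 or total_n <= 0:
        raise ValueError("library size must be positive")
    out = []
    for g in shared:
        n = normal_counts[g]
        if n == 0:
            out.append(DepthRatio(g, 0.0, flagged=True))
        else:
            out.append(DepthRatio(g, (tumor_counts[g] / total_t) / (n / total_n)))
    return out


def _vaf_penalty_table(a: np.ndarray, d: np.ndarray, c_max: int) -> np.ndarray:
    """penalty[i, c] = min_{1<=m<=c} -log Binom(a_i | d_i, m/c), c = 0..c_max.

    c = 0 is scored like c = 1 (a variant cannot sit in a deleted locus,
    so a candidate scale that deletes its gene gets the worst single-copy
    explanation rather than a free pass).
    """
    n = len(a)
    table = np.full((n, c_max + 1), np.inf)
    for c in range(1, c_max + 1):
        ms = np.arange(1, c + 1)
        # (n, c) matrix of -logpmf over multiplicities; VAFs clipped away
        # from 0/1 so sequencing error never yields -inf likelihoods
        p = np.clip(ms / c, 1e-3, 1.0 - 1e-3)
        lp = stats.binom.logpmf(a[:, None], d[:, None], p[None, :])
        table[:, c] = -lp.max(axis=1)
    table[:, 0] = table[:, 1]
    return table


def fit_ploidy_model(
    ratios: list[DepthRatio],
    variants: list[tuple[int, int, str]] | None = None,
    *,
    c_max: int = 8,
    lam: float = 1.0,
    s_grid: np.ndarray | None = None,
    purity: float = 1.0,
) -> PloidyModel:
    """Grid-search the global scale ``s`` over [0.2, 3.0] step 0.01.

    ``variants`` is an optional list of ``(alt_count, depth, gene_id)``
    tuples; their binomial likelihood under the best discrete multiplicity
    at each candidate scale (weighted by ``lam``) disambiguates scales that
    the depth residuals alone cannot.  Ties are broken toward s closest
    to 1.0 (then toward the larger s, i.e. the lower-ploidy explanation).
    """
    usable = [dr for dr in ratios if not dr.flagged]
    if not usable:
        raise ValueError("no usable (unflagged) ratios")
    r = np.array([dr.r for dr in usable])
    if np.allclose(r, 0.0):
        raise ValueError("degenerate input: all ratios are zero")
    gene_index = {dr.gene_id: i for i, dr in enumerate(usable)}
    if s_grid is None:
        s_grid = np.arange(0.2, 3.0 + 1e-9, 0.01)

    penalty = var_gene = None
    if variants:
        var_a = np.array([v[0] for v in variants])
        var_d = np.array([v[1] for v in variants])
        var_gene = np.array([gene_index.get(v[2], -1) for v in variants])
        mask = var_gene >= 0
        var_gene = var_gene[mask]
        penalty = _vaf_penalty_table(var_a[mask], var_d[mask], c_max)

    cs = np.arange(0, c_max + 1)
    best = None
    for s in s_grid:
        resid = (r[:, None] - cs[None, :] * s / 2.0) ** 2
        c_hat = np.argmin(resid, axis=1)
        obj = float(resid[np.arange(len(r)), c_hat].sum())
        if penalty is not None:
            obj += lam * float(
                penalty[np.arange(len(var_gene)), c_hat[var_gene]].sum()
            )
        key = (round(obj, 10), round(abs(s - 1.0), 10), round(-s, 10))
        if best is None or key < best[0]:
            best = (key, float(s), obj)
    return PloidyModel(s=best[1], c_max=c_max, purity=purity, objective=best[2])


def infer_copy_number(
    ratio: DepthRatio,
    model: PloidyModel,
    *,
    deletion_max_ratio: float = 0.25,
) -> CopyNumberCall:
    """Round a depth ratio to the nearest integer copy number under ``model``.

    ``c = argmin_{0..c_max} |r - c*s/2|`` with ties broken toward the lower
    c.  A homozygous-deletion call (c=0) additionally requires
    ``r < deletion_max_ratio * s``, separating true deletions from noisy
    low-coverage genes.  Ratios above ``(c_max + 0.5) * s / 2`` are flagged
    as amplified beyond the model.
    """
    if ratio.flagged:
        return CopyNumberCall(ratio.gene_id, c=None)
    s = model.s
    cs = np.arange(0, model.c_max + 1)
    resid = np.abs(ratio.r - cs * s / 2.0)
    c = int(np.argmin(resid))  # argmin takes first (lowest c) on ties
    if c == 0 and ratio.r >= deletion_max_ratio * s:
        c = 1
    amplified = ratio.r > (model.c_max + 0.5) * s / 2.0
    return CopyNumberCall(
        ratio.gene_id,
        c=c,
        fit_residual=float(resid[c]),
        amplified_beyond_model=amplified,
    )


def smooth_calls(
    calls: list[CopyNumberCall], genes_in_order: list[str], window: int = 11
) -> list[CopyNumberCall]:
    """Optional running-median smoothing of integer calls along chromosome order.

    Guards against sparse single-gene outliers; off by default in the
    pipeline.  Flagged (c=None) calls pass through untouched.
    """
    by_id = {c.gene_id: c for c in calls}
    ordered = [by_id[g] for g in genes_in_order if g in by_id]
    cvals = np.array([c.c if c.c is not None else -1 for c in ordered], dtype=float)
    half = window // 2
    out = dict(by_id)
    for i, call in enumerate(ordered):
        if call.c is None:
            continue
        lo, hi = max(0, i - half), min(len(ordered), i + half + 1)
        win = cvals[lo:hi]
        win = win[win >= 0]
        out[call.gene_id] = CopyNumberCall(
            call.gene_id,
            c=int(np.median(win)),
            fit_residual=call.fit_residual,
            amplified_beyond_model=call.amplified_beyond_model,
        )
    return [out[c.gene_id] for c in calls]


def infer_zygosity(
    variant: VariantRecord,
    c: int,
    a: int,
    d: int,
    *,
    model: PloidyModel | None = None,
    error_rate: float = 1e-3,
) -> ZygosityCall:
    """Maximum-likelihood allele multiplicity for a variant in a copy-c locus.

    ``m = argmax_{1..c} Binom(a | d, VAF(m, c))``; the call is homozygous
    iff every tumor copy carries the mutation (m = c).  With the default
    pure-tumor model VAF(m, c) = m/c, so an observed VAF of 1.0 is always
    called homozygous.  Expected VAFs are clipped into
    ``[error_rate, 1 - error_rate]``: sequencing error means a homozygous
    site can still show a few reference reads, so a 98% observed VAF at
    c=4 must compare against ~0.999, not exactly 1.
    """
    if c < 1:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: variant in deleted region (c=0)"
        )
    if d <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= a <= d:
        raise ValueError("alt count outside [0, depth]")
    ms = np.arange(1, c + 1)
    if model is None:
        probs = ms / c
    else:
        probs = np.array([model.expected_vaf(int(m), c) for m in ms])
    probs = np.clip(probs, error_rate, 1.0 - error_rate)
    logpmf = stats.binom.logpmf(a, d, probs)
    m = int(ms[np.argmax(logpmf)])
    return ZygosityCall(
        variant=variant,
        c=c,
        m=m,
        vaf=a / d,
        zygosity="homozygous" if m == c else "heterozygous",
    )


def cn_summary(calls: list[CopyNumberCall]) -> dict:
    """Median, mean and integer histogram of callable copy numbers."""
    cs = [call.c for call in calls if call.c is not None]
    if not cs:
        raise ValueError("no callable copy numbers")
    arr = np.array(cs)
    hist: dict[int, int] = {}
    for c in cs:
        hist[c] = hist.get(c, 0) + 1
    return {
        "n": len(cs),
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "histogram": dict(sorted(hist.items())),
    }
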