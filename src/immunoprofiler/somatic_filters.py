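"""Consensus and binomial confidence filters for somatic variant calls.

A high-confidence somatic SNV must be reported by every caller in every
sequencing replicate, its tumor alt reads must be inconsistent with the
sequencing error rate (one-sided binomial test), and the matched normal
must be covered deeply enough that a germline heterozygote would almost
surely have shown alt reads there.  Indels follow simpler count rules:
enough supporting tumor reads and zero germline support.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io_formats import VariantRecord

__all__ = [
    "FilterParams",
    "FilterVerdict",
    "consensus_calls",
    "tumor_error_filter",
    "germline_coverage_filter",
    "indel_filter",
    "rna_zygosity",
    "filter_snvs",
]


@dataclass(frozen=True)
class FilterParams:
    """Tunable thresholds for the somatic filter chain.

    error_rate
        Per-base sequencing error rate e; default 1e-3 (typical Illumina).
    alpha_tumor
        Significance level for rejecting "alt reads are sequencing error".
    beta_germline
        Max probability that a true germline heterozygote would have shown
        at most the observed number of alt reads in the normal sample.
    min_indel_reads
        Minimum tumor reads supporting an indel.
    """

    error_rate: float = 1e-3
    alpha_tumor: float = 1e-4
    beta_germline: float = 1e-3
    min_indel_reads: int = 10
    germline_het_vaf: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        for name in ("alpha_tumor", "beta_germline"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class FilterVerdict:
    variant: VariantRecord
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when reasons is empty")


def consensus_calls(
    call_sets: dict[tuple[str, int], set],
    *,
    min_replicates: int | None = None,
) -> set:
    """Variants present in every (caller, replicate) call set.

    ``call_sets`` maps ``(caller, replicate)`` to a set of variant keys.
    The strict default requires presence in every cell; ``min_replicates``
    relaxes the per-caller replicate requirement to "at least k replicates".
    """
    if not call_sets:
        raise ValueError("no call sets supplied")
    if min_replicates is None:
        out: set | None = None
        for calls in call_sets.values():
            out = set(calls) if out is None else out & calls
        return out
    callers: dict[str, list[set]] = {}
    for (caller, _rep), calls in call_sets.items():
        callers.setdefault(caller, []).append(calls)
    result: set | None = None
    for reps in callers.values():
        all_keys = set().union(*reps)
        kept = {k for k in all_keys if sum(k in s for s in reps) >= min_replicates}
        result = kept if result is None else result & kept
    return result


def tumor_error_filter(
    a: int, d: int, params: FilterParams = FilterParams()
) -> tuple[bool, float]:
    """Test whether the tumor alt count exceeds sequencing error.

    p = P(X >= a) for X ~ Binom(d, e); the variant passes when p <=
    alpha_tumor, i.e. the observed alt reads are implausible as error.
    Returns (passed, p).
    """
    if d <= 0:
        return (False, 1.0)
    if not 0 <= a <= d:
        raise ValueError("alt count outside [0, depth]")
    p = float(stats.binom.sf(a - 1, d, params.error_rate))
    return (p <= params.alpha_tumor, p)


def germline_coverage_filter(
    g_a: int, d_g: int, params: FilterParams = FilterParams()
) -> tuple[bool, float]:
    """Guard against somatic calls caused by thin germline coverage.

    p_miss = P(X <= g_a) for X ~ Binom(d_g, 0.5): the chance a germline
    heterozygote would have produced no more alt reads than observed.  A
    somatic call is allowed only when p_miss <= beta_germline.  At
    g_a = 0 this reduces to 0.5^d_g, so depth >= 10 is needed at the
    default beta = 1e-3.  Returns (passed, p_miss).
    """
    if d_g < 0 or not 0 <= g_a <= max(d_g, 0):
        raise ValueError("invalid germline counts")
    if d_g == 0:
        return (False, 1.0)
    p_miss = float(stats.binom.cdf(g_a, d_g, params.germline_het_vaf))
    return (p_miss <= params.beta_germline, p_miss)


def indel_filter(
    variant: VariantRecord,
    tumor_support_reads: int,
    germline_support_reads: int,
    params: FilterParams = FilterParams(),
) -> bool:
    """Indels require >= min_indel_reads tumor support and zero germline support."""
    if variant.is_snv:
        raise ValueError("indel_filter applied to an SNV")
    if tumor_support_reads < 0 or germline_support_reads < 0:
        raise ValueError("negative read counts")
    return (
        tumor_support_reads >= params.min_indel_reads
        and germline_support_reads == 0
    )


def rna_zygosity(a: int, d: int, homo_vaf_min: float = 0.85) -> str:
    """Classify zygosity from very deep RNA coverage of a variant site.

    At RNA depths of thousands of reads the VAF estimate is tight enough
    that a simple threshold separates homozygous (VAF near 1.0) from
    heterozygous (VAF near 0.5) calls; 0.85 keeps a binomial 95% interval
    at d >= 20 on the correct side for both.
    """
    if d <= 0:
        raise ValueError("depth must be positive")
    return "homozygous" if a / d >= homo_vaf_min else "heterozygous"


def filter_snvs(
    variants: list[VariantRecord],
    call_sets: dict[tuple[str, int], set],
    params: FilterParams = FilterParams(),
    *,
    tumor_sample: str = "T",
    normal_sample: str = "N",
    min_replicates: int | None = None,
) -> list[FilterVerdict]:
    """Run the full SNV filter chain and report per-variant verdicts.

    The three filters (caller/replicate consensus, tumor binomial error
    test, germline coverage test) are independent per variant, so the
    surviving set does not depend on their order; all failing reasons are
    accumulated rather than short-circuited.
    """
    consensus = consensus_calls(call_sets, min_replicates=min_replicates)
    verdicts = []
    for v in variants:
        reasons: list[str] = []
        if v.key not in consensus:
            present = {k for k, s in call_sets.items() if v.key in s}
            missing_callers = {c for c, _ in call_sets} - {c for c, _ in present}
            reasons.append("caller_missing" if missing_callers else "replicate_missing")
        ref_t, alt_t = v.pooled_depth(tumor_sample)
        ok, _p = tumor_error_filter(alt_t, ref_t + alt_t, params)
        if not ok:
            reasons.append("tumor_error")
        ref_n, alt_n = v.pooled_depth(normal_sample)
        ok, _p = germline_coverage_filter(alt_n, ref_n + alt_n, params)
        if not ok:
            reasons.append("germline_undercovered")
        verdicts.append(
            FilterVerdict(variant=v, passed=not reasons, reasons=tuple(reasons))
        )
    return verdicts
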