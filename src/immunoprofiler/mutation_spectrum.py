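"""Substitution classes, 3' context, coding effects and per-Mb rates.

Substitutions are collapsed onto the pyrimidine strand (the standard
mutational-signature convention): each of the 12 raw ref>alt pairs maps to
one of six classes C>A, C>G, C>T, T>A, T>C, T>G, and the base immediately
3' of the mutation is reported on that same strand.  When the reference
base is a purine the whole local context is reverse-complemented, so the
pyrimidine-strand 3' neighbor is the complement of the purine-strand 5'
neighbor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import VariantRecord

__all__ = [
    "SubstitutionClass",
    "CodingEffect",
    "Transcript",
    "substitution_class",
    "spectrum_summary",
    "coding_effect",
    "most_severe_effect",
    "mutation_rate_per_mb",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}
CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = {"C>T", "T>C"}


@dataclass(frozen=True)
class SubstitutionClass:
    pyrimidine_class: str  # one of CLASSES
    three_prime_base: str  # A/C/G/T on the pyrimidine strand
    is_transition: bool

    def __post_init__(self) -> None:
        if self.pyrimidine_class not in CLASSES:
            raise ValueError(f"unknown class {self.pyrimidine_class}")
        if self.three_prime_base not in _COMPLEMENT:
            raise ValueError(f"bad 3' base {self.three_prime_base}")
        if self.is_transition != (self.pyrimidine_class in TRANSITIONS):
            raise ValueError("transition flag inconsistent with class")

    @property
    def doublet(self) -> str:
        """Class with its 3' neighbor, e.g. 'CT>TT' for C>T followed by T."""
        ref, alt = self.pyrimidine_class.split(">")
        return f"{ref}{self.three_prime_base}>{alt}{self.three_prime_base}"


def substitution_class(
    ref: str, alt: str, flank5: str, flank3: str
) -> SubstitutionClass:
    """Canonical pyrimidine-strand substitution class with 3' context.

    ``flank5`` and ``flank3`` are the reference bases immediately 5' and 3'
    of the mutated position on the strand ``ref``/``alt`` are reported on
    (normally '+').  For a purine ref the context is reverse-complemented,
    so the reported 3' neighbor is the complement of ``flank5``.
    """
    for b in (ref, alt, flank5, flank3):
        if b not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("ref == alt")
    if ref in _PYRIMIDINES:
        cls = f"{ref}>{alt}"
        three = flank3
    else:
        cls = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
        three = _COMPLEMENT[flank5]
    return SubstitutionClass(
        pyrimidine_class=cls,
        three_prime_base=three,
        is_transition=cls in TRANSITIONS,
    )


def spectrum_summary(
    classes: list[SubstitutionClass],
) -> dict:
    """Class counts, transition fraction and the 6x4 class-by-context matrix."""
    if not classes:
        raise ValueError("no substitutions supplied")
    n = len(classes)
    counts = Counter(c.pyrimidine_class for c in classes)
    context = pd.DataFrame(
        0, index=list(CLASSES), columns=["A", "C", "G", "T"], dtype=int
    )
    for c in classes:
        context.loc[c.pyrimidine_class, c.three_prime_base] += 1
    transitions = sum(counts.get(k, 0) for k in TRANSITIONS)
    return {
        "n": n,
        "class_counts": {k: counts.get(k, 0) for k in CLASSES},
        "transitions": transitions,
        "transversions": n - transitions,
        "transition_fraction": transitions / n,
        "context_matrix": context,
    }


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------

_SEVERITY = {"nonsense": 4, "missense": 3, "silent": 2, "UTR": 1, "noncoding": 0}


@dataclass(frozen=True)
class Transcript:
    """Minimal transcript: an in-frame coding sequence for effect calling.

    ``cds`` starts at codon 1; variant positions are given 1-based within
    the CDS.  Genomic-to-CDS mapping is the caller's concern.
    """

    transcript_id: str
    gene_id: str
    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length must be a multiple of 3")
        if set(self.cds.upper()) - set("ACGT"):
            raise ValueError(f"{self.transcript_id}: CDS contains non-ACGT bases")


@dataclass(frozen=True)
class CodingEffect:
    category: str  # silent | missense | nonsense | UTR | noncoding
    aa_change: str | None = None  # e.g. "G12D"; None outside coding regions

    def __post_init__(self) -> None:
        if self.category not in _SEVERITY:
            raise ValueError(f"unknown category {self.category}")
        coding = self.category in ("silent", "missense", "nonsense")
        if coding != (self.aa_change is not None):
            raise ValueError("aa_change present iff the effect is coding")


def coding_effect(transcript: Transcript, cds_pos: int, ref: str, alt: str) -> CodingEffect:
    """Effect of a single-base substitution at 1-based CDS position ``cds_pos``.

    Translates the reference and mutated codon with the standard genetic
    code; silent when the amino acid is unchanged, nonsense when the
    mutated codon is a stop.  aa_change is "<refAA><codon#><altAA>",
    e.g. the activating Kras change GGC>GAC at codon 12 formats as "G12D".
    """
    cds = transcript.cds.upper()
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(
            f"{transcript.transcript_id}: CDS position {cds_pos} outside 1..{len(cds)}"
        )
    if cds[cds_pos - 1] != ref.upper():
        raise ValueError(
            f"{transcript.transcript_id}: reference base mismatch at CDS pos "
            f"{cds_pos} (transcript has {cds[cds_pos - 1]}, variant says {ref})"
        )
    codon_idx = (cds_pos - 1) // 3
    codon_start = codon_idx * 3
    codon = cds[codon_start : codon_start + 3]
    offset = (cds_pos - 1) % 3
    mut_codon = codon[:offset] + alt.upper() + codon[offset + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut_codon).translate())
    change = f"{ref_aa}{codon_idx + 1}{alt_aa}"
    if alt_aa == ref_aa:
        return CodingEffect("silent", change)
    if alt_aa == "*":
        return CodingEffect("nonsense", change)
    return CodingEffect("missense", change)


def most_severe_effect(effects: list[CodingEffect]) -> CodingEffect:
    """Pick one effect per variant when it hits multiple transcripts.

    Severity order: nonsense > missense > silent > UTR > noncoding.
    """
    if not effects:
        raise ValueError("no effects to rank")
    return max(effects, key=lambda e: _SEVERITY[e.category])


def mutation_rate_per_mb(n_mut: int, coding_nt: int) -> tuple[float, int]:
    """Mutations per megabase of coding sequence: (exact rate, nearest int)."""
    if coding_nt <= 0:
        raise ValueError("coding_nt must be positive")
    if n_mut < 0:
        raise ValueError("negative mutation count")
    rate = n_mut / (coding_nt / 1e6)
    return rate, int(np.rint(rate))
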