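"""MHC typing and expression quantification from RNA reads.

Short RNA reads are assigned to MHC allele reference sequences by exact
substring matching in either orientation; a read counts toward an allele
only when it matches that allele uniquely.  Per-allele counts are
RPKM-normalized by the allele transcript length, and the genotype is the
set of alleles above a detection threshold.  Class II presentation is
called functional only when a class II allele is detected AND the class II
transactivator (Ciita) is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .expression import rpkm as _rpkm

__all__ = [
    "MhcAllele",
    "MhcProfile",
    "H2_TRANSCRIPT_LENGTHS_NT",
    "assign_reads",
    "allele_rpkm",
    "call_genotype",
    "balbc_reference_lengths",
]

# Published transcript lengths (nt) for the mouse H-2 allele references of
# the BALB/c (d haplotype) and C57BL/6 (b haplotype) strains.
H2_TRANSCRIPT_LENGTHS_NT: dict[str, int] = {
    "H-2Dd": 1586,
    "H-2Kd": 1540,
    "H-2Ld": 1102,
    "H-2Iad": 978,
    "H-2Db": 1567,
    "H-2Kb": 1564,
    "H-2Iab": 932,
}


def _mhc_class(name: str) -> str:
    return "II" if "Ia" in name else "I"


@dataclass(frozen=True)
class MhcAllele:
    """An MHC allele reference transcript.

    When ``sequence`` is given, ``length_nt`` must equal its length; when
    absent (length-only bookkeeping) the published transcript lengths are
    honored via :data:`H2_TRANSCRIPT_LENGTHS_NT`.
    """

    name: str
    mhc_class: str  # "I" | "II"
    sequence: str = ""
    length_nt: int = 0

    def __post_init__(self) -> None:
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"{self.name}: class must be I or II")
        if self.sequence:
            if self.length_nt == 0:
                object.__setattr__(self, "length_nt", len(self.sequence))
            elif self.length_nt != len(self.sequence):
                raise ValueError(f"{self.name}: length_nt != len(sequence)")
        elif self.length_nt <= 0:
            if self.name in H2_TRANSCRIPT_LENGTHS_NT:
                object.__setattr__(self, "length_nt", H2_TRANSCRIPT_LENGTHS_NT[self.name])
            else:
                raise ValueError(f"{self.name}: no sequence and no length")

    @classmethod
    def from_fasta_record(cls, name: str, sequence: str) -> "MhcAllele":
        return cls(name=name, mhc_class=_mhc_class(name), sequence=sequence.upper())


@dataclass
class MhcProfile:
    unique_counts: dict[str, int]
    ambiguous: int
    unmatched: int
    rpkm: dict[str, float] = field(default_factory=dict)
    genotype: set[str] = field(default_factory=set)
    class_ii_functional: bool = False

    @property
    def total_reads(self) -> int:
        return sum(self.unique_counts.values()) + self.ambiguous + self.unmatched


def _matches(read: str, allele_seq: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return read in allele_seq
    import edlib

    res = edlib.align(read, allele_seq, mode="HW", task="distance", k=max_mismatch)
    return res["editDistance"] != -1


def assign_reads(
    reads: list[str],
    reference: list[MhcAllele],
    *,
    max_mismatch: int = 0,
) -> MhcProfile:
    """Assign each read to the unique allele it matches, if any.

    A read matches an allele when it (or its reverse complement) occurs as
    a substring of the allele sequence, allowing up to ``max_mismatch``
    substitutions.  Reads matching several alleles are ambiguous and
    unassigned; unique + ambiguous + unmatched always partitions the input.
    """
    if not reference:
        raise ValueError("empty allele reference")
    for al in reference:
        if not al.sequence:
            raise ValueError(f"{al.name}: allele has no sequence to match against")
    counts = {al.name: 0 for al in reference}
    ambiguous = unmatched = 0
    for read in reads:
        read = read.upper()
        rc = str(Seq(read).reverse_complement())
        hits = [
            al.name
            for al in reference
            if _matches(read, al.sequence, max_mismatch)
            or _matches(rc, al.sequence, max_mismatch)
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unmatched += 1
    return MhcProfile(unique_counts=counts, ambiguous=ambiguous, unmatched=unmatched)


def allele_rpkm(count: int, allele: MhcAllele, total_mapped: int) -> float:
    """RPKM for an allele using its reference transcript length."""
    if count == 0:
        return 0.0
    return _rpkm(count, allele.length_nt, total_mapped)


def quantify(
    profile: MhcProfile, reference: list[MhcAllele], total_mapped: int
) -> MhcProfile:
    """Fill in per-allele RPKM on a profile from its unique counts."""
    profile.rpkm = {
        al.name: allele_rpkm(profile.unique_counts.get(al.name, 0), al, total_mapped)
        for al in reference
    }
    return profile


def call_genotype(
    profile: MhcProfile,
    reference: list[MhcAllele],
    *,
    detect_rpkm: float = 1.0,
    ciita_rpkm: float = 0.0,
) -> MhcProfile:
    """Genotype = alleles expressed at or above the detection threshold.

    Class II antigen presentation additionally requires the transactivator:
    ``class_ii_functional`` is true only when some class II allele is
    detected and ``ciita_rpkm > 0``.
    """
    if not profile.rpkm:
        raise ValueError("profile has no RPKM values; run quantify() first")
    by_name = {al.name: al for al in reference}
    profile.genotype = {
        name for name, v in profile.rpkm.items() if v >= detect_rpkm
    }
    class_ii_detected = any(
        by_name[n].mhc_class == "II" for n in profile.genotype if n in by_name
    )
    profile.class_ii_functional = bool(class_ii_detected and ciita_rpkm > 0)
    return profile


def balbc_reference_lengths() -> dict[str, int]:
    """Published BALB/c (d-haplotype) allele transcript lengths."""
    return {k: v for k, v in H2_TRANSCRIPT_LENGTHS_NT.items() if k.endswith("d")}
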