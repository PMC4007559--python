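"""Readers and writers for the small set of text formats the pipeline touches.

Conventions match the named standards bit-for-bit: variant positions are
1-based (VCF), gene intervals are 0-based half-open (BED).  Per-replicate
sequencing depths are encoded as repeated sample columns ("T1", "T2", "T3",
"N1", ...), reflecting a triplicate tumor/normal exome design.

All writers emit tab-separated UTF-8 with a single '#'-prefixed header row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "VariantRecord",
    "ProteinRecord",
    "FormatError",
    "read_variants",
    "write_variants",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
]

_NUCS = frozenset("ACGT")
_AA = frozenset("ACDEFGHIKLMNPQRSTVWY*")


class FormatError(ValueError):
    """Malformed input file; message carries the file name and line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: BED-style 0-based half-open genomic interval.

    ``exonic_length_nt`` is the summed exon length used for RPKM
    normalization; ``coding_length_nt`` the protein-coding subset.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    exonic_length_nt: int
    coding_length_nt: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if not 0 < self.exonic_length_nt <= self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: exonic length {self.exonic_length_nt} "
                f"outside (0, {self.end - self.start}]"
            )
        if not 0 <= self.coding_length_nt <= self.exonic_length_nt:
            raise ValueError(f"{self.gene_id}: coding length exceeds exonic length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class VariantRecord:
    """A substitution or anchored indel with per-sample, per-replicate depths.

    ``pos`` is 1-based (VCF convention).  ``depths`` maps a
    ``(sample, replicate)`` pair such as ``("T", 1)`` to
    ``(ref_count, alt_count)``.  Indels are VCF-style left-anchored: ref and
    alt share their first base and have unequal lengths.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depths: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)
    callers: frozenset[str] = frozenset()
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        for s in (self.ref, self.alt):
            if not s or set(s) - _NUCS:
                raise ValueError(f"ref/alt must be non-empty over ACGT, got {s!r}")
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if min(c for d in self.depths.values() for c in d) < 0 if self.depths else False:
            raise ValueError("negative depth")
        object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant irrespective of depths/provenance."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def interval(self) -> tuple[int, int]:
        """0-based half-open genomic footprint: [pos-1, pos-1+len(ref))."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def depth(self, sample: str, replicate: int) -> tuple[int, int]:
        return self.depths[(sample, replicate)]

    def pooled_depth(self, sample: str) -> tuple[int, int]:
        """Sum of (ref, alt) counts over all replicates of ``sample``."""
        pairs = [v for (s, _), v in self.depths.items() if s == sample]
        if not pairs:
            raise KeyError(f"no depths for sample {sample!r}")
        return (sum(p[0] for p in pairs), sum(p[1] for p in pairs))


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence tied to a gene; '*' only terminal unless truncating."""

    protein_id: str
    sequence: str
    gene_id: str = ""
    truncating: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")
        if "*" in self.sequence[:-1] and not self.truncating:
            raise ValueError(f"{self.protein_id}: internal stop without truncating flag")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_TSV_FIXED = ["chrom", "pos", "ref", "alt", "gene_id", "callers"]


def _parse_depth_col(name: str) -> tuple[str, int]:
    """Split a depth column name like 'T1' or 'N12' into (sample, replicate)."""
    i = len(name)
    while i > 0 and name[i - 1].isdigit():
        i -= 1
    if i == 0 or i == len(name):
        raise FormatError(f"depth column {name!r} is not <sample><replicate>")
    return name[:i], int(name[i:])


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read variants from ``path`` in the given dialect.

    Dialects: ``tsv`` (this package's tab-separated layout) or ``vcf_min``
    (VCF 4.x sites with per-sample AD depth fields).  Records come back in
    file order with 1-based positions preserved.  Malformed lines raise
    :class:`FormatError` naming the line number.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf_min":
        return _read_variants_vcf(path)
    raise FormatError(f"unknown variant dialect {dialect!r}")


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if header is None:
                if not line.startswith("#"):
                    raise FormatError(f"{path}:{lineno}: missing '#' header row")
                header = line.lstrip("#").split("\t")
                missing = [c for c in _TSV_FIXED[:4] if c not in header]
                if missing:
                    raise FormatError(f"{path}:{lineno}: header lacks {missing}")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: {len(fields)} fields, header has {len(header)}"
                )
            row = dict(zip(header, fields))
            depths: dict[tuple[str, int], tuple[int, int]] = {}
            for col in header:
                if col in _TSV_FIXED:
                    continue
                val = row[col].strip()
                if not val or val == ".":
                    raise FormatError(
                        f"{path}:{lineno}: missing depth field {col!r} for "
                        f"{row['chrom']}:{row['pos']}"
                    )
                try:
                    r, a = val.split(":")
                    depths[_parse_depth_col(col)] = (int(r), int(a))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: bad depth {val!r} in column {col!r}"
                    ) from exc
            try:
                rec = VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"].upper(),
                    alt=row["alt"].upper(),
                    depths=depths,
                    callers=frozenset(
                        c for c in row.get("callers", "").split(",") if c
                    ),
                    gene_id=row.get("gene_id") or None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if header is None:
        raise FormatError(f"{path}: empty file, expected '#' header")
    return records


def write_variants(
    records: Sequence[VariantRecord], path: str | Path, dialect: str = "tsv"
) -> None:
    path = Path(path)
    if dialect == "vcf_min":
        _write_variants_vcf(records, path)
        return
    if dialect != "tsv":
        raise FormatError(f"unknown variant dialect {dialect!r}")
    depth_cols = sorted(
        {k for r in records for k in r.depths}, key=lambda k: (k[0], k[1])
    )
    col_names = [f"{s}{i}" for s, i in depth_cols]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_TSV_FIXED + col_names) + "\n")
        for r in records:
            row = [
                r.chrom,
                str(r.pos),
                r.ref,
                r.alt,
                r.gene_id or "",
                ",".join(sorted(r.callers)),
            ]
            for k in depth_cols:
                ref_c, alt_c = r.depths[k]
                row.append(f"{ref_c}:{alt_c}")
            fh.write("\t".join(row) + "\n")


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for n, rec in enumerate(vf, 1):
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record {n} ({rec.chrom}:{rec.pos}) must have exactly "
                    "one ALT allele"
                )
            depths: dict[tuple[str, int], tuple[int, int]] = {}
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    raise FormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {s} lacks AD"
                    )
                depths[_parse_depth_col(s)] = (int(ad[0]), int(ad[1]))
            callers = rec.info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            gene = rec.info.get("GENE")
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alt=rec.alts[0].upper(),
                    depths=depths,
                    callers=frozenset(callers),
                    gene_id=gene,
                )
            )
    return records


def _write_variants_vcf(records: Sequence[VariantRecord], path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    contigs = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    for c in contigs:
        header.contigs.add(c)
    header.info.add("CALLERS", ".", "String", "Callers reporting this variant")
    header.info.add("GENE", "1", "String", "Overlapping gene id")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    depth_cols = sorted(
        {k for r in records for k in r.depths}, key=lambda k: (k[0], k[1])
    )
    for s, i in depth_cols:
        header.add_sample(f"{s}{i}")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            if r.callers:
                rec.info["CALLERS"] = tuple(sorted(r.callers))
            if r.gene_id:
                rec.info["GENE"] = r.gene_id
            for k in depth_cols:
                rec.samples[f"{k[0]}{k[1]}"]["AD"] = r.depths[k]
            out.write(rec)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ``[(name, SEQUENCE), ...]`` preserving order.

    Sequences are upper-cased with whitespace stripped (SeqIO handles
    wrapped lines).  Duplicate identifiers raise an error listing them.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    seen: dict[str, int] = {}
    dups = []
    for name, _ in records:
        seen[name] = seen.get(name, 0) + 1
        if seen[name] == 2:
            dups.append(name)
    if dups:
        raise FormatError(f"{path}: duplicate FASTA identifiers: {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# gene tables (BED-like)
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# replicate count tables (gene_id, T1..Tk, N1..Nk)
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a replicate count TSV into {column -> {gene_id -> count}}.

    Columns after ``gene_id`` are per-replicate samples like T1..T3, N1..N3.
    """
    path = Path(path)
    out: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if header is None:
                if not line.startswith("#"):
                    raise FormatError(f"{path}:{lineno}: missing '#' header row")
                header = line.lstrip("#").split("\t")
                if header[0] != "gene_id":
                    raise FormatError(f"{path}:{lineno}: first column must be gene_id")
                out = {c: {} for c in header[1:]}
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: column count mismatch")
            for col, val in zip(header[1:], fields[1:]):
                try:
                    out[col][fields[0]] = int(val)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad count {val!r}") from exc
    if header is None:
        raise FormatError(f"{path}: empty file, expected '#' header")
    return out


def write_count_table(columns: dict[str, dict[str, int]], path: str | Path) -> None:
    names = list(columns)
    genes = list(columns[names[0]])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\t" + "\t".join(names) + "\n")
        for g in genes:
            fh.write(g + "\t" + "\t".join(str(columns[c][g]) for c in names) + "\n")


_GENE_COLS = ["chrom", "start", "end", "gene_id", "exonic_length", "coding_length", "strand"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a BED-like gene table: chrom start end gene_id exonic coding strand."""
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_GENE_COLS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_GENE_COLS)} columns, got "
                    f"{len(fields)}"
                )
            try:
                gene = GeneModel(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    exonic_length_nt=int(fields[4]),
                    coding_length_nt=int(fields[5]),
                    strand=fields[6],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_GENE_COLS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        str(g.exonic_length_nt),
                        str(g.coding_length_nt),
                        g.strand,
                    ]
                )
                + "\n"
            )
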