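"""Published reference values for the CT26 / BALB/cJ tumor-normal pair.

CT26 is a chemically induced (NMU) BALB/c colon carcinoma cell line, one
of the most widely used syngeneic mouse tumor models.  This module bundles
the small published summary tables for that characterization — the gp70
envelope-glycoprotein variant calls obtained from deep RNA coverage, the
cancer-testis antigen expression table, example neoepitopes, and the
headline mutation counts — as plain data for worked examples, validation
and report annotation.  Nothing here is computed; these are literature
values for the CT26 system.
"""

from __future__ import annotations

from .io_formats import VariantRecord

# Headline CT26 exome counts (mm9 reference, CCDS coding space).
SNV_TOTAL = 3023               # high-confidence exonic SNVs
SNV_CODING = 2394              # of which in coding sequence
SNV_NONSYNONYMOUS = 1688       # missense + nonsense
SNV_MISSENSE = 1620
SNV_NONSENSE = 68
SNV_TRANSITIONS = 2313
SNV_C_TO_T = 1980              # C>T/G>A transitions
SNV_HOMOZYGOUS = 296
INDEL_TOTAL = 362
CODING_NT = 32_000_000         # protein-encoding nucleotides in the mouse genome
MEAN_EXOME_COVERAGE = 170

# Expression/binding prioritization cascade sizes for the 3,023 SNVs.
CASCADE_EXPRESSED = 1172
CASCADE_STRONG_BINDER = 154
CASCADE_HIGH_EXPRESSION = 73

# gp70 (MuLV envelope) variants relative to mm9, called from RNA reads at
# >5,000x coverage; the locus lies in a tetraploid region, negative strand.
# Fields: (mm9 coordinate, ref, alt, zygosity, aa_change)
GP70_VARIANTS: list[tuple[str, str, str, str, str]] = [
    ("chr8:125952138", "T", "A", "homozygous", "S>T"),
    ("chr8:125951873", "G", "A", "heterozygous", "W>*"),
    ("chr8:125951822", "A", "G", "heterozygous", "Y>C"),
    ("chr8:125951717", "G", "A", "heterozygous", "W>*"),
    ("chr8:125951634", "G", "A", "homozygous", "E>K"),
    ("chr8:125951556", "G", "T", "heterozygous", "G>*"),
    ("chr8:125951208", "G", "A", "homozygous", "G>S"),
    ("chr8:125950710", "G", "A", "heterozygous", "E>L"),
    ("chr8:125950284", "G", "A", "heterozygous", "G>R"),
]

# Cancer-testis antigen expression (RPKM) in CT26 vs normal mouse colon.
# Fields: gene -> (ct_antigen_id, tumor_rpkm, colon_rpkm)
CT_ANTIGEN_TABLE: dict[str, tuple[str, float, float]] = {
    "Atad2": ("CT137", 42.4, 0.5),
    "Casc5": ("CT29", 10.2, 0.1),
    "Cep55": ("CT111", 25.4, 0.4),
    "Ctage5": ("CT21", 17.7, 1.8),
    "Dcaf12": ("CT102", 11.4, 7.8),
    "Pbk": ("CT84", 39.6, 1.0),
    "Rqcd1": ("CT129", 30.4, 5.4),
    "Spag9": ("CT89", 14.7, 1.2),
    "Ttk": ("CT96", 13.1, 0.3),
}
GP70_EXPRESSION = (7225.4, 0.0)  # (CT26 RPKM, colon RPKM); highest-expressed gene

# Example CT26 neoepitopes: expressed missense mutations whose best
# class I epitope has a consensus percentile rank <= 1%.
# Fields: (gene, aa_change, epitope, allele)
NEOEPITOPE_EXAMPLES: list[tuple[str, str, str, str]] = [
    ("Csnk1g3", "N42K", "VGPKFRVGKK", "H-2Dd"),
    ("E2f8", "I522T", "TYLQPAQAQM", "H-2Kd"),
    ("Fam111a", "G213E", "CVYGFKEETI", "H-2Dd"),
    ("Hdac2", "P228S", "KYYAVNFM", "H-2Kd"),
    ("Nudt19", "L335F", "IYMTFPSENK", "H-2Kd"),
    ("Phf3", "G1814E", "FPPQNMFEF", "H-2Dd"),
    ("Smc3", "D733A", "KFKASRASI", "H-2Kd"),
]

BALBC_CLASS_I = ("H-2Dd", "H-2Kd", "H-2Ld")
BALBC_CLASS_II = ("H-2Iad",)


def gp70_variant_records() -> list[VariantRecord]:
    """The gp70 variant table as parsed :class:`VariantRecord` objects."""
    out = []
    for coord, ref, alt, _zyg, _aa in GP70_VARIANTS:
        chrom, pos = coord.split(":")
        out.append(
            VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt, gene_id="gp70")
        )
    return out


def gp70_true_vafs() -> list[float]:
    """Idealized allele fractions implied by each gp70 zygosity call."""
    return [1.0 if z == "homozygous" else 0.5 for *_xs, z, _aa in GP70_VARIANTS]
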