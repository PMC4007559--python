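"""Ground-truthed synthetic tumor/normal data generator.

Emulates the statistical structure a triplicate tumor/normal exome +
RNA-seq characterization assumes, at desk scale:

* a segmental integer copy-number landscape (contiguous runs of genes
  share a copy state; mostly triploid/tetraploid with a small amplified
  tail, echoing a high-ploidy carcinoma);
* Poisson read counts proportional to gene length and, in the tumor, to
  copy number (at a fixed sequencing budget, so the tumor/normal ratio is
  c / mean-ploidy);
* somatic variants whose alt counts are binomial at the discrete allele
  fractions m/c, plus sequencing-error artifact sites with alt counts
  binomial at the error rate, injected inconsistently across callers;
* log-normal gene expression with a zero-inflation mass, calibrated so
  10 RPKM sits near the 80th percentile of all genes;
* random proteomes carrying the missense mutations, with cascade tiers
  computed from the toy binding predictor;
* 50 nt RNA reads drawn uniformly from known MHC allele sequences.

Everything is deterministic for a fixed seed (NumPy PCG64 generators,
seeded per stage), and every emitted file parses through
:mod:`immunoprofiler.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .io_formats import GeneModel, ProteinRecord, VariantRecord
from .mhc_quant import H2_TRANSCRIPT_LENGTHS_NT, MhcAllele
from .neoepitope import (
    AMINO_ACIDS,
    NeoepitopeCandidate,
    ToyPwmPredictor,
    best_epitope,
    enumerate_mutant_peptides,
    prioritize_cascade,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_exome_counts",
    "simulate_variants",
    "simulate_expression_and_proteome",
    "simulate_mhc_reads",
    "synthetic_mhc_reference",
    "simulate_all",
    "write_simulation",
]

CALLERS = ("samtools", "mutect", "somaticsniper")

# Default copy-state proportions: mostly triploid/tetraploid with a small
# amplified tail (median 3, mean ~3.5 across genes).
DEFAULT_CN_STATES: dict[int, float] = {
    2: 0.10,
    3: 0.45,
    4: 0.39,
    5: 0.02,
    6: 0.02,
    7: 0.01,
    8: 0.01,
}

# Default pyrimidine-strand substitution-class probabilities: strongly
# transition-dominated (~77%), mostly C>T, as in an alkylating-agent-
# induced tumor.
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "C>T": 0.655,
    "T>C": 0.110,
    "C>A": 0.05875,
    "C>G": 0.05875,
    "T>A": 0.05875,
    "T>G": 0.05875,
}

_PAIRS_BY_CLASS = {
    "C>A": [("C", "A"), ("G", "T")],
    "C>G": [("C", "G"), ("G", "C")],
    "C>T": [("C", "T"), ("G", "A")],
    "T>A": [("T", "A"), ("A", "T")],
    "T>C": [("T", "C"), ("A", "G")],
    "T>G": [("T", "G"), ("A", "C")],
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic tumor.

    Defaults mirror a triplicate 170x tumor/normal exome design on a
    high-ploidy tumor; sizes are desk-scale.
    """

    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 19
    cn_states: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CN_STATES))
    segment_genes: int = 50          # mean genes per copy-number segment
    mean_depth: float = 170.0        # mean per-base exome coverage (pooled)
    read_len: int = 50
    n_replicates: int = 3
    snv_count: int = 300
    error_site_count: int = 100
    error_rate: float = 1e-3
    artifact_cell_prob: float = 0.7  # chance an artifact enters a caller/replicate cell
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    expr_mu: float = 0.95            # log-normal location of nonzero RPKMs
    expr_sigma: float = 2.0
    zero_inflation: float = 0.2      # mass of exactly-zero expression
    protein_len_min: int = 60
    protein_len_max: int = 600
    mhc_alleles: tuple[str, ...] = ("H-2Dd", "H-2Kd", "H-2Ld")
    mhc_read_count: int = 2000
    mhc_read_error: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.cn_states.values()) - 1.0) > 1e-9:
            raise ValueError("cn_states proportions must sum to 1")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if min(self.cn_states) < 0 or self.n_genes <= 0:
            raise ValueError("invalid counts")


@dataclass
class GroundTruth:
    gene_cn: dict[str, int] = field(default_factory=dict)
    # variant key -> dict(m, c, somatic, vaf, substitution_class, flank5, flank3)
    variants: dict = field(default_factory=dict)
    rpkm: dict[str, float] = field(default_factory=dict)
    mhc_genotype: set[str] = field(default_factory=set)
    tiers: dict[str, frozenset] = field(default_factory=dict)

    @property
    def mean_ploidy(self) -> float:
        return float(np.mean(list(self.gene_cn.values())))


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    # independent, documented per-stage streams from one master seed
    offsets = {
        "genome": 1,
        "counts": 2,
        "variants": 3,
        "expression": 4,
        "mhc": 5,
    }
    return np.random.default_rng((config.seed * 1000 + offsets[stage]) % (2**31))


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Gene models plus a segmental true copy-number per gene.

    Per-state gene quotas are allocated by largest remainder so realized
    frequencies match the configured proportions to within rounding; each
    quota is split into contiguous segments (mean ``segment_genes`` genes)
    whose order along the genome is shuffled.
    """
    rng = _rng(config, "genome")
    n = config.n_genes
    states = sorted(config.cn_states)
    quotas = {s: int(np.floor(config.cn_states[s] * n)) for s in states}
    remainder = n - sum(quotas.values())
    frac = sorted(
        states, key=lambda s: config.cn_states[s] * n - quotas[s], reverse=True
    )
    for s in frac[:remainder]:
        quotas[s] += 1

    segments: list[tuple[int, int]] = []  # (state, n_genes)
    for s in states:
        left = quotas[s]
        while left > 0:
            size = min(left, max(1, int(rng.geometric(1.0 / config.segment_genes))))
            segments.append((s, size))
            left -= size
    order = rng.permutation(len(segments))
    genes: list[GeneModel] = []
    cn: dict[str, int] = {}
    per_chrom = int(np.ceil(n / config.n_chromosomes))
    idx = 0
    for seg_i in order:
        state, size = segments[seg_i]
        for _ in range(size):
            chrom = f"chr{idx // per_chrom + 1}"
            within = idx % per_chrom
            start = within * 20000
            exonic = int(rng.integers(500, 5001))
            gid = f"g{idx:05d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    start=start,
                    end=start + max(exonic, 10000),
                    exonic_length_nt=exonic,
                    coding_length_nt=int(exonic * 0.8),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            cn[gid] = state
            idx += 1
    return genes, cn


def simulate_exome_counts(
    genes: list[GeneModel],
    cn: dict[str, int],
    config: SimulationConfig,
) -> dict[str, dict[str, int]]:
    """Per-replicate Poisson read counts for tumor and normal libraries.

    Normal: lambda_g = depth * len_g / read_len (split over replicates).
    Tumor: the same budgeted library, re-weighted by c_g / mean-ploidy, so
    genome-wide tumor output matches the normal library while per-gene
    depth tracks copy number.
    """
    rng = _rng(config, "counts")
    mean_ploidy = float(np.mean([cn[g.gene_id] for g in genes]))
    out: dict[str, dict[str, int]] = {}
    for rep in range(1, config.n_replicates + 1):
        t_col: dict[str, int] = {}
        n_col: dict[str, int] = {}
        for g in genes:
            lam = (
                config.mean_depth
                * g.exonic_length_nt
                / config.read_len
                / config.n_replicates
            )
            n_col[g.gene_id] = int(rng.poisson(lam))
            t_col[g.gene_id] = int(
                rng.poisson(lam * cn[g.gene_id] / mean_ploidy) if mean_ploidy > 0 else 0
            )
        out[f"T{rep}"] = t_col
        out[f"N{rep}"] = n_col
    return out


def _draw_substitution(rng: np.random.Generator, config: SimulationConfig):
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes])
    cls = classes[int(rng.choice(len(classes), p=probs))]
    ref, alt = _PAIRS_BY_CLASS[cls][int(rng.integers(2))]
    flank5, flank3 = (
        "ACGT"[int(rng.integers(4))],
        "ACGT"[int(rng.integers(4))],
    )
    return cls, ref, alt, flank5, flank3


def simulate_variants(
    genes: list[GeneModel],
    cn: dict[str, int],
    config: SimulationConfig,
) -> tuple[list[VariantRecord], dict[tuple[str, int], set], GroundTruth]:
    """Somatic variants plus error artifacts, as multi-caller call sets.

    True somatic variants draw a multiplicity m ~ Uniform{1..c}, tumor alt
    counts ~ Binom(d, m/c), and appear in every caller/replicate call set.
    Artifact sites draw alt counts ~ Binom(d, error_rate) and enter each
    call-set cell independently with probability ``artifact_cell_prob``.
    """
    rng = _rng(config, "variants")
    eligible = [g for g in genes if cn[g.gene_id] >= 1]
    truth = GroundTruth(gene_cn=dict(cn))
    variants: list[VariantRecord] = []
    call_sets: dict[tuple[str, int], set] = {
        (caller, rep): set()
        for caller in CALLERS
        for rep in range(1, config.n_replicates + 1)
    }
    used_pos: set[tuple[str, int]] = set()

    def _depths(vaf: float) -> dict[tuple[str, int], tuple[int, int]]:
        depths = {}
        for rep in range(1, config.n_replicates + 1):
            d_t = int(rng.poisson(config.mean_depth / config.n_replicates))
            a_t = int(rng.binomial(d_t, vaf)) if d_t > 0 else 0
            d_n = int(rng.poisson(config.mean_depth / config.n_replicates))
            a_n = int(rng.binomial(d_n, config.error_rate)) if d_n > 0 else 0
            depths[("T", rep)] = (d_t - a_t, a_t)
            depths[("N", rep)] = (d_n - a_n, a_n)
        return depths

    def _new_site(g: GeneModel) -> tuple[str, int]:
        while True:
            pos = int(rng.integers(g.start + 1, g.end + 1))
            if (g.chrom, pos) not in used_pos:
                used_pos.add((g.chrom, pos))
                return g.chrom, pos

    for _ in range(config.snv_count):
        g = eligible[int(rng.integers(len(eligible)))]
        c = cn[g.gene_id]
        m = int(rng.integers(1, c + 1))
        cls, ref, alt, f5, f3 = _draw_substitution(rng, config)
        chrom, pos = _new_site(g)
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            depths=_depths(m / c),
            callers=frozenset(CALLERS),
            gene_id=g.gene_id,
        )
        variants.append(rec)
        truth.variants[rec.key] = {
            "somatic": True,
            "m": m,
            "c": c,
            "vaf": m / c,
            "substitution_class": cls,
            "flank5": f5,
            "flank3": f3,
            "gene_id": g.gene_id,
        }
        for cell in call_sets:
            call_sets[cell].add(rec.key)

    for _ in range(config.error_site_count):
        g = eligible[int(rng.integers(len(eligible)))]
        cls, ref, alt, f5, f3 = _draw_substitution(rng, config)
        chrom, pos = _new_site(g)
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            depths=_depths(config.error_rate),
            callers=frozenset(CALLERS),
            gene_id=g.gene_id,
        )
        variants.append(rec)
        truth.variants[rec.key] = {
            "somatic": False,
            "m": 0,
            "c": cn[g.gene_id],
            "vaf": config.error_rate,
            "substitution_class": cls,
            "flank5": f5,
            "flank3": f3,
            "gene_id": g.gene_id,
        }
        for cell in call_sets:
            if rng.random() < config.artifact_cell_prob:
                call_sets[cell].add(rec.key)
    return variants, call_sets, truth


def simulate_expression_and_proteome(
    variants: list[VariantRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    *,
    rank_max: float = 1.0,
    high_expr: float = 10.0,
) -> dict:
    """Expression, mutated proteomes and the true prioritization tiers.

    Gene RPKM ~ LogNormal(mu, sigma) with a zero-inflation point mass;
    every somatic variant's gene gets a random protein carrying a missense
    substitution, and the true cascade tier of each variant is computed
    with the deterministic toy predictor (so pipeline recovery can be
    checked exactly).
    """
    rng = _rng(config, "expression")
    somatic = [v for v in variants if truth.variants[v.key]["somatic"]]
    genes = sorted({truth.variants[v.key]["gene_id"] for v in somatic})
    for gid in sorted(truth.gene_cn):
        if rng.random() < config.zero_inflation:
            truth.rpkm[gid] = 0.0
        else:
            truth.rpkm[gid] = float(
                np.exp(rng.normal(config.expr_mu, config.expr_sigma))
            )

    aas = np.array(list(AMINO_ACIDS))
    proteins: dict[str, ProteinRecord] = {}
    mutations = []  # (variant_key, gene_id, protein_id, mut_pos, wt_aa, mut_aa)
    for gid in genes:
        length = int(rng.integers(config.protein_len_min, config.protein_len_max + 1))
        seq = "".join(rng.choice(aas, size=length))
        proteins[gid] = ProteinRecord(protein_id=f"{gid}_p1", sequence=seq, gene_id=gid)
    for v in somatic:
        gid = truth.variants[v.key]["gene_id"]
        prot = proteins[gid]
        pos = int(rng.integers(1, len(prot.sequence) + 1))
        wt = prot.sequence[pos - 1]
        mut = wt
        while mut == wt:
            mut = str(rng.choice(aas))
        mutations.append((v.key, gid, prot.protein_id, pos, wt, mut))
        truth.variants[v.key]["aa_change"] = f"{wt}{pos}{mut}"

    predictor = ToyPwmPredictor()
    best_ranks: dict = {}
    best_eps: dict = {}
    for key, gid, pid, pos, wt, mut in mutations:
        cands = [
            NeoepitopeCandidate(
                gene_id=gid,
                aa_change=f"{wt}{pos}{mut}",
                peptide=p,
                wildtype_peptide=w,
                mut_offset=off,
            )
            for p, w, off in enumerate_mutant_peptides(proteins[gid], pos, mut)
        ]
        ep = best_epitope(cands, list(config.mhc_alleles), predictor)
        best_ranks[key] = ep.percentile_rank
        best_eps[key] = ep
    gene_of = {key: gid for key, gid, *_rest in mutations}
    tiers = prioritize_cascade(
        [m[0] for m in mutations],
        gene_of,
        truth.rpkm,
        best_ranks,
        rank_max=rank_max,
        high_expr=high_expr,
    )
    truth.tiers = {name: t.members for name, t in tiers.items()}
    return {
        "expression": dict(truth.rpkm),
        "proteins": proteins,
        "mutations": mutations,
        "best_epitopes": best_eps,
        "best_ranks": best_ranks,
        "tiers": tiers,
    }


def synthetic_mhc_reference(
    seed: int = 7, names: tuple[str, ...] | None = None
) -> list[MhcAllele]:
    """Synthetic stand-in MHC allele reference (random sequences).

    Real H-2 allele transcripts are not bundled; these are random
    nucleotide sequences with the published per-allele transcript lengths,
    adequate for read-assignment simulations.
    """
    rng = np.random.default_rng(seed)
    names = names or tuple(H2_TRANSCRIPT_LENGTHS_NT)
    nts = np.array(list("ACGT"))
    out = []
    for name in names:
        seq = "".join(rng.choice(nts, size=H2_TRANSCRIPT_LENGTHS_NT[name]))
        out.append(MhcAllele.from_fasta_record(name, seq))
    return out


def simulate_mhc_reads(
    config: SimulationConfig,
    reference: list[MhcAllele],
    *,
    weights: dict[str, float] | None = None,
) -> tuple[list[str], set[str]]:
    """Uniform random 50 nt substrings of the configured alleles.

    Half the reads are reverse-complemented; an optional per-base error
    rate introduces random substitutions.  Returns (reads, true genotype).
    """
    rng = _rng(config, "mhc")
    by_name = {al.name: al for al in reference}
    chosen = [by_name[n] for n in config.mhc_alleles]
    if weights is None:
        w = np.ones(len(chosen)) / len(chosen)
    else:
        w = np.array([weights[a.name] for a in chosen], dtype=float)
        w = w / w.sum()
    comp = str.maketrans("ACGT", "TGCA")
    reads = []
    for _ in range(config.mhc_read_count):
        al = chosen[int(rng.choice(len(chosen), p=w))]
        start = int(rng.integers(0, len(al.sequence) - config.read_len + 1))
        read = al.sequence[start : start + config.read_len]
        if config.mhc_read_error > 0:
            bases = list(read)
            for i in range(len(bases)):
                if rng.random() < config.mhc_read_error:
                    bases[i] = "ACGT"[int(rng.integers(4))]
            read = "".join(bases)
        if rng.random() < 0.5:
            read = read.translate(comp)[::-1]
        reads.append(read)
    return reads, {a.name for a in chosen}


def simulate_all(config: SimulationConfig) -> dict:
    """Run every stage; returns all artifacts plus the consolidated truth."""
    genes, cn = simulate_genome(config)
    counts = simulate_exome_counts(genes, cn, config)
    variants, call_sets, truth = simulate_variants(genes, cn, config)
    expr = simulate_expression_and_proteome(variants, truth, config)
    reference = synthetic_mhc_reference(seed=(config.seed * 7919 + 11) % (2**31))
    reads, genotype = simulate_mhc_reads(config, reference)
    truth.mhc_genotype = genotype
    return {
        "config": config,
        "genes": genes,
        "counts": counts,
        "variants": variants,
        "call_sets": call_sets,
        "expression": expr,
        "mhc_reference": reference,
        "mhc_reads": reads,
        "truth": truth,
    }


def write_simulation(sim: dict, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact in the input formats the pipeline stages read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.tsv"
    io_formats.write_gene_table(sim["genes"], paths["genes"])

    paths["counts"] = outdir / "exome_counts.tsv"
    io_formats.write_count_table(sim["counts"], paths["counts"])

    paths["variants"] = outdir / "variants.tsv"
    io_formats.write_variants(sim["variants"], paths["variants"], dialect="tsv")

    for (caller, rep), keys in sim["call_sets"].items():
        p = outdir / f"calls_{caller}_{rep}.tsv"
        recs = [v for v in sim["variants"] if v.key in keys]
        io_formats.write_variants(recs, p, dialect="tsv")
        paths[f"calls_{caller}_{rep}"] = p

    expr = sim["expression"]
    paths["expression"] = outdir / "expression.tsv"
    with open(paths["expression"], "w", encoding="utf-8") as fh:
        fh.write("#gene_id\trpkm\n")
        for gid in sorted(expr["expression"]):
            fh.write(f"{gid}\t{expr['expression'][gid]:.6g}\n")

    paths["proteins"] = outdir / "proteins.fasta"
    io_formats.write_fasta(
        [(p.protein_id, p.sequence) for p in expr["proteins"].values()],
        paths["proteins"],
    )

    paths["mutations"] = outdir / "protein_mutations.tsv"
    with open(paths["mutations"], "w", encoding="utf-8") as fh:
        fh.write("#chrom\tpos\tref\talt\tgene_id\tprotein_id\taa_change\n")
        for key, gid, pid, pos, wt, mut in expr["mutations"]:
            chrom, vpos, ref, alt = key
            fh.write(f"{chrom}\t{vpos}\t{ref}\t{alt}\t{gid}\t{pid}\t{wt}{pos}{mut}\n")

    paths["mhc_reference"] = outdir / "mhc_reference.fasta"
    io_formats.write_fasta(
        [(al.name, al.sequence) for al in sim["mhc_reference"]], paths["mhc_reference"]
    )
    paths["mhc_reads"] = outdir / "mhc_reads.fasta"
    io_formats.write_fasta(
        [(f"read{i:06d}", r) for i, r in enumerate(sim["mhc_reads"])],
        paths["mhc_reads"],
    )

    truth = sim["truth"]
    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("#record\tkey\tvalue\n")
        for gid in sorted(truth.gene_cn):
            fh.write(f"gene_cn\t{gid}\t{truth.gene_cn[gid]}\n")
        for key, info in truth.variants.items():
            k = f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"
            fh.write(
                f"variant\t{k}\t"
                f"somatic={int(info['somatic'])};m={info['m']};c={info['c']}\n"
            )
        for gid in sorted(truth.rpkm):
            fh.write(f"rpkm\t{gid}\t{truth.rpkm[gid]:.6g}\n")
        for name in sorted(truth.mhc_genotype):
            fh.write(f"mhc_genotype\t{name}\t1\n")
        for tier, members in truth.tiers.items():
            for key in sorted(members):
                k = f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"
                fh.write(f"tier_{tier}\t{k}\t1\n")
    return paths
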