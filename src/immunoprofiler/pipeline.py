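"""End-to-end characterization: wire the stages together over files.

Given a directory of inputs (as written by :func:`synthetic_tumor.write_simulation`
or assembled from real data in the same formats), run copy number,
somatic filtering, mutation spectrum, expression, MHC typing and
neoepitope prioritization, and write one TSV per result plus a plain-text
summary.  Outputs are byte-identical across reruns of the same inputs;
timing goes to a sidecar log.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from . import io_formats
from .copy_number import (
    cn_summary,
    fit_ploidy_model,
    infer_copy_number,
    infer_zygosity,
    normalized_ratio,
)
from .expression import ct_antigen_filter, expression_percentile
from .io_formats import ProteinRecord
from .mhc_quant import MhcAllele, assign_reads, call_genotype, quantify
from .mutation_spectrum import spectrum_summary, substitution_class
from .neoepitope import (
    NeoepitopeCandidate,
    ToyPwmPredictor,
    best_epitope,
    enumerate_mutant_peptides,
    prioritize_cascade,
)
from .somatic_filters import FilterParams, filter_snvs

__all__ = ["RunConfig", "StageFailure", "run_characterization"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for a full characterization run.

    Only ``genes``, ``counts`` and the variant inputs are mandatory;
    expression/protein/MHC stages are skipped with a notice when their
    inputs are absent.
    """

    outdir: Path
    genes: Path | None = None
    counts: Path | None = None
    variants: Path | None = None
    calls_dir: Path | None = None
    expression: Path | None = None
    proteins: Path | None = None
    protein_mutations: Path | None = None
    mhc_reference: Path | None = None
    mhc_reads: Path | None = None
    antigen_list: tuple[str, ...] = ()
    normal_expression: Path | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    purity: float = 1.0
    c_max: int = 8
    rank_max: float = 1.0
    high_expr: float = 10.0
    detect_rpkm: float = 1.0
    ciita_rpkm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "genes",
            "counts",
            "variants",
            "calls_dir",
            "expression",
            "proteins",
            "protein_mutations",
            "mhc_reference",
            "mhc_reads",
            "normal_expression",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p} does not exist")


def _read_expression_tsv(path: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if header is None:
                header = line.lstrip("#").split("\t")
                continue
            gid, val = line.split("\t")[:2]
            out[gid] = float(val)
    return out


def _load_call_sets(calls_dir: Path) -> dict[tuple[str, int], set]:
    pattern = re.compile(r"calls_(?P<caller>[A-Za-z0-9]+)_(?P<rep>\d+)\.tsv$")
    call_sets: dict[tuple[str, int], set] = {}
    for p in sorted(Path(calls_dir).iterdir()):
        m = pattern.search(p.name)
        if not m:
            continue
        recs = io_formats.read_variants(p, dialect="tsv")
        call_sets[(m["caller"], int(m["rep"]))] = {r.key for r in recs}
    if not call_sets:
        raise FileNotFoundError(f"no calls_<caller>_<rep>.tsv files in {calls_dir}")
    return call_sets


def run_characterization(config: RunConfig, log=None) -> dict:
    """Run all available stages; returns a report dict and writes TSVs.

    Any stage failure aborts with :class:`StageFailure` naming the stage;
    partial outputs written so far stay on disk and are listed in the
    summary as partial.
    """
    def _log(msg: str) -> None:
        if log is not None:
            log(msg)

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"skipped": [], "outputs": {}}
    summary_lines: list[str] = []
    class_i_genotype: list[str] = []

    # --- (b1) somatic filtering ------------------------------------------
    # Filtering runs before copy number so the ploidy fit sees only
    # high-confidence somatic allele fractions: unfiltered artifact sites
    # have near-zero VAFs that fit no discrete m/c state and bias the
    # scale search.
    passed = []
    verdicts = []
    if config.variants and config.calls_dir:
        try:
            all_variants = io_formats.read_variants(config.variants, dialect="tsv")
            call_sets = _load_call_sets(config.calls_dir)
            verdicts = filter_snvs(
                [v for v in all_variants if v.is_snv], call_sets, config.filter_params
            )
            passed = [v.variant for v in verdicts if v.passed]
            _log("stage somatic done")
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise StageFailure("somatic_filters", exc)
    elif config.variants:
        # no call sets: take the variant table as already-filtered
        passed = [
            v
            for v in io_formats.read_variants(config.variants, dialect="tsv")
            if v.is_snv
        ]

    # --- (a) copy number -------------------------------------------------
    cn_calls = {}
    model = None
    if config.genes and config.counts:
        try:
            genes = io_formats.read_gene_table(config.genes)
            counts = io_formats.read_count_table(config.counts)
            t_cols = sorted(c for c in counts if c.startswith("T"))
            n_cols = sorted(c for c in counts if c.startswith("N"))
            tumor = {
                g.gene_id: sum(counts[c][g.gene_id] for c in t_cols) for g in genes
            }
            normal = {
                g.gene_id: sum(counts[c][g.gene_id] for c in n_cols) for g in genes
            }
            ratios = normalized_ratio(tumor, normal)

            vaf_obs: list[tuple[int, int, str]] = []
            for v in passed:
                ref_t, alt_t = v.pooled_depth("T")
                if ref_t + alt_t > 0 and v.gene_id:
                    vaf_obs.append((alt_t, ref_t + alt_t, v.gene_id))
            model = fit_ploidy_model(
                ratios, vaf_obs or None, c_max=config.c_max, purity=config.purity
            )
            cn_calls = {
                dr.gene_id: infer_copy_number(dr, model) for dr in ratios
            }
            summ = cn_summary(list(cn_calls.values()))
            p = outdir / "copy_number.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("#gene_id\tc\tresidual\tamplified_beyond_model\n")
                for gid in sorted(cn_calls):
                    call = cn_calls[gid]
                    fh.write(
                        f"{gid}\t{'' if call.c is None else call.c}\t"
                        f"{call.fit_residual:.6g}\t{int(call.amplified_beyond_model)}\n"
                    )
            p2 = outdir / "copy_number_histogram.tsv"
            with open(p2, "w", encoding="utf-8") as fh:
                fh.write("#c\tn_genes\n")
                for c, n in summ["histogram"].items():
                    fh.write(f"{c}\t{n}\n")
            report["outputs"]["copy_number"] = p
            report["copy_number_summary"] = summ
            report["ploidy_model"] = model
            summary_lines += [
                f"copy number: scale s={model.s:.2f}, median c={summ['median']:g}, "
                f"mean c={summ['mean']:.2f} over {summ['n']} genes",
            ]
            _log("stage cnv done")
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise StageFailure("copy_number", exc)
    else:
        report["skipped"].append("copy_number")

    # --- (b2) somatic verdicts + zygosity --------------------------------
    if verdicts:
        try:
            p = outdir / "somatic_verdicts.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("#chrom\tpos\tref\talt\tpassed\treasons\n")
                for v in verdicts:
                    fh.write(
                        f"{v.variant.chrom}\t{v.variant.pos}\t{v.variant.ref}\t"
                        f"{v.variant.alt}\t{int(v.passed)}\t{','.join(v.reasons)}\n"
                    )
            report["outputs"]["somatic_verdicts"] = p
            report["n_high_confidence_snvs"] = len(passed)
            summary_lines.append(
                f"somatic: {len(passed)} of {len(verdicts)} SNVs pass the "
                "consensus+binomial filter chain"
            )

            # zygosity for passing variants, using copy-number calls if present
            if cn_calls and model is not None:
                p = outdir / "zygosity.tsv"
                n_homo = 0
                with open(p, "w", encoding="utf-8") as fh:
                    fh.write("#chrom\tpos\tgene_id\tc\tm\tvaf\tzygosity\n")
                    for v in passed:
                        call = cn_calls.get(v.gene_id or "")
                        if call is None or call.c is None or call.c < 1:
                            continue
                        ref_t, alt_t = v.pooled_depth("T")
                        z = infer_zygosity(v, call.c, alt_t, ref_t + alt_t, model=model)
                        n_homo += z.zygosity == "homozygous"
                        fh.write(
                            f"{v.chrom}\t{v.pos}\t{v.gene_id}\t{z.c}\t{z.m}\t"
                            f"{z.vaf:.4f}\t{z.zygosity}\n"
                        )
                report["outputs"]["zygosity"] = p
                summary_lines.append(f"zygosity: {n_homo} homozygous variants")
            _log("stage somatic done")
        except StageFailure:
            raise
        except Exception as exc:
            raise StageFailure("somatic_filters", exc)
    else:
        report["skipped"].append("somatic_filters")

    if passed:
        try:
            # spectrum from neutral flanks when no reference context is given
            classes = [
                substitution_class(v.ref, v.alt, "A", "A")
                for v in passed
                if v.is_snv
            ]
            spec = spectrum_summary(classes)
            p = outdir / "spectrum.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("#class\tcount\n")
                for k, n in spec["class_counts"].items():
                    fh.write(f"{k}\t{n}\n")
                fh.write(f"transition_fraction\t{spec['transition_fraction']:.4f}\n")
            report["outputs"]["spectrum"] = p
            report["spectrum"] = spec
            summary_lines.append(
                f"spectrum: {spec['transitions']} transitions / {spec['n']} SNVs "
                f"({100 * spec['transition_fraction']:.1f}%)"
            )
        except Exception as exc:
            raise StageFailure("mutation_spectrum", exc)

    # --- (d) expression + CT antigens ------------------------------------
    expr = {}
    if config.expression:
        try:
            expr = _read_expression_tsv(Path(config.expression))
            pct = expression_percentile(list(expr.values()), 10.0)
            summary_lines.append(
                f"expression: {len(expr)} genes, 10 RPKM at the "
                f"{pct:.0f}th percentile"
            )
            report["rpkm10_percentile"] = pct
            if config.antigen_list and config.normal_expression:
                normal = _read_expression_tsv(Path(config.normal_expression))
                sel = ct_antigen_filter(expr, normal, list(config.antigen_list))
                p = outdir / "ct_antigens.tsv"
                with open(p, "w", encoding="utf-8") as fh:
                    fh.write("#gene\ttumor_rpkm\tnormal_rpkm\n")
                    for g in sel:
                        fh.write(f"{g}\t{expr[g]:.4g}\t{normal[g]:.4g}\n")
                report["outputs"]["ct_antigens"] = p
                report["ct_antigens"] = sel
                summary_lines.append(f"CT antigens selected: {len(sel)}")
            _log("stage expr done")
        except Exception as exc:
            raise StageFailure("expression", exc)
    else:
        report["skipped"].append("expression")

    # --- (e) MHC typing ---------------------------------------------------
    if config.mhc_reference and config.mhc_reads:
        try:
            ref = [
                MhcAllele.from_fasta_record(n, s)
                for n, s in io_formats.read_fasta(config.mhc_reference)
            ]
            reads = [s for _n, s in io_formats.read_fasta(config.mhc_reads)]
            profile = assign_reads(reads, ref)
            profile = quantify(profile, ref, total_mapped=max(len(reads), 1))
            profile = call_genotype(
                profile,
                ref,
                detect_rpkm=config.detect_rpkm,
                ciita_rpkm=config.ciita_rpkm,
            )
            p = outdir / "mhc_profile.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("#allele\tclass\tunique_reads\trpkm\tin_genotype\n")
                for al in ref:
                    fh.write(
                        f"{al.name}\t{al.mhc_class}\t"
                        f"{profile.unique_counts[al.name]}\t"
                        f"{profile.rpkm[al.name]:.4g}\t"
                        f"{int(al.name in profile.genotype)}\n"
                    )
            report["outputs"]["mhc_profile"] = p
            report["mhc_profile"] = profile
            class_i_genotype = sorted(
                n
                for n in profile.genotype
                if n in {al.name for al in ref if al.mhc_class == "I"}
            )
            summary_lines.append(
                "mhc: genotype "
                + ",".join(sorted(profile.genotype))
                + f"; class II functional: {profile.class_ii_functional}"
            )
            _log("stage mhc done")
        except Exception as exc:
            raise StageFailure("mhc_quant", exc)
    else:
        report["skipped"].append("mhc_quant")

    # --- (f) neoepitopes ---------------------------------------------------
    if config.proteins and config.protein_mutations and expr:
        try:
            proteins = {
                n: ProteinRecord(protein_id=n, sequence=s)
                for n, s in io_formats.read_fasta(config.proteins)
            }
            muts = []
            with open(config.protein_mutations, encoding="utf-8") as fh:
                header = None
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    if header is None:
                        header = line.lstrip("#").split("\t")
                        continue
                    row = dict(zip(header, line.split("\t")))
                    muts.append(row)
            predictor = ToyPwmPredictor()
            # score against the cell line's own class I type when typed
            alleles = class_i_genotype or ["H-2Dd", "H-2Kd", "H-2Ld"]
            rows = []
            best_ranks = {}
            gene_of = {}
            keys = []
            for row in muts:
                m = re.fullmatch(r"([A-Z*])(\d+)([A-Z*])", row["aa_change"])
                if not m or m.group(3) == "*" or m.group(1) == m.group(3):
                    continue
                key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                keys.append(key)
                gene_of[key] = row["gene_id"]
                prot = proteins[row["protein_id"]]
                cands = [
                    NeoepitopeCandidate(
                        gene_id=row["gene_id"],
                        aa_change=row["aa_change"],
                        peptide=p_,
                        wildtype_peptide=w_,
                        mut_offset=off,
                    )
                    for p_, w_, off in enumerate_mutant_peptides(
                        prot, int(m.group(2)), m.group(3)
                    )
                ]
                ep = best_epitope(cands, alleles, predictor)
                best_ranks[key] = ep.percentile_rank
                rows.append((key, ep))
            tiers = prioritize_cascade(
                keys,
                gene_of,
                expr,
                best_ranks,
                rank_max=config.rank_max,
                high_expr=config.high_expr,
            )
            p = outdir / "neoepitopes.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write(
                    "#gene\tmutation\tepitope\twildtype\tallele\tic50_nm\t"
                    "percentile_rank\texpressed\tbinder\thigh_expression_binder\n"
                )
                for key, ep in sorted(rows, key=lambda r: r[1].percentile_rank):
                    fh.write(
                        f"{ep.gene_id}\t{ep.aa_change}\t{ep.peptide}\t"
                        f"{ep.wildtype_peptide}\t{ep.allele}\t{ep.ic50_nm:.1f}\t"
                        f"{ep.percentile_rank:.2f}\t"
                        f"{int(key in tiers['expressed'].members)}\t"
                        f"{int(key in tiers['binder'].members)}\t"
                        f"{int(key in tiers['high_expression_binder'].members)}\n"
                    )
            report["outputs"]["neoepitopes"] = p
            report["tiers"] = tiers
            tier_counts = {k: len(t.members) for k, t in tiers.items()}
            report["tier_counts"] = tier_counts
            summary_lines.append(
                "neoepitope cascade: "
                + " ; ".join(f"{k}={v}" for k, v in tier_counts.items())
            )
            _log("stage neo done")
        except Exception as exc:
            raise StageFailure("neoepitope", exc)
    else:
        report["skipped"].append("neoepitope")

    if report["skipped"]:
        summary_lines.append("skipped stages: " + ", ".join(report["skipped"]))
    summary = outdir / "summary.txt"
    with open(summary, "w", encoding="utf-8") as fh:
        fh.write("\n".join(summary_lines) + "\n")
    report["outputs"]["summary"] = summary
    report["summary_lines"] = summary_lines
    return report
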