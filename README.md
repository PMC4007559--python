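# immunoprofiler

Tumor/normal "mutanome → immunome" profiling for syngeneic mouse tumor
models such as the CT26 colon carcinoma / BALB/cJ pair: from exome read
counts and multi-caller variant call sets to an integrated map of absolute
copy number, high-confidence somatic mutations, mutation spectrum, gene
expression, MHC type and candidate neoepitopes.

## Who this is for

Groups characterizing a tumor cell line against its matched normal with
triplicate exome and RNA sequencing, who want the downstream analysis —
not the read alignment or the variant callers themselves — as a testable,
scriptable library. Every stage also runs against a ground-truthed
synthetic tumor generator, so the whole pipeline is exercisable without
any sequencing data.

## The models

**Absolute copy number and zygosity.** For gene *g* with tumor/normal
library-normalized depth ratio *r_g = (t_g/T)/(n_g/N)*, a pure tumor with
integer copy number *c_g* satisfies *E[r_g] = c_g · s/2* for one global
scale *s*. Simultaneously, a somatic mutation present on *m* of the *c*
copies has variant allele fraction constrained to the discrete values
*m/c*. The scale is fitted by grid search (s ∈ [0.2, 3.0], step 0.01)
minimizing

```
Σ_g min_c (r_g − c·s/2)²  +  λ Σ_v min_{m≤c(g)} [−log Binom(a_v | d_v, m/c(g))]
```

then *c_g* is the nearest integer state and *m* the binomial
maximum-likelihood multiplicity; *m = c* is a homozygous mutation.

**Somatic filters.** A high-confidence SNV must be called by every caller
in every replicate, its tumor alt count *a* must reject the sequencing
error hypothesis (*P(X ≥ a | Binom(d, e)) ≤ α*, defaults e = 10⁻³,
α = 10⁻⁴), and the matched normal must be deep enough that a germline
heterozygote would have been seen (*P(X ≤ g_a | Binom(d_g, ½)) ≤ β*,
β = 10⁻³). Indels need ≥ 10 supporting tumor reads and zero germline
support.

**Spectrum.** Substitutions collapse onto the pyrimidine strand into six
classes with their 3′ neighbor; coding effects come from codon
translation; rates are reported per Mb of coding sequence.

**Expression and antigens.** RPKM = count / (kb of transcript · millions
of mapped reads). Cancer-testis antigens are selected at tumor RPKM > 10
and normal RPKM < 10.

**MHC and neoepitopes.** RNA reads are assigned to MHC allele reference
transcripts by unique exact substring match (either orientation) and
RPKM-normalized with the published allele transcript lengths; class II
presentation additionally requires the transactivator Ciita. For every
missense mutation, all 8–11-mer peptides containing the mutated residue
are scored against the class I alleles through a pluggable predictor
(a deterministic toy PWM predictor ships; precomputed consensus scores
plug in via a TSV), and mutations are prioritized through the nested
cascade *expressed (RPKM > 0) ⊇ strong binder (consensus percentile ≤ 1%)
⊇ highly expressed binder (RPKM ≥ 10)*.

## Worked example

```sh
profiler simulate --seed 17 --out demo/data
profiler run --indir demo/data --out demo/report
cat demo/report/summary.txt
```

prints (exactly, for seed 17):

```
copy number: scale s=0.58, median c=3, mean c=3.48 over 2000 genes
somatic: 300 of 400 SNVs pass the consensus+binomial filter chain
zygosity: 98 homozygous variants
spectrum: 219 transitions / 300 SNVs (73.0%)
expression: 2000 genes, 10 RPKM at the 80th percentile
mhc: genotype H-2Dd,H-2Kd,H-2Ld; class II functional: False
neoepitope cascade: all=300 ; expressed=215 ; binder=145 ; high_expression_binder=28
```

Reading: the simulated tumor is triploid/tetraploid-heavy (median copy
number 3), the filter chain kept all 300 planted somatic SNVs and
rejected the 100 error artifacts, the transition-dominated spectrum and
the log-normal expression distribution match the configured conditions,
the BALB/c class I type is recovered with no functional class II, and the
expression/binding cascade nests 300 ⊇ 215 ⊇ 145 ⊇ 28. Per-stage TSVs
(`copy_number.tsv`, `somatic_verdicts.tsv`, `zygosity.tsv`,
`spectrum.tsv`, `mhc_profile.tsv`, `neoepitopes.tsv`) sit next to the
summary. The same stages are importable from Python
(`immunoprofiler.copy_number`, `.somatic_filters`, `.mutation_spectrum`,
`.expression`, `.mhc_quant`, `.neoepitope`, `.synthetic_tumor`).

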