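# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Joint copy-number / zygosity model

The tumor sample is modeled as pure (purity 1.0, appropriate for a cell
line) with an integer copy number *c* per gene and a single global scale
*s* relating the library-normalized tumor/normal depth ratio to copy
number: *E[r] = c·s/2*. Depth ratios alone leave *s* unidentifiable — a
genome that is uniformly triploid produces the same ratio profile as a
diploid one — so variant allele fractions are brought in: a somatic
mutation on *m* of *c* copies has expected VAF *m/c*, a discrete set that
differs between candidate ploidies. The fit is a grid search over
s ∈ [0.2, 3.0] in steps of 0.01 minimizing the sum of squared depth
residuals plus λ (default 1.0) times the best-case binomial negative
log-likelihood of each variant's alt count. Remaining ties (e.g. an
exactly uniform genome) are broken toward the scale closest to 1.0 and
then toward the larger scale (the lower-ploidy explanation).

Numerical choices:

* Expected VAFs are clipped into [e, 1−e] with e = 10⁻³ before binomial
  evaluation. Without this, a homozygous state (m = c, p = 1) has zero
  likelihood as soon as a single reference read is observed, which is an
  artifact of ignoring sequencing error; with the clip, a 98% observed
  VAF at c = 4 is correctly called homozygous.
* Candidate c = 0 in the fit is scored like c = 1 for the VAF term (a
  variant cannot live on zero copies).
* Copy-number rounding ties break toward the lower c. A c = 0 call
  additionally requires r < 0.25·s, separating a true homozygous
  deletion from a noisy low-coverage gene; ratios above (c_max + 0.5)·s/2
  (c_max default 8) are flagged as amplified beyond the model.
* Purity is exposed (expected VAF m·p/(p·c + 2(1−p))) but defaults to 1.
* Optional 11-gene running-median smoothing along chromosome order is
  available and off by default; the model is otherwise per-gene, with no
  segmentation.

In the end-to-end pipeline the somatic filter chain runs **before** the
ploidy fit, and only filter-passing variants contribute VAFs. Error
artifacts have VAF ≈ e, which fits no discrete m/c state; feeding them to
the fit rewards scales whose dense multiplicity grids contain small
fractions and demonstrably drags the grid search to its boundary.

## Somatic filter chain

Three per-variant, mutually independent filters (so the surviving set is
order-independent):

* **Consensus**: present in every (caller, replicate) call set. A
  `min_replicates` relaxation (at least k replicates per caller) exists
  for sparser designs.
* **Tumor error test**: reject "alt reads are sequencing error" when
  P(X ≥ a | X ~ Binom(d, e)) ≤ α. Defaults e = 10⁻³ (typical Illumina
  substitution error) and α = 10⁻⁴. At 170x pooled depth this passes
  VAFs down to ~1/8 while rejecting ≥ 99% of artifact sites.
* **Germline coverage test**: allow a somatic call only when a germline
  heterozygote would almost surely have shown more alt reads than
  observed: P(X ≤ g_a | Binom(d_g, ½)) ≤ β, default β = 10⁻³. At
  g_a = 0 this is 0.5^d, requiring germline depth ≥ 10. The het
  probability ½ assumes a diploid inbred normal.

Indels bypass the binomial machinery: ≥ 10 supporting tumor reads
(counted after realignment, supplied as input) and zero germline support.

RNA-based zygosity (`rna_zygosity`) is a plain VAF threshold, homozygous
at ≥ 0.85, intended for very deep RNA coverage (thousands of reads) where
the binomial interval around 0.5 and 1.0 cannot straddle the threshold.

## Mutation spectrum

Substitutions are collapsed onto the pyrimidine strand (six classes ×
four 3′ neighbors), the standard signature convention; the 2-to-1 mapping
from the 12 raw ref>alt pairs is exercised exhaustively in tests. When a
variant's reference base is a purine, the reported 3′ neighbor is the
complement of the 5′ neighbor on the reported strand. Coding effects
translate the reference and mutated codon with the standard code; when a
variant hits several transcripts the most severe effect is kept
(nonsense > missense > silent > UTR > noncoding). Per-Mb rates divide by
the coding-space size in megabases and also report the nearest integer,
matching how such rates are conventionally printed.

## Expression and antigen filtering

RPKM is count / ((length/10³)·(library/10⁶)); replicates are averaged
after quantification. The expression percentile of a threshold is the
percentage of genes strictly below it. "Expressed" in the neoepitope
cascade means RPKM > 0 — the least restrictive reading, configurable via
`expr_min`. The cancer-testis antigen filter is strict on both sides
(tumor > 10, normal < 10 RPKM).

## MHC typing and expression

Reads are assigned by exact substring matching against the allele
reference in both orientations; only uniquely matching reads count, and
unique + ambiguous + unmatched always partitions the input. This replaces
an aligner-based workflow and is exact for error-free reads; a
mismatch-tolerant mode (≤ k substitutions, via edlib infix alignment)
handles noisy simulations. Allele RPKM uses the published H-2 transcript
lengths (H-2Dd 1586, H-2Kd 1540, H-2Ld 1102, H-2Iad 978, H-2Db 1567,
H-2Kb 1564, H-2Iab 932 nt). The genotype is the set of alleles at
≥ 1 RPKM (configurable), and class II presentation is called functional
only when a class II allele is detected **and** Ciita (supplied
externally as an RPKM) is non-zero.

## Neoepitope enumeration and prioritization

For a missense mutation at protein position p, all windows of length
8–11 containing p and fitting inside the protein are enumerated —
Σ_L [min(p, n−L+1) − max(1, p−L+1) + 1]⁺ windows, 38 for an interior
site — each paired with its wild-type counterpart. Stop-gains and
frameshifts are excluded (no fixed-length mutant peptide set). The best
epitope–allele pair minimizes the consensus-style percentile rank over
the peptide × allele grid, with deterministic tie-breaks (IC50, then
peptide, then allele), so results are independent of enumeration order.

The shipping predictor is a deterministic toy: a per-(allele, length)
position-weight matrix drawn from a hash-seeded RNG, scored against a
fixed 1,000-peptide background; the percentile rank is the share of
background peptides scoring at least as well, and IC50 is a fixed
monotone transform of the PWM score. It is versioned (`v1`) and stable
across runs and platforms. It carries no immunological information —
passing tests show the machinery (enumeration, argmin, cascade set
algebra) is correct, not that any particular peptide binds MHC. Real
predictions drop in through `TablePredictor` (a peptide/allele/IC50/rank
TSV) without touching the cascade.

Cascade thresholds: strong binder = percentile ≤ 1.0; highly expressed =
RPKM ≥ 10. Tiers are nested by construction and monotone in the rank
threshold. Class II predictions are excluded from the cascade.

## Synthetic tumor generator

The generator emulates the statistical structure the stages assume, with
these defaults as the study conditions:

* **Copy number**: segmental states with proportions 10% diploid, 45%
  triploid, 39% tetraploid and a 6% amplified tail (2% c=5, 2% c=6, 1%
  c=7, 1% c=8), i.e. median 3 and mean ≈ 3.5; mean segment length 50
  genes. Quotas are allocated by largest remainder so realized
  frequencies match the proportions to rounding, then shuffled as
  contiguous segments.
* **Depth**: Poisson counts, mean coverage 170x pooled over 3
  replicates, 50 nt reads. The tumor library is budget-matched (scaled
  by c/mean-ploidy), so tumor/normal ratios are informative about
  relative, not absolute, DNA content — exactly the identifiability gap
  the VAF term closes. Negative-binomial overdispersion is not modeled.
* **Variants**: 300 somatic SNVs (m ~ Uniform{1..c}, alt ~ Binom(d,
  m/c)) and 100 artifact sites (alt ~ Binom(d, 10⁻³)); artifacts enter
  each caller/replicate call set independently with probability 0.7, so
  some artifacts survive consensus and must be caught by the binomial
  test. Substitution classes are drawn transition-heavy (65.5% C>T, 11%
  T>C, rest split evenly), echoing an alkylating-agent-induced tumor.
* **Expression**: log-normal (μ = 0.95, σ = 2.0) with a 20% zero mass,
  calibrated so 10 RPKM sits at the 80th percentile of all genes.
* **Proteome**: uniform-random proteins (60–600 aa) carrying the
  missense mutations; true cascade tiers are computed with the toy
  predictor so pipeline recovery can be checked exactly.
* **MHC**: random allele sequences at the published transcript lengths
  (explicitly synthetic stand-ins; real transcripts are not bundled),
  2,000 error-free 50 nt reads from the BALB/c-like class I trio, half
  reverse-complemented.

What it does **not** emulate: GC/mappability bias, subclonality and
impurity, correlated caller errors, strand bias, indel realignment
artifacts, splice structure, allele sequence homology (random references
share no 50-mers, so real-world class I cross-mapping ambiguity is
understated). Passing recovery tests therefore demonstrates correctness
of the inference machinery under the stated generative model, not
robustness to every bias of real sequencing data.

Determinism: one master seed derives fixed per-stage PCG64 streams;
reruns are byte-identical, which the test suite asserts file-by-file.

## Problem sizes

Default simulations use 2,000 genes / 300 SNVs / 100 artifacts; test
batteries use 200–1,000 genes and 5–50 seeded repetitions. These sizes
give the recovery statistics comfortable margins (binomial CIs well
inside the asserted thresholds) while keeping the full suite and the
acceptance script in the seconds-to-minutes range.

## Known limitations

* The ploidy scale is reported on the fitted grid (resolution 0.01);
  scale errors within one grid step are expected and tested for.
* The spectrum stage uses neutral placeholder flanks when no reference
  context accompanies a variant table; class assignment is unaffected,
  only the 3′-context matrix becomes uninformative.
* `rna_zygosity`'s threshold classifier is inappropriate below ~20x
  depth; the copy-number-aware binomial classifier should be used there.
* The headline recount loaders expect TSV exports of full annotation
  tables; the published supplements are spreadsheets and must be
  exported by the user.
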