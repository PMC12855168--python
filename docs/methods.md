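# Methods

`halogwas` implements a desk-scale version of a strain-panel workflow that
links a continuous salt-tolerance phenotype of bacteria to genomic
determinants. This note records the models, the numerical conventions, the
open design choices and what the synthetic test bed does and does not show.

## Phenotyping

A well's respiration signal over time is summarised by the area under its
kinetic curve, computed by the trapezoidal rule over hours. The instrument's
proprietary area unit is thereby only approximated; any absolute scale
difference cancels because every downstream quantity is a ratio: for strain
*s* at salt concentration *c*, each replicate area is divided by the mean
control (0 mM) area of the same strain, and the per-strain mean ratio
r̄_{s,c} is the working phenotype. By construction the across-replicate mean
ratio at the control concentration is exactly 1.

Metabolic Activity Reduction is MAR = (1 − r̄)·100, reported to one decimal
(half away from zero). MAR may be negative when salt stimulates activity;
values are never clamped and stimulation is flagged in the tolerance
profile. Three replicates are the expected design, but any n ≥ 1 is
accepted.

A one-way ANOVA across strains on the replicate ratios is computed per
concentration purely as a gate/report; it selects nothing. When within-group
variance is exactly zero with distinct means, p is reported as 0 with a
warning.

### Scott-Knott grouping

Strains are partitioned into non-overlapping letter groups by the original
divisive Scott-Knott procedure. On the g means sorted in descending order,
every cut between adjacent distinct values is scored by the between-group
sum of squares B₀ and the best cut is tested with

    λ = π / (2(π − 2)) · B₀ / σ̂₀²,
    σ̂₀² = ( Σᵢ (ȳᵢ − ȳ)² + ν s²_ȳ ) / (g + ν),   s²_ȳ = MSE / r,

where ν is the error degrees of freedom and r the replicate count. The
split is declared when λ exceeds the χ² quantile at ν₀ = g/(π − 2) degrees
of freedom, and the procedure recurses into both halves. Ties in means are
ordered stably by strain id and never straddle a cut. The error variance is
pooled across strains within one concentration by default (the degrees of
freedom and MSE of the per-condition one-way ANOVA); `scott_knott` also
accepts an externally pooled MSE, which covers the alternative pooling
choice.

## k-mer GWAS

Genomes are decomposed into canonical 13-mers: each window is represented
by the lexicographic minimum of itself and its reverse complement, so the
matrix is invariant to the arbitrary orientation of draft-assembly
scaffolds. Windows containing non-ACGT symbols are skipped. Internally
k-mers are packed into 2-bit-per-base int64 codes so whole scaffolds are
processed vectorised; the public API speaks strings.

k-mers present in fewer than `min_present` = 2 strains or absent from fewer
than `min_absent` = 2 strains are discarded (the min-2/max-2 rule). One
consequence worth stating: variants private to a single strain are
invisible to the test by design.

### Clonal-structure correction

Bacterial panels contain near-identical (clonal) strains that violate the
independence assumption of a two-sample test. The correction builds a
UPGMA guide tree from pairwise Mash-style distances

    d(a, b) = −(1/k) · ln( 2J / (1 + J) ),  capped at 1,

where J is the Jaccard index of the two strains' canonical k-mer sets
(computed from the already-built matrix rather than a separate sketching
pass: one data structure, fully deterministic). UPGMA tie-breaks are fixed
(merge the pair whose lexicographically smallest member labels sort
first), so the tree is reproducible regardless of input order.

Gerstein–Sonnhammer–Chothia weights are then read off the tree: each leaf
starts with its terminal branch length, and every internal branch's length
is distributed among its descendant leaves in proportion to their
accumulated weights (equally while all are zero), ascending from the tips.
Weights are normalised to mean 1. A cluster of clones thus shares the
weight mass one distinct lineage would receive. The correction can be
disabled (`correct_structure=False`), which reduces every test to the
classical Welch t-test.

### Weighted Welch test

For each retained k-mer the panel splits into carriers and non-carriers;
groups with fewer than two members are skipped and counted. With weights
w and values x in one group,

    m = Σwx / Σw,   n_eff = Σw,
    s² = Σw(x − m)² · Σw / ((Σw)² − Σw²)        (unbiased, frequency-weight
                                                 corrected),
    t = (m₁ − m₂) / √(s₁²/n₁ + s₂²/n₂),

with Welch–Satterthwaite degrees of freedom on the two variance
components and a two-sided p from the t distribution. At unit weights this
reproduces the classical Welch test to 1e-10 (tested against an
independent implementation). k-mers sharing an identical presence pattern
are tested once and share the statistic, which also guarantees results are
independent of how the matrix is batched.

The primary output keeps k-mers with p ≤ 0.05; Benjamini–Hochberg
q-values are emitted as non-selecting metadata, and an extreme-p "top set"
can be cut either by p-value ceiling or by rank (`top_p` / `top_n`) — the
two readings of a published top-set cut are both exposed because neither
is canonical.

## Annotation mapping

Significant k-mers are placed exactly (no mismatches, no gaps) on either
strand; canonical k-mers are strandless, so only the CDS strand determines
the upstream direction. Coordinates are 1-based inclusive (GFF3
convention). Per placement and CDS:

* any shared base with a CDS interval → relative position 0, a gene hit;
* a k-mer wholly on the 5′ side of a CDS start gets a negative offset,
  measured on the coding strand from the start coordinate to the nearest
  k-mer base; the promoter window is inclusive at −600 and exclusive at 0;
* one record per eligible CDS, so a k-mer between two divergent promoters
  is legitimately reported twice;
* anything farther than 600 nt upstream with no overlap is intergenic.

The rule set lives in a single function (`relative_position`) so an
alternative reading changes exactly one unit. Open details — whether a
k-mer overlapping two CDSs should count once, and whether the window is
anchored at the start codon when it differs from the feature start — are
resolved here as "one record per target CDS" and "feature start".

Gene hits are cross-referenced against a pangenome presence/absence matrix
(Roary `gene_presence_absence` dialect or plain cluster × strain TSV);
each locus maps to at most one cluster and is reported as strain-unique or
shared. COG classes of gene hits are tallied as plain frequencies (no
enrichment test). Scaffolds are attributed to reference replicons
(chromosome, pSymA, pSymB) by k-mer containment — the fraction of the
scaffold's canonical k-mers found in each reference — with an explicit
acceptance threshold (0.5) and runner-up margin (0.1), replacing
whole-genome alignment, which is out of scope. Percentages over
{chromosome, pSymA, pSymB, unknown} always sum to 100.

## Phenotype-Microarray profiles

A carbon-source well is called active when its raw area reaches 13,000
(the default threshold, motivated as the maximum negative-control area);
no control subtraction is performed and technical replicates are accepted
but not required (means are used if present). Utilization summaries are
per strain × salt condition; duplicate wells are an error. Retention is
the percentage of control-active sources still active under salt,
reported rounded **up** to the next whole percent — the convention that
reproduces the published counts-to-percent arithmetic — so a ratio of
0.9901 also reports 100 while exact multiples are unchanged.

"Retaining high metabolic activity" has no printed criterion; the default
operationalization is: active call at 300 mM in every tolerant strain AND
an area ratio (300 mM / 0 mM) ≥ 0.5, with the ratio cutoff in config and
reported alongside. The common set is the intersection of all strains'
control-active sets, and the retained subset is always contained in it.

## Synthetic data

The generator emulates exactly what the pipeline assumes about real
panels, with truth labels for every stage:

* one random backbone (default 50 kb; 200 kb in the recovery experiments)
  shared by all strains;
* SNPs as panel-level segregating sites: each site is polymorphic with
  probability `snp_rate` (default 0.01, a density typical of a diverse
  bacterial species panel), with a derived-allele frequency drawn
  uniformly on (0.05, 0.95) and carriers drawn binomially. Sites are
  shared across strains — private mutations would be erased wholesale by
  the min-2/max-2 filter and leave nothing to test;
* accessory genes as random ORF-like blocks (ATG, non-stop codons, stop;
  300–1500 nt) inserted at fixed backbone sites in a Bernoulli(prevalence)
  subset of strains, annotated as CDS records together with a set of core
  genes;
* optional clone pairs copying both SNPs and carriage, to exercise the
  GSC weighting;
* a latent phenotype latent = baseline − Σ effect·carries + N(0, noise_sd)
  clipped to [0, 1] (clips counted and warned), default baseline 0.9,
  noise sd 0.03, effects 1.5× the noise sd;
* replicate areas drawn so that control normalization recovers the latent
  value up to replicate noise (3% CV, 3 replicates, control scale 50,000),
  and logistic kinetic curves whose trapezoidal area equals any requested
  area;
* PM tables with designated tolerant/sensitive strains, ~55% active
  sources, and retention probabilities 0.6 / 0.45 — retained wells keep
  ≥ 60% of their control area, lost wells drop below threshold.

Everything is deterministic given the seed (single `numpy` Generator
stream per operation).

What passing tests on this bed do **not** show: real draft assemblies have
repeats, contamination and assembly breakpoints that multiply k-mer
placements; real clonal structure is hierarchical rather than
pairwise-clonal; real phenotype noise is not Gaussian and not homoscedastic
across strains; and accessory genes recombine rather than sitting at fixed
insertion sites. The test bed validates the arithmetic and the contracts,
not the biology.

### A note on recovery power

With ten additive causal loci each of effect 1.5× the noise sd at
prevalence 0.5, the nine non-focal loci contribute 9·0.25·e² to the
within-group variance of any single-locus test, which bounds the per-locus
t noncentrality by √n/3 (≈ 2.36 at n = 50) even with zero replicate noise.
Per-locus power at p ≤ 0.05 therefore tops out near 0.65, and typical runs
tag 5–9 of the 10 loci. A single planted locus at 3× the noise sd, by
contrast, is recovered essentially always and its k-mers occupy the
minimum-p stratum. Under the null (all effects zero) the significant
fraction of tested k-mers sits near 0.05, as it should.

## Problem sizes and runtime

Recovery and calibration experiments run at 50 strains × 200 kb (about
235,000 canonical 13-mers, ~58,000 tested after filtering; ~10 s per run);
unit and end-to-end fixtures use 12–30 strains × 10–30 kb. These sizes were
chosen so the whole suite exercises every stage at full fidelity while the
statistics above (power bound, null calibration) — not raw scale — carry
the scientific content.

## Known limitations

* The k-mer matrix is dense in memory; panels far beyond ~100 strains ×
  multi-Mb genomes would need the streamed-batch path to be driven from
  disk (the statistics are already batch-independent).
* UPGMA assumes a constant divergence rate; strongly rate-heterogeneous
  panels would distort the GSC weights.
* Replicon assignment by containment cannot resolve scaffolds spanning
  replicon boundaries (they fall to `unknown` by the margin rule — which
  is the conservative behaviour one wants).
* The weighted Welch test treats weights as frequency weights in the
  variance estimator; other weighted-variance conventions exist and give
  slightly different small-sample behaviour. The chosen estimator is
  recorded in the output metadata.
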