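# Methods

`florin` re-implements, as a tested library, the integrative analysis used to
dissect late flowering (LF) versus normal flowering (NF) in *Prunus
sibirica*: differential expression of mRNA/lncRNA/miRNA, miRNA response
element (MRE) calling, cis/trans lncRNA target assignment, hypergeometric
shared-MRE ceRNA triplet inference, and a case/control SNP association scan
with Bonferroni thresholding, candidate regions and promoter G-box
disruption. This note records the models, the surrogates chosen where the
original work delegated a step to external software, the tunable parameters,
and what the synthetic benchmarks do and do not establish.

## Differential expression

Counts are the primitive unit; FPKM and TPM are derived from them:

- FPKM_is = c_is · 10⁹ / (L_i · C_s), with C_s the column (library) sum;
- TPM_is = (c_is / L_i) / Σ_j (c_js / L_j) · 10⁶, so every non-degenerate
  sample column sums to exactly 10⁶.

The DE statistic is a deterministic surrogate suited to a two-replicate
design: counts are pooled within condition and each feature is tested with a
two-sided exact conditional test on the 2×2 table (feature count vs rest of
library, NF vs LF). Two-sidedness follows the minimum-likelihood rule (sum
the probabilities of all tables no more likely than the observed one). The
reported log2 ratio is log2((pool_LF + 1)/(pool_NF + 1)) after scaling both
pools to the mean library size; the pseudocount of 1 avoids ±∞ at empty
pools and never enters the test itself. Raw p-values are Benjamini–Hochberg
corrected; the filters are inclusive: |log2 ratio| ≥ 1 with q ≤ 0.001 for
mRNA/lncRNA and q ≤ 0.1 for miRNA.

Two caveats are inherent to a pooled exact test. First, it conditions on the
pooled table and therefore ignores biological replicate dispersion; the
|log2 ratio| ≥ 1 filter is what keeps the false-positive rate low under
overdispersion (measured ≈0.3% per feature at dispersion 0.05 with two
replicates). Second, it is composition-sensitive: with very few features,
one large planted effect shifts the library ratio of everything else.
Pipelines built on this module should therefore test all feature classes
against one pooled library (as the benchmark scenarios do) rather than
class-by-class on small matrices.

## miRNA target (MRE) scoring

The classic plant-target penalty scheme replaces the external predictors:
the miRNA is read antiparallel to the transcript window (miRNA position 1
pairs the window's 3′ end); each position contributes 0 for a Watson–Crick
pair, 0.5 for a G:U wobble, 1 otherwise, doubled over positions 2–13; a
site qualifies at total penalty ≤ 4.0 (`Thresholds.mre_cutoff`). Windows are
ungapped — no bulges — which makes the scan exactly reproducible by a
brute-force double loop (a property the suite asserts). Overlapping
qualifying windows of one miRNA collapse to the lowest-scoring one, ties to
the leftmost. "Same MRE" on two different molecules means the same miRNA's
element on both; a strict mode additionally compares the pairing pattern.

The scheme's true symmetry is duplex reversal with role swap (reversing both
strands and exchanging miRNA/target roles preserves the score, because the
penalty table is symmetric); naive reverse-complementation of both strands
does *not* preserve scores, since it maps a G:U wobble onto an A:C mismatch.

## cis/trans lncRNA targets

cis: the lncRNA locus intersects a strand-aware window around the mRNA —
10 kb past the 5′ end and 20 kb past the 3′ end, pads swapping sides on the
− strand, boundaries inclusive — and the expression profiles satisfy
Spearman ρ ≥ 0.6 *and* Pearson r ≥ 0.6 (midranks for ties; a zero-variance
profile fails the filter). trans: evaluated for non-cis pairs only, requiring
the same dual correlation filter plus a duplex energy below −30 under an
additive surrogate: the best contiguous, fully-paired antisense duplex with
per-pair energies G:C −3, A:T −2, G:U −1. The −30 cutoff is kept as printed
and applies to these surrogate units, not kcal/mol. With only two replicates
per condition (four samples) correlations are very noisy; the module warns
below six samples, and correlation-dependent benchmarks use four replicates.

## ceRNA triplets

With N the number of distinct miRNAs having ≥ 1 predicted MRE anywhere in
the dataset, K of them targeting the mRNA, n the lncRNA and k shared, the
shared-MRE p-value is the upper hypergeometric tail P(X ≥ k), evaluated via
the scipy survival function and verified against exhaustive enumeration
(N ≤ 12) and exact rational arithmetic (N ≤ 2000, ≤ 10⁻¹⁰ relative). A
triplet (mRNA, lncRNA, miRNA) is emitted when (1) all three pass their DE
filters, (2) the miRNA has an MRE on both partners, (3) the mRNA and lncRNA
directions agree and oppose the miRNA's, and the pair's shared-MRE test has
p ≤ 0.05. Direction constraints are enforced on DE labels; pairwise Pearson
correlations are attached for audit but not thresholded, since the
lncRNA–mRNA correlation constraint already lives in the cis/trans module.
No multiplicity correction is applied across pairs by default (the analysis
is pathway-focused via an optional focus gene list); BH across pairs is
available behind a flag.

## Association scan

QC keeps biallelic SNPs with missing rate < 0.2 and MAF > 0.05, both strict,
MAF computed on non-missing calls. The association statistic is the
Cochran–Armitage trend test with additive scores (0, 1, 2) — a closed-form,
calibration-testable surrogate for the mixed-model scan, appropriate here
because the synthetic panel has no relatedness or stratification. Its
empirical size at α = 0.05 is within ±2% absolute over 10⁴ null panels of
66 accessions. Significance uses the Bonferroni cutoff −log10(α/m) at full
precision; displayed thresholds are truncated (not rounded) to two decimals,
the convention that reproduces the printed 7.71 at m = 2,598,398. Candidate
regions pad each significant SNP by ±10 kb, merge overlapping or touching
intervals, and attach genes by interval intersection.

Genotype–phenotype concordance is the best two-group genotype dichotomy:
each of {0}|{1,2}, {0,1}|{2}, {0,2}|{1} is tried with both class
assignments and the maximal agreement fraction reported. This estimator
exactly reproduces the arithmetic of the reported 86.36–93.94% range
(57/66 and 62/66) and is offered as such, without claiming to be the
original estimator. Promoter G-box analysis scans both strands for exact
motif occurrences (default set {TACGTG}, configurable — the canonical
G-box CACGTG can be added) and re-tests each SNP-containing hit after
substituting the alt allele, strand-aware; a hit is disrupted iff the
substituted window matches no motif in the set.

## Synthetic data

The generator's defaults are the study's conditions: two biological
replicates per condition, 66 accessions split 43 NF / 23 LF, MAF drawn
uniformly on (0.05, 0.5). Quantities the study does not state were fixed
once at field-typical values: negative-binomial dispersion 0.05, baseline
log2 means uniform on (3, 10), missingness 0.05 (inside the < 0.2 QC bound),
causal-SNP penetrance 0.9 (the midpoint of the reported concordance range),
promoter length 2 kb. All outputs are fully determined by the design seed.

- **Layout** — mRNAs occupy disjoint 80-kb slots; exactly
  round(cis_fraction · n_lncRNA) lncRNAs are placed inside cis windows and
  the rest in dead zones straddling slot boundaries, so the realised cis set
  is exact by construction and verified against the window scanner.
- **Transcripts** — i.i.d. uniform background with planned MREs written in;
  each planned penalty is composed from non-seed wobbles (+0.5), non-seed
  mismatches (+1), seed wobbles (+1) and seed mismatches (+2) and re-scored
  to confirm exactness (a fractional penalty requires a G/U miRNA base
  outside the seed; otherwise the plan errors).
- **Expression** — negative-binomial counts; a planted DE effect multiplies
  the LF mean by 2^±effect; each planted triplet shares a per-sample
  standard-normal latent activity z with multipliers exp(+cz) on the miRNA
  and exp(−cz) on both partners, giving the ceRNA sign pattern
  (mRNA–lncRNA positive, each negative with the miRNA).
- **Genotypes** — non-causal SNPs are exactly null (allele frequency drawn
  independently of phenotype); the phenotype split is exactly 43/23 and the
  causal genotype matches the class with probability = penetrance; the
  causal SNP is never missing and its reference base is the third nucleotide
  of a planted promoter G-box.

What the generator does not emulate: library-preparation biases, linkage
disequilibrium, population stratification or relatedness, gapped/bulged
miRNA duplexes, or any thermodynamically calibrated hybridization energy.
Passing benchmarks therefore demonstrates correctness of the pipeline's
logic under its own assumptions, not performance on real sequencing data.

## Benchmark problem sizes

The recovery benchmarks use 30 mRNAs + 30 lncRNAs + 30 miRNAs, four
replicates per condition, a planted DE shift of 4 log2 units with coupling
0.9 (the coupling latent itself contributes about one log2 unit of
pooled-ratio noise at four replicates, so the planted shift is set well
clear of the |log2 ratio| ≥ 1 filter), and SNP panels of 2,000 markers over
66 accessions. Across 20 seeds the planted triplet is recovered with zero
false triplets, and the causal SNP ranks first and falls inside a candidate
region, in 100% of runs at these sizes; trend-test calibration uses 10⁴
null panels.

## Numerical conventions

Coordinates are 1-based inclusive at every interface (BED output converts at
the boundary). U is normalised to T at read time so all sequence logic runs
on one alphabet. Hypergeometric tails are clamped to (0, 1]; chi-square
p-values are floored at the smallest positive double before taking −log10.
Degenerate inputs are defined, not special-cased ad hoc: zero library size
or all-zero TPM columns yield zero columns with a warning, constant
genotypes are flagged untestable and excluded from thresholding, and
zero-variance expression profiles fail the correlation filter.
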