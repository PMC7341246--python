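# Methods

`herdgen` implements the genomic-management analysis chain used for small,
fragmented livestock breeds genotyped on medium-density SNP arrays: quality
control, runs-of-homozygosity (ROH) inbreeding, LD-based ancestral effective
population size, pedigree BLUP with EBV deregression, and a
stratification-corrected single-SNP association scan. This note documents the
models, the defaults and why they were chosen, the synthetic-data generators
used for validation, and known limitations.

## Quality control and LD pruning

Filters are applied in a fixed, logged order so removal tallies are
reproducible: (1) non-autosomal/unmapped markers (autosome set configurable,
default 1–29 for cattle), (2) samples with call rate < 0.95, (3) SNPs with
call frequency < 0.95, (4) SNPs with MAF < 0.01 (computed on non-missing
calls only), (5) SNPs with Hardy–Weinberg exact p ≤ 0.001. The HWE test is
the exact conditional test: given the observed allele counts, the
probabilities of all possible heterozygote counts are summed over outcomes no
more probable than the observed one (two-sided by probability mass). Missing
genotypes use a distinct sentinel, never 0.

LD pruning is pairwise-r² based: within windows of 50 SNPs advanced by 5,
while any retained pair has genotype-correlation r² > 0.5 the member of the
worst pair with the lower MAF is removed (ties: the later position). Note
that some widely used tools implement their default "independence" pruning
via variance-inflation factors; this package implements the pairwise-r²
criterion directly, which is the behaviour usually reported in method
sections, and guarantees post hoc that no surviving within-window pair
exceeds the threshold.

## Runs of homozygosity and F_ROH

Detection is sliding-window (the consecutive-runs approach of the standard R
tooling): a 15-SNP window is homozygous if it contains at most 1
heterozygous and at most 1 missing call; a SNP is in run-state when at least
5% of the windows covering it are homozygous; maximal run-state stretches
become segments after enforcing ≥ 40 SNPs, ≥ 4 Mb, density ≥ 1 SNP/100 kb
and a 1 Mb maximum gap (a larger gap terminates the current candidate rather
than discarding it). The window allowances and the 5% run-state threshold
are the detection tool's documented defaults; all are configurable.

F_ROH(i) = Σ length of i's segments ≥ L / total covered autosome length,
with L = 4 Mb by default and 8 Mb on demand. "Covered length" is the span
between the first and last SNP per chromosome (robust to array coverage);
assembly lengths can be supplied via a chrom-sizes table instead. Lengths
use inclusive 1-based coordinates (end − start + 1); individuals with no
segments get F_ROH = 0, so F_ROH is monotone non-increasing in L.

One reporting subtlety: with 639 segments in classes (220, 217, 202) the
exact class frequencies are (34.43, 33.96, 31.61)%; the middle value rounds
to 34.0 but truncates to 33.9. `length_class_table` rounds. Similarly,
a "mean number of ROH" of 15.2 can be read per individual (639/42) — the
reading that is arithmetically consistent with the published tables this
package mirrors — or per chromosome; the summary reports the per-individual
quantity.

## LD decay and ancestral Ne

Pairwise r² is the squared Pearson correlation of genotype dosages over
samples non-missing at both SNPs, within chromosomes only (pairs with < 2
informative samples or zero variance are skipped). Means are taken in 10 kb
half-open distance bins. Each bin is inverted through the drift expectation

    E[r²] ≈ 1/(α + 4·Ne·c) + 1/(β·n)

giving Ne(t) = (1/r²_adj − α)/(4·f(c)) at t = 1/(2·f(c)) generations ago,
with r²_adj = mean r² − 1/(β·n). Defaults follow the conventions of the
standard SNP-chip Ne estimator: α = 2 (mutation-adjusted; 1 and 2.2
selectable), β = 2 for unphased data, physical→genetic map at a constant
1 cM/Mb (no species map is shipped; per-chromosome rates accepted), and
f(c) = c linear with a Haldane-inverse option. Bins with fewer than 50
pairs, non-positive r²_adj, or f(c) = 0 are dropped with a warning, never
clamped.

Two numerical notes. First, the sampling bias of a squared correlation over
n individuals is ≈ 1/(n−1), slightly larger than the 1/(β·n) convention
retained here for compatibility with the published estimator; at n = 50 the
residual ≈ 0.01 biases Ne modestly downward at large distances, and
constant-Ne recovery remains within a factor of two. Second, recent-time
points (large c) equilibrate quickly in a drifting population while
short-distance LD takes ~2·Ne generations to reach stationarity; validation
simulations therefore use a 300-generation burn-in at Ne = 100.

## Animal model, REML and deregression

Inbreeding coefficients come from the Meuwissen–Luo recursion; A⁻¹ is
assembled sparsely with Henderson's rules using inbreeding-adjusted
Mendelian-sampling variances d_i = ½ − ¼(F_s + F_d) (¾ − ¼F with one known
parent). Unknown parents form a single base population (no genetic groups).

BLUP solves Henderson's mixed-model equations for y = Xb + Z_a a [+ Z_m m]
[+ Z_p p] + e, with the direct–maternal covariance block kron(G₀⁻¹, A⁻¹)
when fitted (flag-controlled, since the maternal model is often reported
with the correlation r_AM even where the model statement omits the
covariance). Fixed effects are categorical factors plus an intercept; a
rank-deficient design raises an error naming the columns. Reliability is
r²_i = 1 − PEV_i/σ²_a from the inverse coefficient-matrix diagonal, without
the (1+F) refinement (documented, switchable in principle by adjusting the
denominator).

Variance components for the direct-effects model are estimated by EM-REML:
the classical updates σ²_a ← (â'A⁻¹â + tr(A⁻¹C^aa)σ²_e)/q and
σ²_e ← y'ê/(n − rank X), iterated to a relative change < 1e-8 or 500
iterations (non-convergence returns the last iterate, flagged; EM's
monotone restricted likelihood is asserted in tests). Implementation: fixed
effects are absorbed and the animal equations diagonalized once via
A⁻¹ = LL' and an eigendecomposition of L⁻¹(Z'SZ)L⁻ᵀ, making each EM step
O(q²); the tests verify identity with the naive per-iteration inversion.
EM converges slowly near the optimum, so the iteration cap is usually what
stops it; the parameter drift at that point is far below the sampling noise
of the estimates.

Deregression is the simplified reliability-based form: DEBV = EBV/r²,
association weight w = (1 − c)/[c + (1 − r²)/r²] with c = 0.10 the fraction
of genetic variance not captured by markers. Parent-average removal (the
full published procedure) is omitted by default — shallow pedigrees rarely
carry usable parent-average reliabilities — and a hook exists to add it.
Animals with r² below 0.05 are excluded with a warning. The default scan is
unweighted; a weighted mode accepts w.

## Association scan

Stratification axes are the top eigenvectors of the sample covariance of
genotypes centred by 2p̂ and scaled by √(2p̂(1−p̂)) (missing calls
mean-imputed for the decomposition only; sign fixed by making each axis's
largest-magnitude loading positive; default 3 axes). Phenotype (DEBV) and
each genotype are residualized on the axes plus intercept, and the score
statistic is χ²₁ = (n − k − 1)·r²(residuals), with β the residual regression
slope and SE = |β|/√χ². Genomic control estimates λ as median(χ²)/0.4549
(or by through-origin regression on expected quantiles). The default
adjustment multiplies raw p by λ with a cap at 1 — the literal small-sample
deflation correction used with this scan — while a conventional χ²/λ mode
is available, since multiplying p by λ > 1 is anti-conservative in the
inflation direction. Tiers use strict thresholds: genome-wide p < 5×10⁻⁶,
suggestive p < 5×10⁻⁵. Per-SNP variance explained defaults to
PVE = 2p̂(1−p̂)β²/Var(y) capped at 1, with a score-statistic alternative
χ²/(χ² + n − 2); the formula in use is config-visible. SNP feature labels
(exon/intron/upstream-within-5-kb strand-aware/intergenic, nearest gene
name) come from a GFF3 interval lookup.

## Synthetic data

The generators provide exact ground truth for every stage.

*Pedigree*: generational, litters of two (one male, one female) so
opposite-sex full-sib pairs always exist; a configurable probability of
full-sib mating from the second offspring generation on, or a single
repeated sire. *Gene drop*: founder haplotypes drawn per SNP from a
Uniform(0.05, 0.5) founder MAF; meiosis by Poisson crossovers without
interference (Haldane map, 1 cM/Mb), implemented as a Markov source-switch
between adjacent SNPs; founder-haplotype labels are propagated with the
alleles, so loci where the two labels coincide are exactly autozygous and
true IBD segments need no inference. SNP positions are uniform at ~1 per
50 kb (50K-chip density). *Wright–Fisher*: 2·Ne haplotypes, each gamete
recombining a random individual's pair, run for a configurable number of
generations (default 300 — ≥ 2·Ne, so LD is near-stationary at the
distances that dominate the Ne trajectory). *Phenotypes*: true breeding
values descend the pedigree with inbreeding-adjusted Mendelian-sampling
variance; maternal values are drawn jointly with the configured r_AM;
permanent-environment and residual effects complete y; BLUP can be run
in-line to emit EBV/reliability tables, giving end-to-end fixtures through
the same file formats as real data.

The validation cohort emulating a small inbred island herd uses 44
founders, 3 offspring generations and full-sib-mating probability 0.25,
giving an expected final-generation autozygosity near 0.09–0.10 (the level
reported for strongly fragmented local breeds); 42 animals are genotyped.
What these simulations do **not** emulate: background LD among founders
(founder loci are independent, so ROH false-positive pressure from
ancestral haplotype sharing is lower than in real arrays), ascertainment
bias of chip SNPs, genotyping error (available but off by default), and
overlapping generations. Passing tests therefore demonstrate correctness
of the algorithms under the stated model, not field performance on any
particular breed.

## Validation suite design

Problem sizes were chosen so each recovery study is decisive at its
tolerance: the ROH study uses 29 × 90 Mb chromosomes (≈ 52K SNPs, ≈ 200
true long IBD segments); the Ne study 20 × 30 Mb at n = 50; REML recovery a
400-animal fully phenotyped 3-generation pedigree averaged over 6 seeded
replicates (SE ≈ 0.03); λ calibration panels 2400–5000 SNPs so the
Monte-Carlo spread of a median-based λ is small relative to the asserted
band. The association power study (a single QTL explaining 30% of phenotype
variance in 42 animals against a 5×10⁻⁵ threshold) has an analytic power
near 15% — E[χ²] ≈ 38·0.3 ≈ 11.4 against a critical value of 16.4 — and
the suite reports it as measured.

## Known limitations

- No imputation, phasing, sex chromosomes, or assembly lift-over.
- ROH: no HMM-based autozygosity, ROH islands, or consensus-ROH mapping.
- Ne: no haplotype-phase statistics and no full-likelihood reconstructions;
  the trajectory inherits the bias of the moment inversion at short
  distances described above.
- REML is single-trait EM for the direct model only (the maternal models
  are solved at user-supplied variance components); no AI-REML, no
  multi-trait, no genomic or single-step BLUP.
- GWAS is the fixed-effects score scan; no mixed-model (GRM) association,
  haplotype tests, or pathway/network analysis.
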