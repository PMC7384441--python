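# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Windowed diversity statistics

Windows are non-overlapping, 1-based inclusive spans of 100 kb by
default, tiling each chromosome to the last observed SNP. All
coordinates follow the VCF/GFF3 convention (1-based inclusive).

**Nucleotide diversity.** Per site, π̂ = (n/(n−1))·2p(1−p) with n the
number of non-missing alleles in the group (each diploid inbred
contributes two; heterozygotes contribute one of each) and p the
alternate-allele frequency. Window π is the per-site sum divided by the
window length in bp, so it is additive under window splitting and equals
the all-pairs mean Hamming distance per bp on complete haploid-coded
data (a property the tests verify against a brute-force oracle).

**F<sub>ST</sub>.** Weir & Cockerham's (1984) two-population estimator
with per-site variance components a (between populations), b (between
individuals within populations) and c (within individuals, h̄/2).
Windows aggregate by ratio of sums Σa/Σ(a+b+c) — the convention used by
the common VCF tooling — which is less biased than averaging per-site
ratios. Sites where a component is undefined (a group with fewer than
two genotyped individuals) are skipped. A window with no eligible sites
carries an NaN marker rather than a value.

**Tajima's D.** D = (π̂L − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
constants derived from the sequence count; the sequence count for a
window is the site-wise median number of non-missing alleles. S = 0
yields an undefined marker, not zero. D is reported per group but is
*not* part of the sweep-calling rule, which uses only the π ratio and
F<sub>ST</sub>.

**Sweep calling.** Empirical type-7 quantiles over eligible windows
(defined π ratio and F<sub>ST</sub>, ≥ 3 SNPs per group; the SNP floor
is configurable). Ties at a threshold are included, favoring
sensitivity. A-selected: π ratio ≤ q(tail) AND F<sub>ST</sub> ≥
q(1−tail); B-selected: π ratio ≥ q(1−tail) AND the same F<sub>ST</sub>
rule. Adjacent qualifying windows of the same group merge into regions
for reporting, but the per-window tally is also kept, since window
counts are the natural bookkeeping unit (n windows × 100 kb = Mb under
selection). When a sweep drives a window's diversity in the *reference*
group of the ratio to zero the ratio is undefined and the window leaves
the pools — a structural blind spot of the ratio statistic worth knowing
about when interpreting counts.

## P+K mixed model

Kinship is VanRaden's genomic relationship K = MM′/(2Σp(1−p)) with M the
dosage matrix centered by 2p and missing calls mean-imputed. If K's
smallest eigenvalue falls below 10⁻⁶ the spectrum is shifted up and the
event logged.

The association model is y = μ + PCγ + xβ + u + e, cov(u) = σ²gK. The
ratio δ = σ²e/σ²g is estimated once per trait/environment by REML on the
null model (no SNP), profiled through a single eigendecomposition of K:
a 33-point log-grid scan over δ ∈ [e⁻⁸, e⁸] refined by bounded Brent
search. Each SNP is then tested by generalized least squares in the
rotated basis with a per-marker profiled residual variance and a t-test
on β (df = n − p − 1). With K = I and no PCs this reduces *exactly* to
per-SNP ordinary least squares, which the tests exploit as an oracle.
Three principal components are included by default (configurable);
phenotype input is the per-sample entry mean for one trait and
environment, analyzed separately per environment. The flat 10⁻³
significance threshold applies with no multiplicity correction — the
empirical-threshold convention of the study design this mirrors.

Associated regions flank each significant SNP by ±150 kb (floored at
bp 1) and merge transitively, per trait, whenever intervals overlap or
their resident gene sets intersect; merging is union-find with an
all-pairs closure oracle in the tests. Haplotype grouping renders
homozygous calls as single bases; samples with a heterozygous or missing
call at any member SNP are excluded (inbred context), and carrier
percentages are reported against the group's included-sample count.

## Phenotype statistics

Summaries operate on per-sample entry means. SV% (coefficient of
variation) uses the sample SD (n−1) and half-up rounding to two decimals
for report comparison. Broad-sense heritability is on the entry-mean
basis over k environments, H² = σ²g/(σ²g + σ²e/k); variance components
come from a method-of-moments ANOVA on the genotype × environment
entry-mean table with environment means removed first (equivalently a
two-way entry-mean ANOVA) — without that removal, environment main
effects would inflate MS_err and bias H² downward. σ²g is floored at
zero, which makes single estimates upward-biased near zero; parameter
recovery is therefore asserted on means over replicate draws. Group
contrasts use Welch's unequal-variance t-test with the conventional
star coding; correlations are Pearson on entry means.

## Co-expression network

Expression is normalized by the two-step rule: exact zeros are replaced
with 0.01, then every value maps through log₂(x + 0.01). Note the
literal two-step rule is not monotone on (0, 0.01): an exact zero maps
to log₂(0.02), above inputs slightly greater than zero. A single-step
floor variant (`literal=False`) is monotone everywhere and is offered as
a config switch.

The network is unsigned: a<sub>ij</sub> = |cor(i,j)|^β with β = 6 (the
power at which the degree distribution's scale-free fit clearly exceeds
the β = 1 fit on module-structured data; a helper computes the log-log
R² index). Edge weight means topological overlap,
TOM<sub>ij</sub> = (Σ<sub>u≠i,j</sub> a<sub>iu</sub>a<sub>uj</sub> + a<sub>ij</sub>) /
(min(k<sub>i</sub>,k<sub>j</sub>) + 1 − a<sub>ij</sub>), with
adjacency-based weights behind a flag. Modules come from average-linkage
clustering of 1−TOM with a *static* height cut (default 0.8) and a
minimum size (default 30); clusters below the floor are pooled into an
unassigned label 0. A static cut replaces dynamic tree cutting
deliberately: it is deterministic and has two transparent parameters,
at the cost of less adaptive cluster boundaries — module *counts* are
therefore not comparable across cut heights and are not treated as a
validated output. Neighbor extraction returns edges strictly above the
weight cutoff.

## Synthetic data generator

The generator emulates a two-pool breeding program:

* **Founders.** 60 founder haplotypes are block mosaics of 5 deep
  prototype haplotypes (blocks ~200 kb, 2% founder-private flips), so
  the founder pool carries ancestral LD that decays on a tunable scale —
  real germplasm is not site-independent, and without this the panel's
  r² would be capped near 1/(number of surviving lineages).
* **Breeding.** Each group evolves as a census population (15× the
  genotyped panel by default — programs genotype a sample of a much
  larger nursery) for 10 generations of Wright–Fisher mating with
  partial selfing (0.2) and Poisson recombination (5·10⁻⁷/bp per
  gamete), followed by 3 enforced selfing generations that leave lines
  near-homozygous. Output lines are a random subsample.
* **Sweeps.** A planted sweep starts from a single founder carrier
  whose ~250-kb local segment is introgressed into one line of the
  target group (a backcrossed donor cross). Selection is rank
  truncation: each generation the top 30% of lines by favored-allele
  count form the parent pool, sampled uniformly. Truncation mirrors
  actual breeding practice and, unlike multiplicative per-copy fitness,
  does not collapse the effective population size when several loci
  segregate — with multiplicative fitness the genome-wide drift it
  induces buries the very sweeps being planted. Hitch-hiking arises
  from genuine linkage, not from an explicit flanking-selection knob.
* **Calibration.** Defaults were set so the *neutral* background
  matches the divergence scale such two-pool programs display — median
  π ratio near 0.85 and window F<sub>ST</sub> mostly below 0.3 — while
  planted sweeps fix their alleles in ≥ 95% of runs.
* **Phenotypes.** Genetic value is Σ effect×dosage over planted QTLs
  plus a baseline of 12 trait units. Environment and replicate noise
  are scaled so the realized entry-mean H² over k environments matches
  the target: σ²e = k·σ²g(1−H²)/H², split half at the environment level
  and half at the replicate level. QTLs start at moderate founder
  frequency (0.4) so they segregate within groups.
* **Expression.** Planted modules share one latent sample factor
  (pairwise correlation = the target ρ); values are shifted, scaled
  Gaussians clipped at zero, so matrices are non-negative and contain
  exact zeros that exercise the normalization rule.

**What the synthetic experiments show — and not.** Recovery of planted
sweeps, QTLs, heritabilities and modules demonstrates that the
statistics and thresholds behave as designed under the generator's
assumptions: biallelic SNPs, a shared founder pool, no gene conversion
or structural variation, exchangeable environments, Gaussian noise, and
sweeps that run essentially to fixation. Passing them does not certify
performance on real panels with admixture from outside germplasm,
genotyping error, shared selection targets between pools, or partial
sweeps.

## Experiment problem sizes

The recovery experiments run at the package's standard test scale:
sweep recovery on 30 + 60-line panels, 2,000 SNPs over ten 2-Mb
chromosomes (200 windows, 5 planted sweeps per group), 20 simulation
seeds; QTL power on 120-line panels (40 + 80) with a QTL at a 15%
single-environment variance share, 50 seeds; heritability recovery over
50 phenotype draws on a 200-line panel; the type-I experiment simulates
kinship-correlated null phenotypes on five 120-line panels and averages
the genome-wide rejection rate at α = 0.05. A planted sweep counts as
recovered when a called window of the right group lies within two
windows of it; called windows farther than that from any same-group
planted locus count as false positives.

## Numerical details and degenerate inputs

Quantiles are empirical type 7. Undefined statistics (π ratio with zero
denominator, F<sub>ST</sub> with no eligible sites, D with S = 0, SV%
with zero mean, correlations of zero-variance traits) are NaN markers,
never silent zeros. PCA mean-imputes missing calls per site and uses
the plain covariance (allele-frequency scaling behind a flag); scores
are eigenvectors scaled by the root eigenvalues of the sample
covariance, so they match an independent SVD up to sign. The UPGMA
distance is 1 − IBS allele-sharing on dosages, pairs restricted to
sites non-missing in both samples; bootstrap support counts bipartition
recurrence over site-resampled trees. LD r² uses dosage correlation
(appropriate for near-homozygous inbreds, where genotype and haplotype
r² coincide); pairs with under 3 shared non-missing samples or a
zero-variance member are skipped and counted. The LD decay distance is
linearly interpolated between the flanking bin centers around the 0.2
crossing and reported as "not reached" (None) when the curve stays
above 0.2 within range.
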