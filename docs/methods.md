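# Methods

`bsaseq` simulates NGS-based bulk segregant analysis (BSA-Seq) of an F2
population and benchmarks nine QTL-detection statistics on the simulated
data. This note records the model, the defaults and why they were
chosen, the numerical conventions, and the limits of what the
simulations can show.

## Population and recombination model

One model chromosome carries `n_loci` evenly spaced biallelic markers
(default 10,000 over 100 Mbp, one marker per 10 kb; the locus with
0-based index *i* sits at position (*i*+1) x 10 kb). Parental alleles
are coded 0 (reference parent) and 1 (alternate parent). Each of the
`2 * n_individuals` gametic haplotypes (default 1,000) is an independent
mosaic of the two parental chromosomes built under the Haldane model of
recombination without interference:

* crossover count per gamete ~ Poisson(lambda), with lambda the
  chromosome map length in Morgans;
* crossover positions i.i.d. uniform over the physical chromosome
  (a uniform average recombination rate: genetic distance proportional
  to physical distance);
* starting parental origin Bernoulli(1/2).

The three default case studies span the observed range of crop
recombination rates: lambda = 0.90 (pearl millet, low), 1.30 (rice,
intermediate), 2.15 (foxtail millet, high). The model is restricted to a
single chromosome, a single F2 generation, no crossover interference and
no variation of recombination rate along the chromosome.

## Phenotype and QTL effect

The phenotype is `a * g + eps` with `eps ~ N(0, 1)` and `g` the
alternate-allele dosage (0/1/2) at a single QTL. The effect parameter
`k` is expressed in residual standard deviations, and two codings of the
per-allele-copy effect `a` are supported:

* **default `a = k`** — the standard additive-effect convention (the two
  homozygote classes differ by `2k` residual SD). At `k = 1` the QTL
  then explains a realized fraction (k^2/2)/(k^2/2 + 1) ~ 33% of the
  phenotypic variance. This coding reproduces the published benchmark
  distances and is used everywhere by default.
* **`per_allele_effect = k / sqrt(2)`** — calibrated so that the
  realized QTL variance equals `p(1-p)k^2`, the numerator of the
  explained-variance formula

      pi = p(1-p)k^2 / (p(1-p)k^2 + 1 - 1/n),

  which gives pi = 20% at k = 1 and 5.9% at k = 0.5 for p = 0.5,
  n = 500. `explained_variance` implements this formula verbatim.

The two calibrations are mutually inconsistent — the formula quotes 20%
while the default coding realizes 33% — and no single choice satisfies
both the formula and the published localization errors. We keep the
formula as the documented analytic calibration and the `a = k` coding as
the simulation default, because the benchmark distances are the
quantities this package exists to reproduce; the alternative coding is
one argument away.

## Bulks and sequencing noise

Bulks take the top and bottom `round(n * bulk_fraction)` individuals by
phenotype (default 10%: 50 individuals, 100 chromosomes per bulk; ties
broken towards the lower index; genotype information never enters bulk
selection). The true bulk allele frequency at a locus is the mean over
the bulk's chromosomes.

**Binomial noise (default).** Each parental-allele count per bulk per
locus receives one binomial draw with trial count `depth` (default 100,
the maximum read depth per allele) and success probability equal to the
bulk's true frequency of that allele:
`alt ~ B(depth, P)`, `ref ~ B(depth, 1 - P)` independently. The
per-locus total therefore fluctuates around `depth`. This choice, rather
than the fixed-total variant `ref = depth - alt` (available with
`per_allele=False`), is what reproduces the published behaviour of the
count-based statistics: with independent draws the G statistic exploits
the informative depth variation and localizes better than the delta-SNP
index, as in the published tables; with a fixed total the two are nearly
indistinguishable.

**Empirical noise.** Per-sample read depths harvested from a real VCF
(FORMAT `DP`, or summed `AD`) drive the alternative noise mode: for each
locus a random SNP row of the depth table is drawn, each bulked
chromosome is assigned one per-sample depth from that row (with
replacement) and contributes that many reads of its own parental allele.
Zero-depth loci are undefined (NaN) and carry zero weight in all
smoothers. A negative-binomial synthetic depth table (and VCF writer)
ships for tests, so no external download is needed; it reproduces
overdispersed coverage but not mapping bias, allele-specific error or
linked depth structure of real panels.

## Statistics

Per SNP, from the 2x2 table (alt/ref x high/low):

* `dsnp = alt_H/depth_H - alt_L/depth_L`, in [-1, 1];
* `g = 2 sum o ln(o/e)` with expected counts from the marginals and the
  `0 ln 0 = 0` convention;
* `edm = sqrt((fa_H - fa_L)^2 + (fr_H - fr_L)^2) = sqrt(2) |dsnp|`
  (exact identity, so edm and dsnp always call the same peak);
* `lod` — binomial likelihood-ratio LOD of per-bulk vs pooled allele
  frequencies; identically `g / (2 ln 10)`, a property of this default
  definition (the original tool's exact formula is not published; a
  fixed-null variant testing both bulks against a given frequency, e.g.
  0.5, is available via `null_p`).

Smoothed tracks:

* `tdsnp`, `gprime`, `smlod` — Nadaraya-Watson weighted means with
  tricube weights `w = (1 - (d/h)^3)^3` over loci within `h` of the
  focal position. The half-width `h` equals `window_bp` (default
  3 Mbp, i.e. the window spans +-3 Mbp). This follows the bandwidth
  convention of the locfit-based kernel smoother used by the QTLseqr
  G' implementation, where the `windowSize` argument is passed as the
  locfit bandwidth `h` — the distance at which the tricube weight
  reaches zero — and it reproduces the published smoothed-vs-raw
  accuracy gains; a half-window reading (+-1.5 Mbp) overshoots them.
  On evenly spaced loci the kernel is shift-invariant and the smoother
  is evaluated exactly by convolution; uneven spacing falls back to a
  windowed loop. We evaluate the weighted mean exactly at every locus
  (no evaluation grid or interpolation), which makes these tracks
  slightly *more* accurate at peak localization than reference
  pipelines that evaluate the fit on an adaptive grid.
* `afdexp` — block-regression smoothing: consecutive `window_bp` blocks
  are genetic units; each block contributes its mean dsnp at its mean
  position; a locally weighted linear regression (lowess, robustness
  iterations off) of block means on block positions is evaluated at the
  block positions and linearly interpolated to every locus. The span
  defaults to 3/n_blocks — the smallest span that keeps the local
  linear fit overdetermined. Wider spans (and lowess robustness
  iterations, which treat the QTL blocks as outliers) flatten the peak
  and degrade localization severely.
* `ed100_4` — `(sum of edm over the ed_window_snps-SNP window centred
  on the focal SNP)^4` (default 100 SNPs = 1 Mbp; 50 left, 49 right
  neighbours; truncated, unrenormalized edge windows; NaN contributes
  zero).

## Peak calling, accuracy, thresholds

The QTL call is the locus maximising the decision function — |value|
for the signed tracks (dsnp, tdsnp, afdexp), the value itself for the
non-negative ones — with ties broken to the lowest index. Localization
error is |called - true| position in kb.

The benchmark runs `n_replicates` independent pipeline passes with a
uniformly random QTL locus per replicate (drawn over all loci, no edge
margin) and reports mean/median/SD error per statistic. Replicate *i*
uses a fresh generator seeded `base_seed + i`, so results are
independent of execution order and trivially parallelizable. Degenerate
replicates are retained; genuinely failed ones (never observed under
the defaults) would be logged and re-drawn with the next unused seed.

Significance thresholds come from null simulations (`k = 0`): per
replicate, the 95% quantile (linear-interpolation definition, hence
bit-reproducible under seed) of the decision function across loci; the
threshold is the mean of the per-replicate quantiles. A pooled variant
(one quantile over all replicate-by-locus values) is available; the two
estimands differ under the strong within-replicate locus correlation at
low recombination, where the per-replicate empirical quantile of a
smooth track is pulled towards its median.

## Problem sizes and runtime

Full-scale published-style runs (1,000 accuracy replicates and 10,000
null replicates per condition) are supported from the CLI and API. The
shipped test suite and the acceptance script use 200 accuracy
replicates per map length and 1,000 null replicates per set — enough to
estimate mean errors to a few percent (Monte-Carlo SE ~5-8% of the
mean for per-SNP statistics) while a complete run stays in the minutes
range on one core. A single default-size replicate costs ~30 ms:
haplotypes are drawn as breakpoint lists and only the bulked
individuals' mosaics are expanded over all loci, and all statistics are
computed by vectorised table algebra and convolutions.

## Known limitations

* Single chromosome, single additive QTL, no dominance/epistasis, no
  interference, F2 only.
* The binomial and empirical noise models ignore mapping bias,
  genotyping error and bulk cross-contamination.
* The LOD implementation is a likelihood-ratio reconstruction, not the
  original tool's unpublished formula; under the default definition its
  peaks coincide with G's.
* Published accuracy values are reproduced within Monte-Carlo error for
  the per-SNP statistics and for ED100^4 and AFDexp; the
  exactly-evaluated tricube tracks run a few percent *more* accurate
  than their published counterparts — consistent with evaluation-grid
  interpolation in the reference smoother implementation, which we
  deliberately do not emulate — so relative smoothing gains measured
  here can exceed the published ones by a few points.
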