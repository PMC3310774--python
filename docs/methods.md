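# Methods

`bindqtl` analyses how DNA sequence variation shapes transcription-factor
(CTCF-like) occupancy across a three-generation family, and ships a
synthetic-data generator that emulates the complete study so every stage is
testable offline. This note records the models, the defaults and why they
were chosen, the numerical choices, and what the synthetic conditions do and
do not establish about real data.

## The synthetic study

### Pedigree and transmission

The default pedigree has 12 members: two founder couples, one second-
generation couple (one child from each founder pair), and six full sibs.
Founders carry eight distinct haplotype labels; meioses are simulated as
two-state Markov chains along the site catalog with Haldane switch
probability `0.5*(1-exp(-2d))`. Truth identity-by-descent (IBD) for each of
the 15 sib pairs at each site is the number of shared labels / 2, so IBD is
exact by construction (emulating a dense marker map rather than inferring
IBD from genotypes).

Adjacent catalog sites are separated by `site_genetic_spacing = 0.05`
Morgans by default. Binding sites in a genome-wide survey are scattered
across chromosomes, so neighbouring catalog entries segregate nearly
independently; tying the genetic map to the 3 kb physical spacing of the
synthetic contig would instead place the whole catalog in a single IBD
block and make the sib-pair permutation null degenerate. The physical
spacing is retained for the mappability genome. Setting
`site_genetic_spacing=None` recovers a single physically contiguous region.

### Sites, motifs and SNPs

Each site is a 134 bp resequencing window centred on a 14 bp core motif
sampled from a PWM frequency model (random strand) inside random flanks;
windows are embedded in a synthetic contig so that read-mappability can be
simulated. SNPs are planted uniformly over the window (per-site probability
0.9, with a 0.15 chance of a second SNP to exercise multi-SNP resolution);
the alternate allele is assigned to each of the 8 founder haplotypes with
probability 0.5, which fixes every member's genotype through transmission.

The default PWM is a synthetic CTCF-like matrix (GC-rich 14 bp consensus
with per-position confidences spanning strong, intermediate and degenerate
columns). It exists only to make the synthetic study self-contained; real
frequency matrices are inputs (`motifs.read_pwm`). The three multivalent
models used in scanning are the core plus two variants carrying an 8 bp
upstream module at configurable spacings, mirroring the factor's
mode structure; uniform spacer columns contribute zero log-odds.

### Occupancy model

The paper-level mechanism is a threshold: a sequence change matters when it
pushes a site's binding affinity across the occupied/unoccupied boundary.
We realise it as a logistic curve on PWM log-odds `a` (bits):

    p(a) = 1 / (1 + exp(-(a - a0)/s)),   defaults a0 = 14 bits, s = 1.5 bits

chosen so that PWM-sampled cores (mean score ~17 bits) sit on the upper
shoulder and single-base changes at strong columns (5-6 bits) can cross the
midpoint — i.e. the middle deciles of fitted heterozygote signal straddle
`a0`. Expected ChIP-seq count for a member is
`mu = depth * batch * (p(a1) + p(a2))/2` over its two haplotype scores
(depth 50 per replicate at full occupancy; batch factors 1.0/0.8); counts
are negative binomial with size `theta = 10` (variance `mu + mu^2/theta`).
Replicate structure is 2 per sample with one single-replicate sample.
This generative curve is this package's choice — the source analysis only
posits the threshold mechanism — and every curve-shaped comparison
(decile curves in particular) should be read with that in mind.

At heterozygous sites, pooled reads are partitioned binomially with
probability `p(a_alt)/(p(a_ref)+p(a_alt))` for the alternate allele,
producing allele-specific counts without read-level simulation.

A SNP's truth label is `functional` when its single-SNP relative occupancy
difference `|p(a_ref)-p(a_alt)|/max(...)` exceeds 0.2 (the simulator's
contract; the threshold is configurable). Labels near the threshold are
necessarily fuzzy: a "silent" SNP may carry a real sub-threshold effect.

### Resequencing, conservation

Pileups draw Poisson coverage (mean 50) per sample per SNP; each read
samples one chromosome and reports its base correctly with probability
`1 - base_error` (default 0.01), else one of the other three bases. The
conservation-like track adds Gaussian noise (sd 1.5) to the per-position
motif information content on the core (flanks are pure noise). The noise
level is set so the track is weakly informative about functional status, the
regime the real study reports for per-nucleotide vertebrate conservation at
these sites; at sd 0.5 the track would be a far stronger predictor than any
published conservation score behaves on this problem.

All randomness flows from one master seed through named substreams (one per
stage), so toggling any stage leaves the others' draws untouched and equal
configurations reproduce outputs byte for byte.

## Analysis stages

### Motif energetics

PWMs floor frequencies at a pseudo-frequency of 0.01 and renormalise before
taking log-odds (bits) against an i.i.d. background (flooring rather than
additive smoothing; both appear in the literature, flooring is exposed as
the default). Score p-values are exact under the background model, computed
by dynamic programming over the score distribution discretised at 1e-3
bits; the DP equals exhaustive enumeration within the bin width. Scanning
evaluates all three models, both strands, core-centre offsets within ±15 bp
of the window centre, and keeps the single best p-value (< 1e-2 to match);
ties break by raw score, then smaller |offset|, then + strand. Core
positions are indexed 0-13 from the motif's 5' end; the 44 bp protein-DNA
contact region is 20 bp 5' + core + 10 bp 3' by default (the full extent is
published, the split around the core is not; both offsets are config).

### Signal

Tag density is the count of reads (full 36 bp extents) overlapping a
sliding 150 bp window at 20 bp steps; per sample, one global linear factor
scales the median of bins with >15 reads to 25. Site occupancy is the
maximum normalized bin over the 14 bp core. The mappability filter
enumerates every 36-mer starting within ±147 bp of the site centre, once
per allele at each SNP, against an exact-match k-mer index of the genome
(both strands); a read is ambiguous when its sequence occurs at more than
one locus. Defaults: a site fails above 10% ambiguous reads (the source
filter is unquantified) or when two alleles' ambiguous fractions differ by
more than 0.05. Exact matching (not mismatch-tolerant alignment semantics)
keeps the filter deterministic and desk-scale; a mismatch-tolerant variant
is out of scope.

### Genotyping

Biallelic calls require ≥8× coverage per sample, Phred-scaled site quality
≥30, and ≥20% minor-allele reads for a heterozygote; sub-threshold minor
fractions yield the majority homozygote (keeping the site testable, the
behaviour of common pileup callers). A third allele above 5% of pooled
reads voids the site. Site quality is a synthetic stand-in: the Phred-scaled
binomial tail probability of the minor-allele count under a 1% miscall
model — it increases with depth and allele purity but is not a
sequencing-caller's quality. Sites must segregate Mendelianly through every
trio of the pedigree (missing genotypes unconstrained); a single violating
trio drops the site. SNPs are polarized by an outgroup allele when it
matches one of the two alleles.

### Association

Counts at a testable site (mappability pass; genotyped in ≥6 samples; ≥12
data points with ≥4 in each of ≥2 genotype classes) are modelled as
NB(mu, theta), `log mu = intercept + beta*g + replicate`, `g` = copies of
the alphabetically later allele. Significance is the Wald test of the
additive genotype term. Where class sizes permit (≥4 points in both
collapsed classes), both dominant collapsings of the heterozygote are also
fitted and the AIC winner is reported as the effect's characterisation
(model, slope, fitted heterozygote signal); an ordinary linear fit on the
additive design supplies r².

Dispersion handling is where small samples bite. Per-site theta is
estimated by alternating IRLS for the coefficients with one-dimensional
maximization of the Cox-Reid adjusted profile likelihood for theta (the
unadjusted MLE is biased high at ~24 points, which underestimates the Wald
standard errors and inflates the extreme p-value tail several-fold — fatal
for FDR control at 1%). When ≥40 sites are tested together, per-site
dispersions are further squeezed toward a robust cross-site mean-dispersion
trend (quantile-binned medians on the log-log scale; prior weight 20
residual df), after which the normal Wald reference is used; a lone site
falls back to a t reference on its residual df. Measured on null synthetic
sites, the test's type-I error at nominal 0.05 sits near 0.05-0.07 and the
p<0.001 tail is calibrated-to-conservative.

q-values use Storey's estimator (pi0 from a lambda grid 0.05-0.90 with
cubic-spline smoothing) by default, Benjamini-Hochberg as the alternative;
the headline threshold is FDR 1% with 5% and 0.1% presets. Multi-SNP
windows resolve to the SNP with more data points, then contact-region
membership, then the lowest fitted p (the site flagged
position-ambiguous). Non-converged fits are excluded before FDR.

### Allele-specific occupancy

Heterozygous site/sample records need ≥13 pooled reads and equal allele
mappability. The test is the plain one-degree chi-squared against a 50:50
split (no continuity correction); per site, the sample with the most reads
is the representative (ties: first sample id), and q-values are computed
over representatives. FDR presets 0.1% and 0.005%.

### Differential occupancy and linkage

Differential sites come from an in-house NB likelihood-ratio test of a
sample effect against a replicate-only null. Dispersion per site is a
moment estimate from within-sample replicate variability on size-factor-
normalized counts (residual df corrected), which true sample effects cannot
contaminate, then replaced by the robust cross-site trend. The chi-squared
reference runs slightly liberal at 12 points (raw rate ~0.05-0.10 at
nominal 0.05); BH adjustment at 5% absorbs this in practice. Sites without
replicate structure in at least half the samples are excluded
("no dispersion estimate"), as are all-zero sites.

Counts at differential sites are variance-stabilised with
`v(x) = 2*sqrt(theta)*asinh(sqrt(x/theta))`, standardised per site to mean
0 / sd 1 over all points, then replicates are averaged. Haseman-Elston
regression pools squared sib-pair trait differences over all sites and all
15 pairs against IBD bins {0, 0.5, 1} (entries with IBD uncertainty >0.05
excluded); the original squared-differences estimator is used deliberately
— simple and robust — rather than higher-powered variants. Significance is
one-sided (negative slope) by permutation: whole per-site IBD vectors are
reassigned without replacement to per-site difference vectors (sampling
with replacement is an option; the source wording does not disambiguate),
preserving the correlation structure of 15 pairs drawn from one family,
with the add-one estimator `p = (1 + #{slope_perm <= slope_obs})/(n+1)`.
The analysis is run separately on SNP-associated and unassociated
differential sites. Note the generator contains no heritable variation
beyond SNP effects, so the unassociated stratum is a true null here (slope
~0), unlike the real study where residual heritable signal remains.

### Buffering analyses

The substitution grid reports, per (core position, unordered allele pair),
the proportion of SNPs associated with occupancy change at FDR 1%,
suppressing cells observed at fewer than 3 sites. The decile curve ranks
sites by fitted heterozygote signal into 10 equal-count bins (stable-order
ties) — under the logistic generator it shows the interior maximum that the
threshold mechanism predicts: the weakest sites have too little signal to
lose, the strongest are buffered. Perturbation-vs-strength bins |allele
delta| by motif score among significant SNPs (with a linear trend test and
a non-significant companion table). Mutual information between the base at
context position j and the affected flag (FDR 5%) of SNPs at position k is
plug-in MI in bits over single-SNP, motif-matched sites, rows with ≥5 SNPs;
the published resampling significance is implemented as label permutation
(2000 iterations, add-one p, q-values over all pairs), with a
case-resampling bootstrap behind a flag. Clustering of standardized
occupancy over the sibs is Ward-linkage hierarchical (a linkage the source
does not name; Ward chosen for stability), cut at k=3.

### Predictor evaluation

Reference set: SNPs in the contact region with an association result;
labels: q below the (parameterized) FDR, default 1%. ROC curves group tied
scores (deterministic); AUC equals the normalized Mann-Whitney U, and both
routes are implemented and asserted equal. PPV is reported over a cutoff
grid. `compare_predictors` evaluates the PWM allele delta against the
conservation track on the identical SNP set with a site-resampling
bootstrap CI on the AUC difference. Under the default conditions the delta
is the far better predictor — the generator's effects are
threshold-determined while conservation carries only noisy position-level
information — reproducing the published ordering, though both absolute
AUCs run higher here than on real data because the synthetic truth is
cleaner than biology.

## Problem sizes and determinism

Default scales (600 surveyed sites end-to-end; 2000+ sites for null
calibration; 600 for planted recovery; 100 repeat runs at 260 sites for the
predictor-ordering check) were chosen so the full study and its calibration
experiments complete in minutes on one CPU while leaving binomial noise
well inside the asserted margins. `run_pipeline` serialises its
configuration, logs per-stage row counts with a configuration hash, and is
byte-reproducible given seed and configuration.

## Known limitations

- The generator plants no indels, CNVs, linkage-disequilibrium structure
  beyond pedigree transmission, or non-SNP heritable variation; chromosome
  X and mitochondria are absent by design.
- Truth labels use a hard relative-occupancy threshold; detection of real
  sub-threshold effects is counted against empirical FDR only when the true
  effect is exactly zero.
- The chi-squared allele-specific test and the differential LRT are
  asymptotic; both are rank-faithful but their extreme tails are
  approximate at minimum coverage.
- Passing tests establish correctness of the machinery under the stated
  generative model — saturating occupancy, i.i.d. background flanks, clean
  allele assignment. Real ChIP-seq adds fragment-length effects, copy
  number, mapping artefacts beyond exact-duplicate ambiguity, and motif
  mis-specification, none of which the synthetic conditions probe.
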