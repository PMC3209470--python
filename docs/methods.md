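# Methods

`senseq` re-implements, as a tested library plus analysis drivers, the
statistical pipeline of a low-replicate bulk mRNA-seq comparison: wheat flag
leaves of GPC-RNAi knock-down plants against wild-type sister lines at an
early stage of monocarpic senescence, with isogroups (contig sets merging
splice variants, homoeologs and close paralogs of one gene) as the unit of
analysis.  This note records the models, the tunable parameters, the numerical
choices, and what the synthetic data can and cannot show.

## Count model and testing

Counts `K_ij` (isogroup *i*, library *j*) are modelled as negative binomial
with mean `s_j * q_ig` and variance `mu + alpha * mu^2`, where `s_j` is the
library size factor, `q_ig` the common-scale expression of the feature in the
library's genotype group *g*, and `alpha` the dispersion.

**Size factors** are the median-of-ratios estimator: `s_j = median_i
(K_ij / geomean_i(K))`, with the geometric mean computed in log space and
features containing any zero excluded (their geometric mean is zero, so the
ratio is undefined or infinite).  An even number of eligible features uses the
midpoint of the central pair, keeping the estimator deterministic.  A
normalized matrix has no residual systematic scaling: re-estimating factors on
it gives a constant vector (pinned at the geometric mean of the original
factors).

**Two NB tests** share one conditional scheme.  For a feature, the two group
sums `K_A`, `K_B` are treated as NB with means proportional to the summed
size factors (`mu_A = T * S_A / (S_A + S_B)` given the total `T`) and
variance `mu_g + alpha * (sum_j s_j^2 / S_g^2) * mu_g^2` — the exact
mean/variance of a sum of independent NB counts with a shared dispersion.
The two-sided p-value conditions on `T`: it is the total conditional
probability of all splits `(k, T-k)` whose probability does not exceed the
observed split's.  This "sum of no-more-probable outcomes" definition is
symmetric in the groups and reduces to the binomial two-sided test in the
Poisson equal-factor limit (`(0, 10)` with one sample per group gives
`2/1024`).  Probabilities are compared with a `1e-12` relative tolerance so
ties of equal-probability splits are included deterministically.

The *pooled* variant uses a single dispersion for all features; the *local*
variant evaluates a fitted mean-variance relation `w(mu)` at the feature's
common-scale mean and converts it to an effective dispersion
`(w(mu) - mu) / mu^2`, falling back to Poisson when `w(mu) < mu`.

**Common dispersion** is estimated by maximizing one shared NB likelihood
over all non-zero features, with per-feature per-group means profiled by the
method of moments.  Plain profiling is biased low at 3–4 replicates (each
profiled mean consumes information the likelihood does not see), so the
objective carries the Cox–Reid adjustment: minus half the log Fisher
information of each profiled group mean, `0.5 * log sum_j s_j^2 /
(mu_ij + alpha * mu_ij^2)`.  With the adjustment, `alpha = 0.2` is recovered
to about `+/- 0.005` at 2000 features (the tests assert `+/- 0.05`); without
it the estimate is ~30% low and the pooled test is anti-conservative.  The
optimum is searched on `[0, 10]` (bounded scalar minimization, `xatol 1e-6`)
and floored at zero.

**Local variance fit**: per-feature pooled within-genotype sample variance of
the normalized counts is regressed on the pooled mean with a lowess smoother
(`frac = 0.3`) in log-log space, followed by isotonic regression to enforce a
non-decreasing relation.  Smoothing `log(S^2)` underestimates the mean
variance (Jensen); the fitted curve is raised by the normal-theory bias of a
log chi-square, `log(nu/2) - digamma(nu/2)` at the pooled degrees of freedom
(`nu = 5` for 4 + 3 samples, a factor of about 1.24).  Fewer than 20 usable
features is an error (the smoother is underdetermined).

**Mann–Whitney–Wilcoxon**: exact mode enumerates all `C(n_A + n_B, n_A)`
label assignments of the U statistic; normal mode uses the Gaussian
approximation with tie-corrected variance; `normal_cc` adds the 0.5
continuity correction.  The consensus default is **normal without continuity
correction**, a deliberate choice: with 3 vs 4 samples the most extreme
two-sided exact p is `2/35 ≈ 0.057` and the corrected normal value is
`≈ 0.052`, so under either variant a `p <= 0.05` filter would eliminate every
feature; the uncorrected normal value for the extreme split is `≈ 0.034`, the
only standard two-sided variant under which the filter can operate at this
design size.

**Multiple testing**: Benjamini–Hochberg step-up, implemented directly
(sorted `p_(i) * m / i`, cumulative minimum from the top, capped at 1) and
cross-checked in tests against a brute-force oracle over all rejection
thresholds and against `statsmodels.multipletests`.

**Fold change** is the ratio of common-scale group means (WT / RNAi).  When
exactly one mean is zero, 0.5 is added to both before forming the ratio;
both-zero features are excluded from calls (NaN).  The convention "up" means
higher in WT, i.e. up-regulated during senescence.

**Consensus call**: direction of fold change iff `q_pooled <= 0.01` and
`q_local <= 0.01` and (if enabled) `p_mww <= 0.05` and fold `>= 2` or
`<= 0.5`.  All comparisons are inclusive — a p-value printed as exactly 0.050
counts as significant.  Both the two-test intersection and the three-test set
are reported.

## Variance-stabilizing transform

For distance-based analyses, normalized counts are mapped through
`tau(kappa) = ∫ d(mu) / sqrt(w(mu))` with `w` the fitted variance function.
For `w = mu` this is `2*sqrt(kappa)`; for `w = mu + alpha*mu^2` it is
`(2/sqrt(alpha)) * asinh(sqrt(alpha*kappa))`; both closed forms are test
oracles at `1e-6` relative.  The integral is evaluated by composite 10-point
Gauss–Legendre quadrature on an 801-point log-spaced grid (after the
substitution `mu = e^t`), completed from the nearest node below each
requested point with the same rule — effectively exact for smooth `w` and
fast enough to transform whole matrices.  Outside the fitted domain `w` is
extended linearly with the boundary derivative; below the domain the
extension is floored at a proportional (Poisson-like) decay `w_lo * mu / lo`,
which keeps `w` positive and `1/sqrt(w)` integrable where a raw linear
extension could cross zero.  Zeros are mapped through a left linear extension
of `tau`, preserving monotonicity.

## Permutation null

Empirical type-I error of the whole calling procedure: enumerate all label
assignments that split the 4 + 3 libraries into mixed pseudo-groups of
(2 RNAi + 2 WT) and (2 RNAi + 1 WT) — `C(4,2) * C(3,2) = 18` — draw 10
without replacement (seeded; the original selection is unknowable), re-run
normalization and both NB tests per assignment, and report mean ± SE of the
significant counts and their intersection.  The MWW stage is excluded by
default because it was layered onto the calling pipeline after the
permutation analysis; a flag includes it.  The empirical rate is
`100 * mean intersection count / true-label discoveries`, reported to one
decimal (15 of 815 gives 1.8%).  Enumeration returns the full product of
binomial coefficients; for symmetric shapes an optional flag collapses
assignments differing only by swapping the pseudo-group labels.

## Read QC and the contamination sentinel

Reads are trimmed to the prefix strictly before the first failed-quality
symbol (`'B'` in the Illumina 1.3+ convention, matched literally, not by
score; the exclusive cut is the conservative reading and is configurable),
then filtered: length < 40 nt fails, GC outside the closed interval
[20%, 80%] fails.  Sentinel counting declares a read a match only if it is an
exact substring of the sentinel sequence or of its reverse complement (the
libraries are unstranded; strand matching can be disabled) — no mismatches,
no gaps.  Any sentinel evidence (count > 0) in a library whose genotype is
not expected to carry the construct flags that library for removal; carriers
are never flagged.  Counting is per read occurrence, duplicates included.

## qRT-PCR quantification and power

Linearized expression is `2^-((Ct_target - Ct_reference) - dCt_calibrator)`
— copies per copy in the calibrator sample.  Primer efficiency comes from
the least-squares slope `b` of Ct on log10 dilution: `(10^(-1/b) - 1) * 100`.
Genotype comparison defaults to the pooled-variance two-sample t-test on
linearized values (the rank test is available by flag); per-gene CVs are
summarized with a t-based 95% confidence interval of the mean.

Analytic power places the group means at 1 and `fold_change` with SDs
`cv * mean`, pools them as `sqrt((sd1^2 + sd2^2)/2)`, and evaluates the
two-sided t-test via the noncentral t distribution with noncentrality
`(fold - 1)/pooled_sd * sqrt(n/2)` and `2n - 2` degrees of freedom.  This is
the unique simple CV-based model consistent with both anchor values the
design targets (≈75% power at CV 50% and ≈95% at CV 38% for a 2-fold change
with 10 replicates); a 2000-replicate Monte-Carlo oracle agrees within 2%
across a grid.  Efficiency correction of the ddCt transform is not applied
(per-primer efficiencies are stored for reporting only).

The packaged 22-gene validation panel ships as reference data
(`senseq/data/qpcr_validation_table.tsv`): mRNA-seq and qRT-PCR WT/RNAi
ratios with p-values at 12 and 22 days after anthesis.  Its summary (9 of 22
significant at 12 DAA; 14 genes beyond the 2.5×/0.4× ratio bounds, 9 of
those significant = 64%; 2 genes newly significant at 22 DAA) depends on the
inclusive `<= 0.05` threshold: one panel gene sits exactly at p = 0.050.
The cross-platform ratio correlation is reported descriptively only; its
published scale and axis adjustment are under-specified, and raw vs log2
recomputation gives nearby but different values.

## Downstream structure and category tests

Sample structure uses Euclidean distances between variance-stabilized
profiles, agglomerative clustering (complete linkage by default — only the
distance, not the linkage, is fixed by the design; average and single are
available), a Newick export of the dendrogram, and centered PCA (SVD) with
percent variance per component.  The Kolmogorov–Smirnov comparison of
functional-category distributions treats two aligned category-percentage
vectors as samples over a common ordered axis — a descriptive use of the
two-sample statistic, flagged as such.  The up/down balance test is a
one-degree-of-freedom chi-square against 50:50, without continuity
correction by default (a flag adds it).

## Synthetic data: what it emulates, what it does not

The generator draws NB counts for 4 RNAi + 3 WT libraries (the post-QC
design; the drivers simulate 4 + 4 and let the sentinel stage remove the
contaminated WT library).  Defaults emulate the study conditions: 5.5% DE
features, 30% of them higher in WT, median |log2FC| = 1 (|log2FC| is
log-normal around the location, so the median is exact), log-normal baseline
means with median 100 and `sdlog = 1` (a realistic bulk RNA-seq dynamic
range), dispersion `alpha(mu) = alpha0 + alpha1/mu` with constant
`alpha0 = 0.1` by default, and library size factors log-uniform on
[0.7, 1.4] so normalization always has work to do.  The DE effect is split
symmetrically (`±lfc/2`) around the baseline mean.  qPCR panels draw
linearized values with SD = CV × group mean (default CV 44%), clipped at a
small positive floor — clipping perturbs the group moments far less than
redrawing, keeping empirical rejection rates close to the analytic power.
Ct values are back-computed so the ddCt transform recovers the values
exactly.  Reads get failed-quality tails from a known position and sentinel
reads are exact (possibly reverse-complemented) substrings, so trimming,
filtering and sentinel counts have generator-side truth.

All randomness flows from a single seed through one named
`numpy.random.Generator`; identical configurations are byte-identical.

Not emulated: real sequence content of wheat transcripts, homoeolog
structure, positional/GC biases within reads, mean-correlated library
composition effects, batch structure, or the long-read assembly stage.
Passing tests therefore demonstrate that the statistics behave as specified
under the assumed NB model — not that the model captures every artifact of
real libraries.  In particular the published headline set sizes (815/691/431
genes) are properties of the real data and are not reproduction targets;
what is reproducible is the arithmetic and calibration around them.

## Problem sizes and degenerate inputs

Calibration and recovery checks run at 2000 features (null p-value fractions
are compared with three-binomial-SD bands; dispersion/variance recovery at
the tolerances above); structure recovery uses 20 seeds of 1000 features
with strong effects (25% DE, median 5.7-fold).  These sizes give stable
statistics while keeping the full suite and the acceptance script in the
tens of seconds.  Degenerate inputs are defined, not crashed on: all-zero
features get p = 1 and no call (the feature universe stays stable for
percentage reporting), a zero feature total gives p = 1, constant groups
give MWW p = 1, a constant matrix gives a degenerate PCA, and a single
permutation reports its SE as unavailable.
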