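# Methods

This note documents the models, conventions and defaults behind
`aneuclone`, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Data model and coordinate conventions

Segment files use the SEG convention on disk (1-based inclusive) and are
converted to 0-based half-open intervals in memory, so every length is
`end - start`; BED arm definitions are 0-based half-open throughout. A
whole-chromosome record is synthesized per chromosome as the span of its
arms, so analyses can use either the q arm or the whole chromosome as the
denominator region; the region actually used is recorded in pipeline
output.

Copy-number input encoding must be declared by the caller: `"copies"`
takes the cn column at face value, `"state"` maps an HMM state *k* to
*k − 1* copies (states 1 and 2 are then the deletion-like copies 0 and 1).
The two encodings differ by one everywhere, so guessing silently would
corrupt every deletion call — hence no auto-detection.

Newick trees are rooted; missing branch lengths default to 1 (the least
informative choice that still supports the Brownian null), polytomies are
resolved to binary nodes by inserting zero-length branches, and duplicate
tip labels are an error.

## Cohort prevalence and its permutation nulls

Deletion means arm call = −1. The pooled permutation test treats per-sample
deletion indicators as exchangeable across the cohort: each permutation
reshuffles the pooled indicator vector and re-partitions it into groups of
the original type sizes. The per-type permuted count is therefore exactly a
multivariate hypergeometric draw, and that is how it is sampled (verified
equivalent to literal shuffling in the test suite). The p-value is the
plug-in upper-tail estimator `count / B`; a zero count is displayed as
`< 1/B` while the numeric field stores 0. BH adjustment runs across cancer
types within one arm. Default `B = 10,000`.

The WGD-excluded variant removes whole-genome-doubled samples from both
numerator and denominator before testing, because a heterozygous arm loss
on a doubled genome no longer implies loss of heterozygosity.

The rank test shuffles cancer-type labels instead and re-ranks per-type
prevalences (rank 1 = highest). Ties take the minimum (best) rank, which
is the conservative choice for the focal type's p-value as defined
(`p = #{rank_perm ≤ rank_obs}/B`). The rank test is reported unadjusted.

A design point left open by the ambiguity of "shuffling the combined
pool": the implemented null preserves the observed group sizes
(re-partition reading). The alternative — comparing each type to a single
pooled-prevalence binomial null — is not built.

## Co-occurrence

Per cancer type, the 2×2 table of arm loss × carrier status is tested with
a two-sided Fisher exact test: the sum of hypergeometric probabilities of
all margin-compatible tables whose probability is at most that of the
observed table, with a 1e-7 relative tie tolerance (floating hypergeometric
products need one; the suite checks agreement with exact-rational
enumeration for every table of total ≤ 40). The odds ratio is the sample
cross-product with the Haldane 0.5 correction when a cell is zero; a zero
margin makes the table degenerate (p = 1, OR undefined). BH families are
all cancer types for one (arm, gene) pair, and at a given FDR threshold
OR > 1 ⇒ "co-occurrence", OR < 1 ⇒ "mutual-exclusivity".

## Single-cell statistics

All per-cell quantities are weighted by segment length over the *segmented*
(covered) genome, never nominal chromosome length — uncovered sequence
carries no information, and partial coverage otherwise biases fractions
downward. All threshold comparisons are inclusive (≥), applied uniformly.

- `arm_deletion_fraction`: covered and deleted (cn ≤ cutoff, default 1)
  lengths of segments clipped to the region; undefined (not an error) when
  nothing covers the region.
- `baseline_cn`: length-weighted *lower* median copy-number state — the
  smallest state whose cumulative length reaches half the genome. The
  lower-median convention keeps the baseline an attained integer state
  (~2 in diploid cells, ~4 in WGD/endopolyploid cells).
- `genome_burden`: loss/gain fractions are lengths at least one copy
  below/above baseline; the typical deviation is the length-weighted lower
  median of |cn − baseline| over altered segments (0 when nothing is
  altered). `wgd_like` flags baseline ≥ 3: 3 is the smallest baseline
  inconsistent with diploidy, and the cutoff is exposed as a parameter.
- `classify_states_absolute`: baseline-independent megabase totals at
  copies ≤ 1 (deletion-like) and ≥ 3 (gain-like).

All of these are invariant to splitting segments into equal-copy-number
pieces (merge invariance), which the suite asserts.

## Fritz–Purvis D

Ancestral values are estimated by contrasts-style weighted averaging down
the binary tree (child values weighted by inverse branch length, with the
standard correction extending the parent's effective branch by
`b_L b_R / (b_L + b_R)`); d sums |sister difference| over internal nodes.
Because each nodal value is a fixed linear functional of tip values,
`d(x) = Σ|C x|` for a precomputed contrast matrix, and both nulls reduce
to matrix products — 1000 permutations on hundreds of tips cost
milliseconds, which is what makes the calibration suites cheap.

Nulls, with the trait's positive count k held fixed:

- random: tip states shuffled uniformly;
- Brownian: increments simulated along branches with variance equal to
  branch length from root value 0, then the k largest tip values set to 1
  (by Brownian symmetry the tail choice does not affect the d
  distribution; fixing it makes runs reproducible).

`D = (d_obs − mean d_B)/(mean d_R − mean d_B)`; `p1 = #{d_R ≤ d_obs}/B`
(lower tail: small p1 ⇒ more clustered than random) and
`p0 = #{d_B ≥ d_obs}/B` (upper tail: small p0 ⇒ more over-dispersed than
Brownian). This is the unique tail pairing under which a clustered clonal
trait gives small p1 with large p0, and a scattered trait the reverse.
Default `B = 1000`. Zero-length branches receive an epsilon of 1e-8 of the
mean branch length before weighting; an all-equal trait is an error; a
trait with fewer than 3 tips in either state is flagged `unstable` —
extreme D values under such sparsity reflect the tiny support of the null
d distributions, not real structure. Branch lengths are used by default;
a unit-branch-length convention is available via `use_branch_lengths=False`
(D's double-null scaling makes the calibration anchors hold under either).

Calibration: traits generated by the random mechanism average D ≈ 1 and
traits generated by the Brownian mechanism average D ≈ 0 (the acceptance
script recomputes both on a fixed 200-tip tree with k = 60, 100 traits,
1000 permutations each).

## Burden regression

Pooled OLS of per-cell altered fraction on intercept + del13 + del17 +
wgd_like, with HC3 sandwich standard errors
`(X'X)^{-1} X' diag(e_i²/(1−h_ii)²) X (X'X)^{-1}` and t tests on n − p
degrees of freedom (the conservative finite-sample convention). Indicators
with no variation in the data are dropped and reported (`dropped_terms`);
an observation with leverage 1 (e.g. a single deletion-positive cell)
makes HC3 undefined and is an error, which the pipeline records in the
bundle rather than failing the whole track. The fit stands on statsmodels;
the suite checks it against an explicit-loop sandwich.

## Synthetic-data generator

The generator defines the conditions under which everything above is
validated.

**Cohorts.** Per cancer type: deletion calls are Bernoulli at the
configured prevalence; WGD flags are independent Bernoulli; carrier flags
are drawn first and an arm linked to a gene is drawn conditionally so that
the population 2×2 table has the configured odds ratio (the 2×2 joint is
the Plackett solution from margins + OR; θ = 1 reduces to independence).
One gene per arm; prevalences and odds ratios are recovered by the suite
at n = 10,000 and n = 5,000 respectively.

**Cell populations.** A pure-birth (Yule) tree — exponential waits at rate
k·λ, one final Exp(nλ) interval to the present, ultrametric — carries
copy-number evolution from a diploid root. Deletion events decrement copy
number by 1 (floor 0); a deletion event removes a contiguous fraction of
the target region drawn uniformly from `event_fraction_range`, default
(0.6, 1.0) so every event clears the 50% calling threshold and truth
recovery is exact when noise is off. Three architectures:

- *clonal*: one event on the internal branch whose clade is nearest a
  quarter of the tips, inherited by all descendants;
- *dispersed*: independent events on terminal branches, each tip affected
  with probability 1 − exp(−r·b) for pendant length b (default r = 0.6,
  about a quarter of tips on a default tree);
- *sparse*: one uniformly chosen tip.

Background events (deletions/gains of 5–30% of a random non-target arm)
arise as a Poisson process along branches and are inherited; they are kept
off the target chromosome so the returned truth map is governed solely by
target events and WGD. Optional WGD doubles all states of one clade of
tips *after* events — so a heterozygous target deletion (1 → 2 copies) is
masked, mirroring why WGD samples are excluded in the cohort analysis.

What the generator does *not* emulate: sequencing noise and HMM
mis-segmentation, subclonal (non-integer) copy number, allele-specific
states and copy-neutral LOH, focal events below arm scale on the target,
and realistic chromosome-level event-size distributions (the event
fraction range is a modeling choice, not an estimate). Passing tests
therefore demonstrate correctness of the statistics under a clean
generative model, not robustness to real-data artifacts.

One emergent property worth knowing: in the dispersed scenario, D averages
around 0.8 rather than exactly 1, because pendant-branch lengths on an
ultrametric tree are phylogenetically autocorrelated and event probability
is proportional to branch length — nearby tips have correlated acquisition
probabilities, a mild real clustering signal. The clonal/dispersed
separation (median D well below 0.5 vs well above) is unaffected.

## Problem sizes and determinism

All randomness flows from one integer seed through named per-stage
streams, so pipeline manifests make runs byte-reproducible. The test suite
uses reduced but statistically adequate sizes chosen as a power
calculation: 200-seed type-I-error and uniformity checks at B = 400,
scenario separation over 50 runs per scenario at 100 tips, coefficient
recovery at n = 2,000 over 10 seeds, and the full Fisher enumeration sweep
for tables of total ≤ 40. The acceptance script runs the D calibration at
its stated size (200 tips, 60 positives, 100 traits, 1000 permutations).

## Known limitations

- The pooled permutation test assumes exchangeability of samples across
  types; covariates (purity, stage, assay) are out of scope.
- Only one gene may be linked per arm in the cohort generator; multi-gene
  joint odds ratios are not modeled.
- The bundled arm table is an approximate hg19-style map for convenience;
  treat arm boundaries as user input for any real analysis.
- The burden regression is pooled across cells with no sample-of-origin
  random effect; inference is robust to heteroskedasticity but not to
  within-sample correlation.
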