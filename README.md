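# aneuclone

Analysis toolkit for **chromosome-arm deletion prevalence and clonal
architecture** in cancer genomics, centered on the arms harboring the
*BRCA1* (17q) and *BRCA2* (13q) tumor-suppressor genes.

Germline *BRCA1/2* carriers lose the wild-type allele most often through
arm-level deletion of chr17q or chr13q. Two complementary questions follow:

1. **Cohort level** — is the deletion of a given arm more prevalent in some
   cancer types (breast, ovarian) than chance would allow, and does it
   co-occur with germline carrier status?
2. **Cell level** — within a tumor or pre-malignant tissue, do the cells
   carrying the deletion form a single clade on the cell phylogeny (an
   early, clonally inherited event) or are they scattered (late,
   independent acquisitions)?

`aneuclone` implements both tracks over standard text formats (BED arm
definitions, SEG-dialect copy-number segments, TSV cohort tables, Newick
trees), plus a synthetic-data module that generates cohorts and simulated
cell populations with known ground truth, so the full pipeline is testable
without any restricted-access data.

## Methods at a glance

- **Prevalence permutation test.** For arm *a* and cancer type *t* with
  $n_t$ samples and $d_t$ deletions, prevalence is $\hat p_t = d_t/n_t$.
  The null reshuffles the pooled vector of per-sample deletion indicators
  across all types and re-partitions it into the original group sizes;
  $p = \#\{\hat p_t^{perm} \ge \hat p_t\}/B$, Benjamini–Hochberg-adjusted
  across types. A WGD-excluded variant drops whole-genome-doubled samples
  (where a single-copy loss no longer implies LOH).
- **Rank permutation test.** Cancer-type labels are shuffled; the focal
  type's prevalence *rank* (1 = highest, ties take the best rank) is
  recomputed per permutation and $p = \#\{rank^{perm} \le rank^{obs}\}/B$.
- **Co-occurrence.** Two-sided Fisher's exact test of the 2×2 table of arm
  loss × germline carrier per cancer type, with Haldane-corrected sample
  odds ratio and BH FDR within each (arm, gene) family.
- **Single-cell statistics.** Per cell: deletion fraction of an arm =
  length of segmented arm at copy number ≤ 1 over segmented arm length
  (called deleted at ≥ 50% by default); baseline ploidy = length-weighted
  lower-median copy-number state; loss/gain/altered fractions and typical
  deviation relative to that baseline.
- **Fritz–Purvis D.** For a binary deletion trait on a rooted binary tree,
  $d$ = sum over internal nodes of |sister-clade value difference| after
  contrasts-style nodal averaging, scaled between the mean of a
  random-shuffle null and a Brownian-threshold null:
  $D = (d_{obs} - \bar d_B)/(\bar d_R - \bar d_B)$, so $D \approx 1$ for a
  random trait and $D \approx 0$ for Brownian (clumped, heritable)
  evolution; $p_1$ is the lower tail of the random null (small ⇒ clustered)
  and $p_0$ the upper tail of the Brownian null.
- **Burden regression.** Pooled OLS of altered fraction on chr13/chr17
  deletion status and WGD-likeness with HC3 heteroskedasticity-robust
  standard errors.

See `docs/methods.md` for assumptions, defaults and numerical conventions.

## Worked example

Simulate a clonal cell population on a 60-tip birth-process phylogeny and
test the clonality of chr17q deletions:

```sh
cat > cells.yaml <<EOF
n_tips: 60
scenario: clonal
target_region: 17q
background_event_rate: 0.2
seed: 9
EOF
aneuclone simulate-cells --config cells.yaml --out-prefix run1
aneuclone sc-arm   --seg run1.seg.tsv --region 17q --out arm.json
aneuclone phylo-d  --tree run1.nwk --seg run1.seg.tsv --region 17q \
                   --n-perm 500 --seed 2 --out d.json
```

The run above prints/writes (numbers from this exact invocation):

- `arm.json`: at the 50% threshold, 14 of 60 cells (23.3%) carry a chr17q
  deletion — the simulated clone, a clade of 14 tips;
- `d.json`: `D = -1.282, p1 = 0.0, p0 = 1.0, k_positive = 14` — the trait
  is far more clustered than random ($p_1 = 0$, i.e. below $1/B$) and
  entirely consistent with clonal (Brownian-like) inheritance, exactly the
  signature of an early deletion inherited by one expanding lineage.

The cohort track mirrors this: `simulate-cohort` → `prevalence` /
`rank-test` / `cooccur`. On a synthetic three-type cohort (ovarian-like
type with 30% chr17q deletion prevalence and a built-in odds ratio of 3
with BRCA1 carriers vs two 8% background types), `prevalence` reports the
enriched type at `p < 1/B`, FDR 0, and `cooccur` classifies the
deletion–carrier pair as "co-occurrence" — while the background types stay
at `p = 1` / "none".

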