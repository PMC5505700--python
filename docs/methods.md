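# Methods

This note documents the models implemented in `tsc2sig`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about behaviour on real data.

## Study design being modelled

The fibroblast arm models a paired experiment on neonatal mouse dermal
fibroblast lines: `n_lines` wild-type (WT) and `n_lines` *Tsc2*-null (KO)
lines, each cultured with vehicle and with the mTORC1 inhibitor sirolimus,
giving 4·`n_lines` samples paired within line.  Three contrasts are
analysed: KO vs WT among vehicle samples (two-class), and sirolimus vs
vehicle within KO and within WT (paired).  The default `n_lines = 3`
matches the design this pipeline targets; it is also the smallest n at
which the permutation machinery is informative (20 label assignments, 8
sign patterns).

The cohort arm models a tumor collection (default 391 tumors, of which 43
carry a non-silent *TSC1*/*TSC2* mutation, i.e. frac_mutant = 43/391 ≈ 11%)
whose expression is scored against the mouse-derived signature after
ortholog mapping.

## SAM differential expression

The implementation follows the standard SAM procedure:

* Input values are log2(x+1)-transformed abundances (FPKM-like or
  normalized-RSEM-like).  The transform is guarded against double
  application via an explicit scale tag.
* Two-class statistic: d = (mean_KO − mean_WT)/(s + s₀) with the pooled
  standard error s = sqrt(a·(SS₁+SS₂)), a = (1/n₁+1/n₂)/(n₁+n₂−2).  At
  s₀ = 0 this equals the pooled-variance t statistic exactly (tested to
  1e−12).  Paired statistic: d = z̄/(s + s₀), s = sqrt(Σ(z−z̄)²/(n(n−1))).
* s₀ is chosen from the percentiles {0, 5, …, 100} of the s distribution by
  minimising the coefficient of variation of the median absolute deviations
  of d within 100 s-quantile windows; ties break toward the smallest
  candidate, and inputs with fewer than 100 genes fall back to the 5th
  percentile with a warning.  Fixed and percentile modes are available.
* The permutation null enumerates every label assignment (unpaired) or
  sign-flip pattern (paired) when the count is at most
  `max_exhaustive_perms`, including the identity; otherwise it samples with
  an explicit seed.  At the default design this is exhaustive, making every
  result deterministic given the input.
* Calling uses SAM's asymmetric rule: genes are ranked by d, compared with
  the mean null order statistics d̄(i), and for a threshold Δ the first
  positive excursion > Δ above the origin sets the upper cutoff (mirrored
  below).  The Δ grid is derived from the observed excursions (deterministic
  thinning to at most 200 values), and the smallest Δ whose estimated FDR
  meets the target is used; if none does, the largest Δ is used and zero
  calls are allowed.
* FDR(Δ) = π₀ · P(#null beyond cutoffs) / #called, where P is a percentile
  across permutations (default 50, i.e. the median-FDR convention) and
  π₀ = min(1, #{d within the null interquartile range}/(m/2)).

### The add-one guard

With 8–20 permutations, the raw median-FDR estimate has a serious
pathology: for a cutoff that isolates the single most extreme gene, the
median permutation count of null exceedances is exactly 0 whenever fewer
than half the permutations exceed that gene's own value — which happens for
roughly half of pure-null datasets, since the observed assignment is one of
the permutations.  The estimated FDR is then 0 and the gene is called, so
the caller is badly anti-conservative under the null.  The implementation
therefore applies the standard permutation-inference correction (a finite
permutation set should never estimate an exactly-zero exceedance count) and
uses (count + 1) in the numerator.  Measured over 40-replicate simulations
at the default design, this yields zero calls on pure-null data while
keeping recall ≈ 0.95 for planted 2-log2-unit effects at noise 0.5.  The
guard can be disabled (`SamConfig(fdr_add_one=False)`), and the
90th-percentile FDR convention is available via `fdr_percentile`.

A consequence of the guard is granularity: at target FDR q with the guard,
a call set must have at least ⌈π₀/q⌉ members, so very small true signatures
cannot be called at stringent targets with so few permutations.  This is a
faithful reflection of how little information 20 permutations carry.

* Genes with zero variance in all groups and zero mean difference get d = 0
  and are never called, avoiding ±∞ propagation; a zero standard error with
  a non-zero difference and s₀ = 0 yields a flagged infinite d.
* Per-gene q is the smallest estimated FDR over the Δ grid at which the
  gene is called, monotonized along the |d − d̄| ranking by a running
  minimum (the BH-style direction, which only ever lowers q).

## Signature construction and reversal

The signature is the set of genes called in the KO-vs-WT contrast with
direction sign(d).  "Reversed by sirolimus" requires a significant call in
the opposite direction in the paired sirolimus-in-KO contrast — an
intersection of two FDR-thresholded lists, not a sign comparison.
Percentages are rounded half-up to integers.  The common-gene fraction
between the WT and KO sirolimus responses treats the WT list as the
putative subset side; both orders can be computed.  The dual-category
candidate screen intersects a gene list with a user-supplied annotation
table (gene → categories), replacing live ontology-service queries so that
tests are version-stable and offline; it composes (requiring the union of
two category sets equals sequential filtering).

## Tumor signature score

Cohort expression is log2(x+1) transformed and z-scored per gene using the
sample (n−1) standard deviation across **all** tumors — mutants included —
since the score definition involves no subsetting.  Down-in-KO genes are
negated and the score is the mean over signature genes present; genes
missing from the matrix or with zero variance are dropped and counted, so
the score remains a mean over the genes actually used.  The score is
invariant to per-gene positive affine transforms of the log values, sums to
zero across tumors when no genes are dropped, and responds monotonically to
any single up-gene's expression.

Ortholog mapping is explicit (two-column table); unmapped genes are dropped
with a count, and a human gene receiving conflicting directions from two
mouse genes is dropped with a warning.  Mutant status is "≥ 1 record in
TSC1/TSC2 with a non-silent class"; the default whitelist renders the
non-silent categories in MAF terms (Missense_Mutation, Nonsense_Mutation,
Frame_Shift_Del/Ins, Splice_Site, In_Frame_Del/Ins, Nonstop_Mutation,
Translation_Start_Site, 5'UTR) and is configurable.  The default group test
is the two-sided Mann–Whitney U with tie correction; Welch's t is offered.

## Clinical association statistics

* Pearson correlation with the two-sided t-based p (scipy); partial
  correlation by the first-order closed form with df = n − 3 (the paper-side
  convention is unstated; one covariate ⇒ n − 3).
* 2×2 factorial simple main effects: OLS fit of the full interaction model
  (statsmodels), Type III omnibus, then cell-mean contrasts using the
  pooled residual variance of the interaction model — the standard
  follow-up, rather than per-stratum variances.
* Percent change is 100·(mean_alt − mean_ref)/mean_ref rounded half-up,
  with a Welch-t p-value.
* Kaplan–Meier estimation and the two-group log-rank test delegate to
  lifelines; the median is the smallest observed time with S(t) ≤ 0.5,
  flagged undefined when the curve never reaches 0.5.  A stratification
  boundary at a threshold value (e.g. %FEV1 = 80) assigns the boundary
  value to the upper ("mild") stratum; this is configurable at the caller.

## Synthetic data

All generators are deterministic given their seed (numpy Generator) and
write plain TSV.  Noise is Gaussian on the log2(x+1) scale rather than
negative-binomial on counts: the analysis operates entirely on transformed
abundances, so the generators target that scale directly, and raw values
are recovered as max(2^y − 1, 0).  Planted-set sizes use round-half-up so
expected counts are exact.

Fibroblast defaults: 2000 genes, 10% planted up / 5% down in KO at 2 log2
units, noise SD 0.5, baselines N(3, 1.5²); 92% of up-genes and 80% of
down-genes are "reversed" (their KO effect removed under sirolimus in KO),
and a 5% shared gene set responds to sirolimus in both genotypes, making
the WT response an approximate subset of the KO response.  Cohort defaults:
391 tumors, 43/391 mutant, a 1-log2-unit shift along signature directions
in mutants, noise SD 1, and 200 background genes; a configurable fraction
of wild-type tumors receives a silent TSC1/TSC2 record.  Clinical defaults:
64 patients, gal3/fev1 correlation −0.32 on the latent scale (gal3 scaled
to ≈ 4650 ± 1980 pg/mL, %FEV1 to ≈ 70 ± 20), BMI linearly confounded with
gal3, an AML shift applied in the mild stratum, and exponential survival
with medians 24/28 weeks by sex under independent exponential censoring.

What the generators do **not** emulate: count-level sampling noise,
library-size and GC artifacts, batch effects, gene–gene correlation, and
the heavy-tailed abundance distributions of real RNA-seq.  Passing tests
therefore establish the correctness and calibration of the *procedures*
under their stated assumptions, not performance on any particular real
dataset; in particular, exact published gene counts from real data are not
reproducible from synthetic inputs and are not claimed.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale problems chosen to exercise every
code path: 200–2000 genes, 20 permutations (exhaustive), 50-replicate null
calibration for the SAM caller, 500-replicate type-I checks for the group
comparison, simple effects and log-rank, and 60–391-tumor cohorts.
Tolerances follow the quantity: 1e−12 for algebraic identities (pooled-t
equivalence, exchangeability), 1e−10 for score zero-centering, 1e−8 for
affine invariance, and binomial three-sigma bands for Monte-Carlo rates.
Ties in the s₀ grid break toward the smaller candidate; the Δ grid
thinning keeps extremes and is deterministic; per-stage seeds are derived
from the global seed by hashing the stage name (stable across runs, below
2³¹).

## Known limitations

* With exhaustive-but-few permutations the attainable FDR values are
  coarse; the estimate is reported exactly as computed, with no
  interpolation.
* The paired contrasts at 3 pairs (8 sign patterns) have very limited
  resolution; reversal percentages on synthetic data are recovered within
  binomial error of the planted fractions, not exactly.
* The annotation screen is only as good as the supplied annotation table;
  no over-representation statistics are computed.
* The cohort score assumes the cohort is large enough for stable per-gene
  z-scores; it refuses single-tumor input.
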