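# Methods

## Data model and matching

The framework consumes three inputs: a binary alteration matrix in GCT
dialect (rows `GENE_MUT`/`GENE_DEL`/`GENE_AMP`, optionally variant-qualified
like `BRAF.V600E_MUT`; columns cell lines, possibly `_ORGAN`-suffixed), a
compound × cell-line AUC table (CSV/TSV or spreadsheet; AUC ∈ [0, 1],
missing entries allowed), and a driver-gene list.  Internally every matrix
is oriented samples × features.  Cell-line matching uppercases both sides
and strips a tissue suffix from alteration-side names using a vocabulary of
organ tokens: the first underscore whose remainder is a known tissue ends
the sample token.  The screens themselves do not document a canonical
normalization, so the rule is explicit and configurable
(`strip_tissue_suffix`, `tissue_vocabulary`); matching keeps the
intersection in alteration-file order and is idempotent.  A first
driver-list line matching a common header token (`gene`, `symbol`, …) is
skipped.

## Predictor reduction

Reduction is deliberately unsupervised — it happens before any response is
seen, so it cannot overfit.

* **Driver filter.**  `gene_of` strips the type suffix and, for
  variant-qualified tokens, everything from the first `.`; alterations
  whose gene is not in the driver set are dropped.
* **Variance filter.**  A binary column with observed prevalence p has
  variance p(1−p).  With the default minimum proportion 0.05 the threshold
  is 0.05·0.95 = 0.0475; "below" is strict, so a column at exactly the
  threshold survives.  Comparisons carry a 1e−12 absolute guard so a
  boundary case reached through different float paths is never dropped.
* **Redundancy clustering.**  Pairwise Pearson correlations of binary
  columns are computed as the phi coefficient from integer 2×2-table counts
  (algebraically identical, numerically stable); the distance is 1 − r².
  Complete-linkage agglomeration merges while the minimum inter-cluster
  distance is ≤ 1 − 0.95² = 0.0975 (ties merge, i.e. |r| = 0.95 counts as
  redundant).  The agglomeration is written in-house because the tie-break
  is pinned down for reproducibility: among tied minimum distances the pair
  with lexicographically smallest member indices merges first.  On
  tie-free inputs the partition equals `scipy.cluster.hierarchy` complete
  linkage cut at the same height (asserted in tests against that oracle).
  Each cluster keeps its first member — smallest original row index — as
  representative; the full composition is retained, because a collapsed
  alteration is considered as important as its representative in reporting.

**Frequency/power check.**  To justify the 0.05 minimum frequency the
package computes the power of a two-sided two-sample t-test comparing mean
response between altered and unaltered lines: group sizes f·n and (1−f)·n
(continuous, power-calculator convention), Cohen's d = 0.5, α = 0.05,
noncentral-t distribution with n − 2 degrees of freedom.  At n = 523 the
power at f = 0.05 is ≈ 0.70, and the smallest f on a 0.001 grid reaching
0.80 is 0.065.

## Per-compound forests

Cell lines with a missing AUC are deleted per compound (no imputation; a
model needs ≥ 10 remaining lines).  Each forest has B = 500 CART regression
trees (scikit-learn `DecisionTreeRegressor`), each trained on a bootstrap of
size n with replacement, m = max(1, ⌊p/3⌋) candidate predictors per split,
no depth cap, minimum leaf size 5 — the defaults of the regression
random-forest ecosystem this framework mirrors; only B and m are prescribed
by the method, the rest are exposed in configuration.  The in-bag
multiplicity matrix is recorded, so the OOB prediction for line i averages
exactly the trees that never drew i; a line in-bag everywhere gets NaN and
is excluded from error and concordance computations (at B = 500 this is
vanishingly rare).  One master seed per run; drug d uses seed + d, so
adding or removing compounds does not shift other models.

**Stability.**  The OOB error curve e_b (OOB MSE after the first b trees)
is computed incrementally from running per-sample prediction sums in
O(B·n).  The stability value is the mean of the last ten squared successive
differences of that curve; `reached` means it rounds to zero at 1e−6.  The
raw value is always stored.

## Concordance

The CCC uses population (1/n) moments throughout: the squared mean shift
does not rescale with n−1 denominators, so mixing conventions would break
the [−1, 1] bound.  |CCC| ≤ |Pearson r| always, with equality iff the two
moment pairs match.  The 95% interval is Lin's asymptotic interval on the
Fisher-z transform of the CCC (variance involves r and the standardized
mean shift, evaluated at the estimates; back-transformed with tanh).  The
method of interval construction is recorded in provenance so a bootstrap
variant can be swapped in.  Reporting multiplies by 100 and bins by
(−∞, 0] none, (0, 20] poor, (20, 40] fair, (40, 60] moderate,
(60, 80] substantial, (80, 100] excellent; real-valued CCCs are binned by
these half-open intervals so the integer-labelled bins are exhaustive.
"At least fair" means the lower bound exceeds 20.

## Permutation importance and its test

For tree b and predictor j, imp_jb is tree b's OOB MSE with column j
permuted within its OOB lines minus the unpermuted OOB MSE — one seeded
permutation per (tree, predictor), keyed by (master seed, drug index,
predictor) so results are reproducible and independent across drugs.  A
predictor a tree never splits on changes nothing and scores exactly 0
without evaluation; trees with fewer than two OOB lines contribute nothing
and the divisor is adjusted.  The z statistic divides the mean importance
by its estimated standard deviation — the B−1 sample standard deviation of
the imp_jb over sqrt(B) — matching the scaling the reference R
implementation applies; the one-sided p is the upper normal tail, the
Bonferroni family is the number of predictors entering that model, and
significance means adjusted p < 0.005.  Degenerate rows are explicit:
sd = 0 with imp ≤ 0 gives p = 1, sd = 0 with imp > 0 gives p = 0.

**Known limitation — null anti-conservatism.**  Under a global null the
per-tree importances of a fixed predictor are not independent across trees:
they share a data-conditional component (the realized chance association
between that predictor and the response), so the z statistic is inflated
relative to N(0, 1) roughly like √B and the family-wise error of the
Bonferroni call is far above its nominal level (measured ≈ 0.5–0.7 at
B = 200 across null replicates, essentially independent of n).  This is the
documented anti-conservatism of scaled permutation importance.  The
dedicated null-calibration test in the acceptance suite measures and
reports this honestly rather than hiding it; significance calls should be
read as a ranking device with a reproducible cutoff, not as calibrated
hypothesis tests.

## Missingness QC

Per compound, on the post-reduction alteration set: CCC (×100) between
full-cohort and screened-subset binary-variance vectors; CCC between full
and subset squared-correlation vectors, paired over the strict upper
triangle in row-major order; the share of retained alterations whose subset
variance violates the threshold (percent); and the share of retained pairs
whose subset |r| reaches the redundancy threshold, in pcm (per hundred
thousand).  A column constant after subsetting has an undefined
correlation: such pairs are excluded from the paired CCC vectors but
counted as violations, and the count of degenerate columns is reported.
Identical vectors (no missingness) score CCC = 100 by convention even when
constant.

## Reports and the interaction screen

Report 1 includes compounds whose lower CCC bound exceeds the threshold
(default 20, configurable downward to admit less predictable compounds),
sorted by decreasing CCC with alphabetical tie-break; each row carries the
mean AUC over that compound's screened lines, the sample size, and the
significant alterations by decreasing importance.  Report 2 counts, per
alteration, the Report-1 compounds it significantly influences, attaches
the redundancy-cluster id/size/members, and lists influenced compounds by
decreasing CCC; ties break alphabetically.  Both reports are deterministic
given the per-drug results.

Candidate pairs are unordered Report-1 pairs with |mean AUC difference| ≤
0.02 and different top (most important significant) alterations, ordered by
ascending difference.  For a pair, both compounds' logit-normalized AUCs
(clipped into [1e−3, 1 − 1e−3]; screens do produce AUC = 1) are stacked
long — one row per compound per screened cell line, pairing ignored — with
Factor 1 the compound and Factor 2 the joint status of the two top
alterations (00/10/01/11).  The interaction is the nested-model F between
the additive and the full factorial OLS fits (statsmodels), which is
unambiguous under unbalanced designs and equals the classical interaction F
when balanced (asserted against a hand-computed oracle).  Per-combination
two-sample t-tests and boxplot-ready group summaries (n, mean, median,
quartiles, non-outlier whiskers at 1.5 IQR) accompany the test; no
multiplicity correction is applied across pairs.

## Synthetic studies

The generator emulates exactly the structure the framework assumes:
independent Bernoulli alteration columns with prevalences spanning
(0.02, 0.45) — including sub-threshold columns for the variance filter —
plus near-duplicate groups (prototype copied, entries flipped with
probability 0.01 by default, realized correlations reported in the truth
record) and a handful of columns whose genes are withheld from the driver
list.  Responses are generated on the logit scale — baseline + planted
effects × alteration + N(0, 0.1) — and mapped through the inverse logit;
interactions are planted as ±δ/2 differential coefficients between a drug
pair, so the ANOVA's estimand is exactly δ.  Missingness is MCAR per drug
at 0.2, matching the screens' average missing share (~19%).  Effects live
on the logit scale so the interaction model is correctly specified under
the generator; what passing tests show is therefore internal correctness
and statistical behaviour under the assumed model, not robustness to real
screens' tissue heterogeneity, drug-specific missingness mechanisms, or
measurement error in the AUC itself, none of which the generator imitates.

The demonstration configuration has 400 cell lines, 60 alterations and
6 drugs: two with −2 logit effects on different alterations and matched
baselines (the planted interaction pair), two with −1.5 effects, two null.
Prevalence of effect-carrying alterations is 0.3.

## Problem sizes used in the test and acceptance runs

Simulation checks run at desk scale, chosen to finish on one CPU while
keeping the estimates stable: planted-signal recovery at n = 400, B = 500
over 20 replicates (10 in the acceptance script); the null calibration at
n = 200, 20 predictors, B = 200 over 200 replicates (100 in the script; the
measured inflation is the same at n = 523, so the scale-down does not drive
the verdict); interaction power at n = 400 over 20 replicates and null
uniformity at n = 120 over 1000 replicates (300 in the script).

## Other design choices

* Real-data headline numbers of the original screens require the frozen
  CCLE/GDSC snapshots and are exercised only through the file-format and
  matching layers; all quantitative tests run on synthetic studies.
* `min_proportion` must lie in (0, 0.5]: above 0.5 the "small proportion"
  reading of the variance threshold is meaningless and the pipeline refuses
  it as infeasible.
* The CLI is a thin veneer; the library API (`run_pipeline`, and the
  per-stage functions it composes) is the primary interface, and cached
  runs can be re-reported (`report`) or re-tested (`interact`) without
  refitting forests.
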