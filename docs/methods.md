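# Methods

`ratiosurv` implements an anchor-gene expression-ratio survival screen for
bulk RNA-Seq cohorts, together with the Monte Carlo calibration, enrichment
and literature-triage stages that turn per-gene statistics into a ranked
table of candidate functions. This note records the model, the defaults and
the design choices, and what the synthetic validation does and does not
establish.

## The screening model

Let `x_g(s)` be the normalized expression of gene `g` in subject `s`, and
let `A` denote the anchor gene (by default named OPCML, after the ovarian
tumor-suppressor scenario the screen was designed around). All values are
rescaled as

    y_g(s) = log2(x_g(s) + 4),

a linear-shift log transform whose minimum possible value is 2.0, so the
per-subject ratio

    r_g(s) = y_A(s) / y_g(s)

always has a denominator bounded away from zero. For every non-anchor gene
the cohort is bifurcated at the sample median of `r_g` ("low" = value <=
median, "high" = value > median; ties go low), and the two groups are
contrasted with:

- a two-sided log-rank test (`km_p_ratio`);
- the same test on a median split of `y_g` alone (`km_p_single`), the
  single-gene baseline;
- a univariate Cox proportional-hazards fit whose single covariate is the
  high-group indicator. The hazard ratio (`cox_hr`) is always high-ratio
  relative to low-ratio. Ties are handled with the Efron approximation,
  declared fixed for reproducibility across implementations.

A raw HR is asymmetric around its null value of 1 (lower tail bounded by 0,
upper tail unbounded), so it is symmetrized:

    HRsym = HR - 1        if HR >= 1
          = -(1/HR) + 1   if HR < 1

which is exactly antisymmetric under HR -> 1/HR and zero iff HR = 1. The
vector of HRsym values over all non-skipped features of one screen is then
Z-scored (sample sd, ddof = 1) into `HRz`. The standardization population is
always a single screen — real or one randomized replicate — never a mixture.

Two filters gate significance:

- **Improvement filter.** The ratio stratification must be at least 10%
  more significant than the single-gene baseline, read multiplicatively on
  the p-value scale: `p_ratio <= 0.9 * p_single` (factor configurable). The
  alternative -log10 reading was rejected as less direct.
- **HRz tails.** Features with `HRz` below the lower threshold are labelled
  `OPCML_plus` (high anchor/gene ratio is protective); above the upper
  threshold, `GENEi_plus`. Thresholds are either the fixed +/-2.0 group
  definitions or the empirical 0.025/0.975 quantiles of the Monte Carlo
  null (default), which for this design land very close to -/+2.

## Monte Carlo null calibration

Ratios share one anchor numerator, so per-feature test statistics within a
cohort are strongly positively dependent and analytic false-positive
arithmetic does not apply to the screen as a whole. The null is therefore
built empirically: each iteration permutes every expression row
independently across subjects and permutes the survival records
(days-to-death and event flag move together), preserving all marginal
distributions and the shared-anchor structure while destroying every
feature-survival linkage; the full screen is re-run and its HRz values are
pooled. The calibration reports the pooled 0.025/0.975 quantiles, the
pooled and per-iteration fractions beyond +/-2.0 (the per-iteration mean is
the headline false-positive rate), and a Shapiro-Wilk p-value for the
pooled statistic (subsampled to 5000 values with a seeded generator when
larger, since the test's p-value is unreliable beyond that size). Default
25 iterations; one seed determines the whole calibration bit-for-bit.

Because each replicate is standardized against itself, the per-replicate
mean is exactly zero and the +/-2.0 exceedance rate is stable near 0.05
even though raw per-feature p-values co-fluctuate strongly within a
replicate. A second-order effect of the shared anchor is visible at scale:
features carry heterogeneous loadings on a per-replicate common factor, and
the loading spread inflates the cross-feature sd without fattening the
conditional tails, so the measured exceedance rate sits slightly below the
naive heavy-tail expectation (about 0.047-0.050 at 189 subjects x 2000
features in this package's simulations, against 0.0455 for an exact
Gaussian).

## Enrichment and triage

Features classified into either tail feed a plain hypergeometric
over-representation analysis against user-supplied GMT collections. The
gene universe is the set of features the screen actually tested (its
sampling frame), not the genome. Active-subnetwork searches over
protein-interaction networks are deliberately out of scope; consequently
function counts from such pipelines are not comparable to this package's
output. Benjamini-Hochberg adjustment is applied at alpha = 0.05 per
collection batch. Repeated function IDs (e.g. the same pathway reached via
several collections) are collapsed keeping the *highest* p-value — the
conservative representative — with first-encountered winning ties.

Each surviving function is labelled by the composition of its significant
member genes: `dependent` when OPCML+ members strictly outnumber 4x the
GENEi+ members (a zero GENEi+ count with any OPCML+ gene qualifies), else
`independent`. Functions are clustered by the Jaccard distance between
their member-gene sets under average-linkage agglomeration, cut into `k`
top-level clusters (default 20, a free parameter). The metric and linkage
were an open design choice; Jaccard + average linkage was picked because
cluster assignments then depend only on set structure, not gene labels.

Literature relevance (the OVca score) is the geometric mean of per-gene
citation counts over a function's significant member genes, computed as
`geomean(count + 1) - 1` and floored at zero: the pseudocount keeps
zero-count genes from annihilating the mean and cancels exactly on
round-number inputs. Counts come from a TSV or an injected offline client;
a live PubMed E-utilities client (query shape
`GENE AND [ovarian cancer] AND 1998:2023[PDAT]`) is available but optional,
throttled, and never fabricates a count on failure. Triage retains at most
the four highest-OVca functions inside any cluster with more than four
members, then ranks dependent-majority functions first, by OVca descending,
ties broken by adjusted p then function ID.

## The synthetic cohort generator

The generator emulates the screen's target study design: a ~189-subject
single-stage decedent cohort (every subject's death observed within a
10-year horizon), a few thousand independent expression features, one
anchor gene, and optional effect features whose anchor/gene ratio is
causally linked to the hazard.

- **Expression.** Per-feature abundance `mu_f ~ N(4.0, 1.5)` on the natural
  log scale with log-normal subject noise (sd 0.8), or a gamma-Poisson
  (negative-binomial, dispersion 2) alternative. The anchor uses a wider
  subject sd of 1.0: an anchor worth screening against splits its cohort
  into near-silenced and constitutively expressing subjects, and a ratio
  screen is only more informative than single-gene splits when the anchor
  actually varies.
- **Survival.** Exponential event times with per-day baseline hazard
  ln(2)/365 (median ~1 year — a decedent-only advanced-stage cohort, whose
  observed death times sit well below population median survival). For each
  effect feature, subjects in its high-ratio half have their log hazard
  shifted by `true_log_hazard` (scalar or per-feature), so
  `exp(true_log_hazard)` is exactly the group HR the screen estimates. By
  default all subjects are events, drawn from the exponential truncated at
  the horizon; at this baseline the horizon carries ~0.1% of the survival
  mass, so truncation leaves planted HRs essentially undistorted. A
  censoring mode (`events_only=False`) emits horizon-censored records
  instead. Days are integers in (0, horizon).
- **Gene sets and citations.** Random GMT-writable sets over the non-anchor
  universe plus one planted set containing the effect features at a stated
  overlap fraction; synthetic citation counts are log-normal integers with
  a boost for effect features so planted functions surface in triage demos.

One caveat the generator makes visible: every ratio split is partly an
anchor split, so *same-direction* planted effects accumulate into an anchor
main effect — the anchor itself becomes prognostic, the whole HRsym
distribution shifts, and standardization then hides individual effects.
The screen's premise (inherited from the motivating study) is that the
anchor alone is not prognostic; realistic planted panels should therefore
mix directions, which cancels the anchor loading. Mixed-direction panels in
turn attenuate each feature's marginal HR through anchor-mediated overlap
of the splits. Both phenomena are properties of ratio screens generally,
not artifacts of this implementation.

What the generator does not model: batch structure, tumor purity, platform
differences, feature-feature co-expression beyond the shared anchor, and
zero inflation. Passing tests therefore demonstrate the statistical
machinery under clean independence assumptions, not performance on real
TCGA-like data.

## Numerical choices

- The per-feature Cox fit (single binary covariate) is solved by a damped
  scalar Newton iteration on the Efron partial likelihood, vectorized
  across features; convergence at step < 1e-12, |log HR| > 10 or a
  non-positive information is reported as separation/degenerate and the
  feature is skipped with a reason, never assigned an HRz. The solver is
  cross-checked against lifelines in the test suite.
- Risk-set accumulations use a fixed left-to-right summation order so that
  a feature evaluated alone is bit-identical to the same feature inside a
  batch; screens are likewise invariant to subject order, and all outputs
  are byte-stable under a fixed seed.
- Median splits require >= 4 subjects and two distinct values; all-tied
  features (e.g. a duplicate of the anchor) are skipped as degenerate.
- Anchor-outlier removal Z-scores the anchor row (sample sd) on the
  normalized scale and drops subjects at |Z| >= 6 by default. The threshold
  is configurable; for heavy-tailed (log-normal-like) anchors a stricter
  threshold such as 12 confines removal to genuinely pathological cases.
- Cohort day filters are strict on both bounds (0 < days < 3650 by
  default); subjects present in only one of expression/clinical are dropped
  with a warning.

## Problem sizes used in validation

The packaged checks run the full pipeline at 189 subjects x 2000 features
with 10-25 Monte Carlo iterations (the calibration scale), single-feature
recovery at 2000 subjects, and 20 replicate cohorts for sensitivity —
sizes chosen so the whole suite re-runs in well under a minute on one CPU
while keeping Monte Carlo error small relative to every acceptance band.

## Known limitations

- The screen is univariate by design; no adjustment for covariates.
- Empirical thresholds are quantiles of a pooled null; with few iterations
  they inherit Monte Carlo noise.
- The HRz centering assumes most features are null; a large fraction of
  same-direction true effects shifts the center and costs sensitivity (see
  the anchor-loading caveat above).
- The OVca score depends on citation counts that drift with database date;
  rankings, not absolute scores, are the stable output.
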