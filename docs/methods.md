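# Methods

## The estimation problem

At a point in a landscape the mean interval between successive fires is
the point mean fire interval; averaged over all points it is the
population mean fire interval (PMFI).  The fire rotation (FR) — the
expected time for cumulative burned area to equal the landscape area — is
analytically equivalent to the PMFI for a stationary regime, so either
quantity can serve as *the* mean rate of burning.  Fire-scar records
estimate these rates only indirectly: a fire scars each tree it burns with
probability below one (the scarring fraction, SF), trees are usually
selected for being well-scarred, and intervals are censored at the ends of
each tree's record.  Composite fire intervals (CFI) pool fire years across
trees and therefore shorten as more trees or area are pooled; individual-
tree fire intervals (ITFI) avoid pooling but miss unrecorded fires.  The
package quantifies these biases and calibrates the estimators against
PMFI/FR by regression.

## Analysis-period restriction

All interval statistics operate on a scar-to-scar analysis period: from
the earliest fire to the latest fire inside a calendar window (default
1600–1900 CE), optionally starting only at the first fire after a minimum
number of series are simultaneously alive (default 10; "alive" is between
a series' inner and outer dates, not "already scarred", matching standard
sample-depth semantics).  Records spanning fewer than a minimum number of
years (default 50) after restriction are rejected with an explicit
signal rather than silently analyzed.

## Interval estimators

For each restricted site the package computes five measures of central
tendency (mean, median, and Weibull scale, mean, median) for four interval
families:

* **CFI-all** — intervals between all composite fire years (any year with
  at least one scar);
* **CFI-10% / CFI-25%** — composite years where the fraction of
  scarred-sample series alive that year that were scarred meets the
  threshold.  The comparison is `>=` by default (a fire on exactly 25% of
  scarred samples qualifies); the strict `>` rule is available because
  analysis software differs on this point and the difference is visible
  exactly at the threshold.  The denominator is series alive that year and
  scarred at least once during the analysis period — not all series, and
  not recorders only — with alternatives deliberately not defaulted.
* **ITFI** — each tree with ≥ 2 scars contributes its own mean inter-scar
  interval; the grand mean is unweighted across qualifying trees.  The
  Weibull ITFI measures are fitted to the pooled set of individual-tree
  intervals (every inter-scar interval on every tree), which keeps the fit
  sample-size reasonable at typical tree counts; this weights multi-
  scarred trees more heavily than the grand mean does, consistent with how
  interval software pools sample-level intervals.

Weibull fits are two-parameter maximum-likelihood fits with the shift
fixed at zero (the reported scale is the 63rd percentile; mean
`b·Γ(1+1/k)`, median `b·(ln 2)^(1/k)`).  Fits need at least three
intervals; zero-variance interval sets and non-convergent fits are
reported as missing rather than forced, mirroring the variable estimator
availability of real compilations.  Intervals are integer years; two scars
in one year on different trees are one composite fire year.

## Fire rotation by the ratio method

Annual burned fraction is the fraction of qualifying series scarred in a
fire year; FR is the observation period over the summed fractions.
Qualifying series are either all scarred series ("total scarred" basis) or
recorders — trees scarred at least once, counted from their first scar
onward.  Per-year denominators use series alive in that year so sparse
early periods do not deflate fractions; deducting series eliminated by
later record truncation is available as an option, since published
applications do not state a uniform rule.  The record is scar-to-scar:
fractions are summed over fire years after the first fire and the
observation period is last-fire minus first-fire year, which makes a
single tree scarred every 20 years yield FR = 20 exactly.

## Bias, inaccuracy, and calibration

Bias of estimator M against reference PMFI/FR is the relative mean error
`RME = mean[(M_i − FR_i)/FR_i]·100%`; inaccuracy is the relative mean
absolute error with the same normalization.  Both are tested against zero
with two-sided one-sample t-tests.  RMAE ≥ |RME| always, and both are
invariant under common rescaling of M and FR.

Calibration models are through-origin least squares,
`PMFI/FR = ß · estimator`, because a zero interval estimate must imply a
zero rate.  Up to two outliers with externally studentized residuals above
3.0 are removed iteratively (largest first, refitting between removals);
leverage uses the no-intercept hat matrix, which makes the "> 3.0" rule
well defined.  R²_adj uses the uncentered total sum of squares, the
standard definition for no-intercept models.  Prediction error is
estimated by 10-fold cross-validation over a seeded uniform shuffle; the
reported RMSE carries fold-assignment noise, so comparisons should use a
fixed seed or a band across seeds (the acceptance checks use a ±0.5-year
band across 20 seeds).  Best-subset models add three sample-size
covariates (sample area, total scarred trees, scarred trees per 100 ha) to
the estimator, enumerate all subsets containing the estimator, and select
the lowest-Mallows-Cp subset among those whose every term is significant
at α = 0.05 (per-coefficient t-tests within each subset fit); if no
covariate qualifies, the estimator-only model stands.  Each estimator's
regression uses its own complete-case set, since estimator availability
varies by site.

## Summary surfaces

Group summaries report n, mean with a t-based 95% CI, sd, CV (sample sd
over mean, as a percent; single-member groups report sd as missing),
quartiles, and a distribution-free 95% CI for the median from
binomial(n, ½) order-statistic ranks with linear interpolation between
adjacent order statistics — statistics packages differ in their
interpolation, so median-CI endpoints are comparable only approximately
across software.  Forest-type comparisons use Welch's t-test.  Histograms
use fixed-width bins anchored at zero (default 15 years), half-open at the
top, with the percent of the distribution strictly exceeding each bin's
lower limit; exceedance percentages, not bin counts, are the stable
reporting surface because bin anchors vary across published figures.

The old-forest proxy classifies a stand by its beginning analysis year:
before 1700 → generally ≥ 200 years old by 1900; before 1750 → ≥ 150
years; otherwise younger.  The low-severity classifier is the published
calibrated structural rule — historical tree density < 178 trees/ha,
large trees > 29.2%, small trees < 46.9%, all strict — and the
area-weighted landscape percentage is total fitting area over total area
across the eleven published GLO-survey/aerial-photo reconstructions
shipped as a data constant (their area-weighted mean is 33.8%).

## The fire-regime simulator

The simulator provides known truth for every upstream stage.  A gridded
landscape (default 20×20 cells, nominally 1 ha/cell) ignites a fire in a
year with fixed probability (default 0.25).  Burned patches are
axis-aligned rectangles whose area fraction is drawn from a bounded
Pareto distribution (default exponent 1.2 on [0.02, 1.0]); the rectangle
wraps toroidally so every cell carries the same long-run burn rate —
the spatial homogeneity under which PMFI and FR coincide, which the tests
verify to within 5% at 2000 simulated years.  Trees (default 20; 30 in
the calibration experiments) are placed uniformly at random, clustered,
or one per cell; each tree inside a fire's footprint is scarred with
probability 0.3 if previously unscarred and 0.7 once it is a recorder.
No quantitative scarring fractions are published for these forests; the
defaults are conventions chosen to be moderate (well below 1, with the
recorder effect clearly present) and are deliberately not adjusted per
experiment.  Tree mortality/recruitment is off by default (every tree
spans the simulation); an optional fixed lifespan staggers inner/outer
dates to exercise sample-depth logic.  Targeted sampling keeps the k
most-scarred trees (ties broken by a seeded shuffle), emulating the
near-universal practice in real compilations.

True FR is simulated years over summed annual burned fraction; true PMFI
is the mean over cells (with ≥ 2 fires) of the cell's mean inter-fire
interval.  Emitted records mark recorder status from each tree's first
scar and serialize to FHX byte-identically under a fixed seed.

What the simulator does *not* emulate: climate forcing and temporal
nonstationarity, irregular fire perimeters and unburned inclusions within
them, severity gradations (all simulated fires are understory burns),
dating error, and spatially varying fuels.  Passing tests therefore
demonstrate that the statistical machinery behaves correctly under a
known stationary regime with imperfect, targeted observation — not that
any particular historical landscape had a particular rate.

## Study conditions used in tests and the acceptance script

The calibration experiments simulate collections of 60 sites (plus 30
prediction sites), 300-year records, 30 trees per 400-cell landscape,
targeted down to the 12 most-scarred trees.  These sizes keep the full
suite and the acceptance script within seconds on one CPU while leaving
Monte-Carlo noise well below the effects being asserted.  Under these
conditions the synthetic pipeline reproduces the structure reported from
real compilations without any tuning: composite means ~80% below true FR
and attenuating across the all → 10% → 25% filters, individual-tree means
within ~20%, recorder-based rotations biased short, a calibration slope
slightly above one with R²_adj ≈ 0.97, and cross-validated RMSE well below
the uncalibrated error.

## Known limitations

* The FHX reader is permissive (unknown matrix codes are logged and
  preserved as opaque injuries) but has only been exercised against the
  dialect it writes plus hand-built variants, not against the full variety
  of archived files.
* Restricted (truncated) sites can place non-recording years at series
  boundaries; such sites are for analysis, and round-trip identity is
  guaranteed only for records whose series begin and end with a visible
  marker or event, as simulator output does.
* Exact reproduction of Weibull estimates from other software can differ
  at the percent level depending on the fitting routine; this package uses
  MLE for reproducibility.
* Median confidence intervals are order-statistic intervals; other
  software's interpolation may differ slightly.
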