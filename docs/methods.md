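# Methods

## The assessment model

The package evaluates the ecological security of a lake watershed from an
annual indicator panel organised by the DPSIR causal chain: driving forces
(D, the socio-economic engines of change), pressures (P, the loads human
activity puts on the lake), status (S, water quality and ecology), impacts
(I, changes in the services the lake provides) and risk (R, the chance of
an ecological disaster — here, a cyanobacterial bloom).

### Risk statistic

The risk component is a single annual statistic computed from daily
records.  With `n_i` daily records in year `i` and `n_Ti`, `n_Pi`, `n_Ni`
the numbers of days with temperature, total phosphorus and total nitrogen
*strictly below* the lowest values at which blooms have been observed,

    x_i = 1 − [(n_i − n_Ti)/n_i] · [(n_i − n_Pi)/n_i] · [(n_i − n_Ni)/n_i].

Each bracket is the fraction of days on which one bloom precondition held,
so `x_i ∈ [0, 1]`, is non-decreasing in each below-threshold count, and is
symmetric in the three counts.  Note the orientation: `x_i` *rises* as more
days fall below the thresholds, i.e. a high value means a safe year.  The
statistic therefore enters normalization as a benefit-direction indicator
by default.  Because the prose meaning of the word "risk" pulls the other
way, the orientation is an explicit per-run setting (`risk.direction` in
the YAML config) rather than something silently corrected.  Records exactly
at a threshold are not counted as below it.  The thresholds themselves are
user inputs with illustrative defaults (10 °C, 0.05 mg/L TP, 0.5 mg/L TN);
they should be replaced by bloom-observation minima for the lake at hand.

### Normalization and aggregation

All indicators are expressed relative to a baseline ("background") year:
benefit indicators as `x'_{i,j} = x_{i,j}/x_{base,j}`, cost indicators as
`x'_{i,j} = x_{base,j}/x_{i,j}`, so that higher is always better and the
baseline year maps to exactly 1.  The direction is a property of the
indicator, not of an individual value; a per-value rule would force every
normalized value to at least 1 and could never produce an index below the
baseline.  Component indices are weighted geometric means of the normalized
indicators, and the Ecological Security Index (ESI) is the weighted
geometric mean of the five component indices; weights default to uniform
(1/m within a component, 1/5 across components).  The geometric mean keeps
the aggregation scale-invariant (rescaling a raw series changes nothing),
bounded between the smallest and largest member, and strictly decreasing
when any single indicator worsens.  Zero or negative raw values are a hard
error naming the indicator and the year, including a zero baseline value of
the risk statistic — no epsilon substitution.

Whether the risk statistic passes through baseline normalization like every
other indicator (default) or enters the ESI directly as its own component
index is configurable (`risk.normalized`); with direct entry the baseline
identity no longer holds for the R component.

### Indicator screening

Composite indices are biased by multicollinearity: several near-duplicate
indicators in one category drag the aggregate in the same direction and
double-count one underlying signal.  Screening runs per category:

1. Pairwise Pearson correlations with two-sided p-values from the t
   distribution on n − 2 degrees of freedom, on the raw annual series.
   No detrending is applied: co-trending is precisely the redundancy being
   screened.  Constant series have undefined correlation, reported as NaN
   and treated as non-significant.
2. Pairs with p ≤ α (default 0.05; 0.01 supported) are linked and clusters
   are the connected components of that graph — the weakest grouping rule
   that still yields a partition.  Singletons pass through.
3. Within a multi-member cluster, PCA on the standardized member series
   (equivalently, on their correlation matrix — indicator units are
   incommensurable, so covariance PCA would be meaningless).  If PC1
   explains at least `pc_variance_threshold` (default 0.8) of the variance,
   the single member with the largest |PC1 loading| is kept.  Otherwise the
   smallest set of leading components reaching the threshold each nominate
   their top-loading not-yet-chosen member.  Loading ties (possible only
   for numerically identical series) break lexicographically by id and are
   logged.

The full audit trail — matrices, clusters, explained variance, loadings —
is kept in the result and serialized, so every selection is inspectable.

### Screened-vs-unscreened comparison

The pipeline computes every index twice, from the screened and from the
full panel, and regresses the unscreened series on the screened one by OLS
per component and for the ESI, excluding the baseline year (where both are
1 by construction, which would inflate the fit).  R² of a simple regression
is symmetric, so the direction of the regression is a reporting convention;
slope and intercept are included so either reading is recoverable.  A
constant predictor yields an undefined (reported as null) R², never 0.
Comparisons for the impact and risk components are flagged as
supplementary: assessments of this design usually examine only D, P, S and
the ESI.

## The synthetic watershed

No public monitoring panel accompanies this model, so the package ships a
generator that reproduces the *statistical* structure such panels show,
with planted ground truth for recovery testing.  It makes no attempt to
match real magnitudes (population counts, load tonnages); only correlation
and trend structure are emulated.

* **Driving-force block** (default 3 cost-direction series over 1988–2007):
  a single-factor model `z_j = sqrt(c_j)·L + sqrt(1−c_j)·ε_j` on a
  standardized linear ramp L.  The communalities `c_j` are distinct — the
  representative member sits at 0.9995 and the rest at a common level
  solved in closed form so that the expected pairwise correlation equals
  the configured target (default 0.98, matching the >0.95 correlations
  typical of socio-economic blocks).  Concentrating the communality gap in
  one member is deliberate: with pairwise correlation pinned near 0.98, an
  evenly spaced loading ladder differs by less than the sampling noise of a
  20-year correlation estimate, and the planted "most representative"
  member would not be identifiable from the data.  Trend amplitudes on the
  log scale are 0.06 for the representative and 0.09–0.15 for the others:
  the representative grows slowest (population-like) while the block mean
  is pulled up by one fast economic series, which is what makes an
  unscreened driving-force index decline more steeply than a screened one.
* **Pressure/status/impact series** (two per category by default) load with
  coefficient 0.55 on a piecewise-linear V-shaped latent whose vertex sits
  exactly at `worst_year` (descent from the first year to the vertex,
  recovery to 60% of the lost ground by the last year) — cost series on its
  negative, benefit series on it directly.  The rest of each series'
  variance is a per-series smooth cosine shape, Gram–Schmidt-orthogonalized
  against the V and against the other shapes, plus white noise of relative
  scale `noise_sd` (default 0.1).  The 0.55 loading keeps within-category
  correlations near 0.30 in expectation — below the significance cutoff of
  a 20-year record at α = 0.05 (|r| ≈ 0.44) — so these series survive
  screening, while their shared V component still dominates the aggregate
  index and puts its minimum at the planted worst year.
* **Daily records**: a seasonal temperature cosine (≈7–25 °C) with 1.5 °C
  day noise, identical across years, and lognormal daily nutrient values
  around yearly medians that rise into the worst year and recede after it.
  The winter tail guarantees some below-threshold temperature days every
  year, keeping the risk statistic strictly inside (0, 1).
* All values leave the generator through `base · exp(amplitude · z)`, so
  positivity is structural.  Noise-free latents are exposed
  (`v_latent`, `monotone_latent`) so the planted extremum can be checked
  without noise.  All randomness flows from one integer seed through
  separate `numpy` generator streams for panel, daily records and block
  duplication.

The defaults were fixed once, at design time, by simulating the planted
structure's identifiability (fraction of seeds in which the block stays
above r = 0.95, the representative is recovered, the ESI minimum lands on
the worst year, and the duplicated-block slope ordering holds); they are
chosen for test power, not calibrated to any real watershed.

What passing tests on this generator do **not** show: robustness to missing
years, to heteroscedastic or autocorrelated measurement error, to indicator
blocks correlated *across* categories, or to real panels whose worst year
differs per component.  The generator's clean factor structure makes the
representative-selection problem better-posed than a real panel may be.

## Numerical choices

* Geometric means are computed as products of powers; tests verify
  agreement with the independent log-space form to 10 decimals.
* Baseline-year normalized values are set to exactly 1.0 (not just within
  roundoff) so the baseline identity of the indices is exact.
* PCA loadings are quantized to 9 decimals before ranking so numerically
  identical series tie deterministically (then lexicographic id order).
* Correlation significance clustering treats p = α as significant (p ≤ α).
* The duplicate-block utility jitters copies relative to each series' own
  log-scale standard deviation; an absolute jitter would make copies of
  slow-growing series disproportionately noisy and bias PCA selection
  toward fast-growing members.
* Comparison R² needs at least 3 shared years after exclusions.

## Problem sizes

The shipped study conditions are a 20-year panel (1988–2007, baseline 1988,
worst year 1998), a 3-member driver block, 6 pressure/status/impact series,
365 daily records per year, and 100-seed replications for all recovery-rate
statements; these sizes match the structure the model is meant for (≥ 20
annual observations) and keep the full test-and-reproduction cycle under a
minute on one CPU.
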