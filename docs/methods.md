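# Methods

This document describes the models implemented in `paleocycles`, the
meaning and defaults of their parameters, the numerical choices made,
what the synthetic generators do and do not emulate, and the known
limitations.  Every empirical number quoted here was computed with this
package (the test suite or the example scripts); there are no imported
claims.

## Conventions

All time series live on descending calendar grids: `t0` is the oldest
bin in cal BP (calendar years before 1950 CE), the step is positive,
and "forward in time" means decreasing cal BP.  Internal computation
uses a 5 a grid; comparative statistics operate on 100 a slices
produced by block averaging (`grids.aggregate`), with the slice time
stamped at the block centre.

## Calibration and SPD

**Ingestion.** Date tables need the columns `lab_id, c14_age, c14_sd,
lon, lat, site_id`.  Rows that fail to parse are skipped; exact
duplicates are collapsed on the key `(c14_age, c14_sd, lon, lat)` —
deliberately excluding the site and lab labels, because the same
measurement is frequently reported under different site spellings in
public compilations.

**Precision filter.** A date is kept when its ¹⁴C error satisfies
`SD ≤ max(220 − sqrt(8·10⁵ km² · n), 40) a`, where `n` is the local
date density in dates/km² on a 4°×4° cell (spherical-Earth cell areas).
Sparse regions therefore admit imprecise dates rather than going empty,
while dense regions are held to 40 a.  The threshold is 220 a at
`n = 0` and exactly 40 a at `n = 0.0405` dates/km² (closed form; both
values are asserted exactly in the acceptance suite).

**Calibration.** The calibrated density of a date is the Gaussian
likelihood of its ¹⁴C age at each calendar age, with variance
`lab² + curve²` from linear interpolation of the tabulated curve
(3-column dialect: cal BP, ¹⁴C age, curve error).  Densities are **not
normalized to unit mass** by default: per-date normalization deflates
densities that straddle a curve plateau and inflates its flanks, which
injects artificial growth-rate excursions that have nothing to do with
population.  `artifact_rgr` makes this auditable: it pushes a uniform
¹⁴C date distribution through the curve and returns the growth rate of
the resulting SPD.  With `normalize=False` (the pipeline's convention)
this is flat even across a plateau — the sum of unit-height likelihoods
over a uniform ¹⁴C grid is constant in calendar time — while
`normalize=True` reproduces the paired positive/negative excursion
around the plateau, i.e. the artifact the non-normalized convention
avoids.  Both behaviours are pinned in the test suite.

**Binning and SPD.** Within a site, calibrated median ages are chained
into bins by single-linkage with a 100 a threshold (`bin_width`), and
densities are averaged within each bin before summation.  This stops
heavily dated single events (many lab measurements of one context) from
counting multiple times, while distinct occupations more than 100 a
apart still count separately.

## Growth rate and preprocessing

`rgr` is the forward relative difference
`{SPD(t+Δt) − SPD(t)} / {SPD(t)·Δt}` with `Δt = 100 a`; zero-density
bins yield NaN rather than infinities, and the youngest `Δt` of the
window is NaN because it has no forward value.

`preprocess` applies, in order: a triangular kernel of 130 a half-width
(distance-decaying weights, NaN-aware), subtraction of a 1500 a
truncated moving average, removal of the residual mean, and division by
the standard deviation.  The two filter lengths define the
multicentennial band: computed on pure tones, a 500 a cycle passes with
gain 0.78 while a 3000 a cycle is attenuated to gain 0.36 (ratio ≈ 2.2),
and centennial-scale noise is suppressed by the smoothing kernel.
The zero-variance guard is relative (`sd ≤ 10⁻¹⁰ × max|input|`), so a
constant series raises rather than dividing by rounding noise.

## Synchrony statistics

**Spectra** are raw one-sided periodograms (boxcar window, demeaned, the
zero frequency dropped).  No smoothing or padding is applied, so peak
positions are honest to the Rayleigh resolution `1/(N·step)`; the
trade-off is the well-known variance of the raw periodogram — under
white noise the max/median power ratio exceeds 12 in about 5 % of
length-120 series (Monte-Carlo bound computed in the test suite; the
naive factor-5 rule fires far too often for exponential-distributed
ordinates).

**Trimmed correlation `r_T`** is the Pearson correlation computed only
where the *reference* series is in its extremal quartiles
(`tail_fraction = 0.25` on each side).  It asks whether extremes
co-occur, not whether the bulk wiggles together.  At
`tail_fraction = 0.5` it reduces exactly to the plain Pearson
correlation (tested).  For preprocessed independent noise of length
120, |r_T| stays below 0.35 in ≥ 95 % of pairs — wider than the naive
`1/sqrt(n)` band because smoothing reduces the effective sample size.

**Phase overlap** measures same-sign co-occurrence inside peak windows.
Peaks of the reference are maximal runs with `|a| > ε`
(`ε = 0.05·sd` by default); each run is extended by a 100 a linear
taper; within the tapered windows the other series' values `b` are
weighted by the taper and the overlap is
`Σ same-sign w·|b| / Σ w·|b|`.  Because the taper reaches into
opposite-sign territory even for a series compared with itself, the raw
self-overlap is below 100 %; the statistic is therefore re-adjusted by
the reciprocal of the self-overlap and clipped to [0, 100].  After
re-adjustment, self-overlap is exactly 100 % (to 10⁻⁶), antiphase pairs
give 0 %, and independent preprocessed noise averages 50 % ± 2 % over
200 pairs — the two calibration targets recomputed by
`scripts/acceptance.py`.  The weighted-|b| denominator (rather than
counting bins) makes the statistic insensitive to near-zero dithering
of the compared series inside a window.

**Classification**: overlap > 67 % → "strong synchrony";
overlap < 49 % *and* r_T < 0 → "antiphase"; otherwise "intermediate".
Thresholds are strict inequalities (boundary values are intermediate).

## Regionalization

For each 400 a slice, sites — not dates — are the exchangeable units:
the per-cell statistic is the mean slice RGR of the cell's summed date
density minus the continental value, and the null distribution is built
by randomly reassigning whole sites to cells (site counts per cell held
fixed).  Cells with fewer than 10 dates are excluded.  Two-sided
permutation p-values use the add-one rank estimator
`(exceed + 1)/(valid + 1)`; q-values are Benjamini–Hochberg across the
slice's cells; the combined score `(1−p) + (1−q)`, signed by the
deviation, is nonzero only when both p < .05 and q < .05.

Scored cells are clustered by k-means on standardized
`(score, lon, lat)` features, k = 2…12, 25 restarts per k, choosing the
k that minimizes `withinss × (1 + exp{−10(N_min/N* − 1)})` with
`N* = 120` dates.  The penalty equals 2 when the smallest cluster holds
exactly N* dates and explodes below it, so partitions whose regions
could not support a stable SPD are rejected regardless of geometric
fit.  The winning partition is projected onto a 0.1° grid by
containment.  Regional growth series are combined as area-weighted
means (a sparse region of equal area counts as much as a dense one),
spatial structure is summarized by mean pairwise correlation per 500 km
centroid-distance bin, and `synchrony_vs_extent` tracks the phase
overlap of the area-averaged growth with a forcing as the spatial
window grows.

## Chronology alignment

Proxy age models carry errors of a century or more, which destroys
naive stacking.  `align_records` aligns an ensemble without choosing a
reference:

1. every pair is matched by dynamic time warping on a common 20 a grid
   over the pair's overlap (squared-difference local cost, symmetric
   steps, numba-compiled DP with backtracking);
2. the pair distance is `path cost ÷ overlap fraction × (1 + (d/100)²)`,
   where the overlap fraction is relative to the shorter record and `d`
   is the maximal time distortion along the path — short-overlap and
   heavily warped pairs are penalized (the factor is exactly 2 at
   `d = 100 a`);
3. pair weights `w_ij = exp(−(D_ij/D̄)²) · w_j` convert distances to
   influence; each record's timings move by the weighted sum of its
   pairwise displacements;
4. cumulative displacement is hard-capped at ±150 a from the original
   timings — age models are wrong by decades, not millennia — and
   monotonicity is restored by isotonic regression;
5. record weights `w_j` are refreshed from each record's mean distance
   to the rest, and the loop runs 4–8 iterations (tolerance: 1 a mean
   update), returning the last state with a warning if the tolerance is
   not met.

The displacement update uses the raw weighted sum (Σ w_ij < 1), which
under-relaxes the motion and stabilizes the fixed point.  On the
default synthetic ensemble (12 proxies, ≤ 150 a smooth distortions) the
first-three-component explained variance rises from ~0.62–0.74
unaligned to ~0.95–0.99 aligned in 20 of 20 seeds, with every applied
displacement within the cap.

Ensembles are aligned separately for the early (> 5.8 ka BP) and late
(< 6.2 ka BP) segments — record coverage differs strongly between them —
and the two stability indices are merged by a linear cross-fade over
5.8–6.2 ka BP.

## Climate stability and forcings

Aligned, standardized records, multiplied by their alignment weights,
are interpolated to a common 20 a grid (records with an internal gap
over 500 a are dropped from the PCA) and decomposed with PCA.  The
stability index is `−normalize(Σ_{c≤5} |d smoothed PC_c / dt|)`: high
when the shared climate state changes slowly, irrespective of what the
state is, and invariant to the arbitrary sign of each component.

Comparison forcings enter through the same preprocessing chain:
`prepare_forcing` returns `−preprocess(TSI)` (solar minima historically
coincide with stable climate, hence the sign), and
`treering_homogeneity` sign-flips the preprocessed across-tree standard
deviation of annual ring widths (years with < 2 trees excluded).

## Boom/bust logistic model

Labels are the sign of the preprocessed growth rate (exact zeros and
NaNs are dropped).  Three variants are fitted by maximum likelihood
(statsmodels `Logit`):

| variant | inputs | reading |
|---|---|---|
| 1V | lagged RGR | endogenous: a boom follows a bust after a lag |
| 2V | stability, −TSI | exogenous: climate paces the cycle |
| 3V | all three | combined |

The lag is 350 a before 7 ka BP and 210 a after (the cycle quickens as
populations grow); lagged values are linearly interpolated and poisoned
within one step of any NaN source bin.  Perfect separation — which
genuinely occurs on short series — triggers a ridge-stabilized IRLS
refit (penalty 10⁻⁶) flagged on the returned model.  Hindcasts are
reported as `2·p̂ − 1` (+1 certain boom, −1 certain bust).  Note that 2V
is *not* nested in 1V, so only orderings against 3V are guaranteed by
likelihood theory; the 3V ≥ 2V ≥ 1V ordering asserted in the acceptance
suite is a property of exogenous-dominant generating laws, not of the
estimator.

## Synthetic generators

`SyntheticScenario` defaults are the study conditions: window
9800–3000 cal BP, growth cycles of 360/500/680 a at 0.0012 a⁻¹ on a
0.0003 a⁻¹ trend, 20,000 dates over 250 sites in 8 spatial clusters,
30 a lab errors, a wiggly (±20 ¹⁴C a, 500 a correlation length) but
strictly monotone calibration curve, 12 proxies with smooth ≤ 150 a
chronological distortions sharing one latent signal, and an AR(1)
red-noise solar-like forcing optionally coupled to the latent.

What the generators capture: date counts proportional to population,
site clustering, lab error, curve wiggles, age-model distortion that is
*smooth* (drift, not white jitter — white jitter is not what age-model
error looks like and would be unalignable), proxy loading diversity
including sign flips, and red forcing spectra.  What they do not
capture: taphonomic loss curves, research-intensity bias between
regions, curve plateaus of realistic shape (the wiggle model is
stationary), heteroskedastic lab errors, proxy archives with
non-Gaussian noise, and any spatial structure in the latent climate
signal (all proxies share one latent).  Conclusions about *spatial*
climate heterogeneity therefore cannot be rehearsed on these defaults.

## Numerical choices

- Non-normalized calibration by default; normalization available per
  call for diagnostics.
- Raw periodograms, no tapering: peak positions are the deliverable,
  not power levels.
- The DTW dynamic program is compiled with numba (`@njit`); everything
  else is vectorized numpy/scipy.
- k-means and PCA come from scikit-learn (25 restarts; seeded), FDR
  from statsmodels; isotonic repair from scikit-learn with an epsilon
  tie-break to restore *strict* monotonicity.
- Permutation p-values use the add-one estimator, so p = 0 is
  impossible and FDR input is well-defined.
- All stochastic components take explicit seeds; the pipeline is
  byte-identical across runs at the same seed (tested).

## Limitations

- The phase-overlap statistic needs at least one peak in the reference
  series; it returns NaN (and the pipeline reports "undefined") on
  peakless inputs.
- Spectral peak recovery at the default window (68 bins of 100 a)
  operates near the Rayleigh limit; neighbouring periods (360 vs 500 a)
  are separated by only ~3.5 Rayleigh bins and a sampling-noise peak
  can displace a true one for unlucky date draws.
- The alignment's 1 a mean-update tolerance is usually not met within 8
  iterations; the returned state is the last iterate (flagged
  `converged=False`), which is by design — the fixed point is
  approached asymptotically and the cap dominates the solution long
  before formal convergence.
- `local_deviation_scores` recalibrates each site's density per slice;
  for continental inputs this is the dominant cost and the permutation
  count (default 999, pipeline default 99) should be budgeted
  accordingly.
- The logistic model treats time slices as independent observations;
  serial correlation inflates the nominal precision of the standard
  errors.  Coefficient recovery is verified distributionally (2 SE
  coverage across replicates), not per fit.
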