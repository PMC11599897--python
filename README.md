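# paleocycles

Multicentennial growth cycles from radiocarbon records: a library for
reconstructing human population growth rates from archaeological
radiocarbon dates and testing their synchrony with climate stability and
solar forcing.

## The science

Archaeological radiocarbon dates, summed over their calibrated
probability densities, trace human activity through time.  The
**summed probability distribution (SPD)** of a large date archive is a
noisy proxy for population density; its **relative growth rate (RGR)**,
`{SPD(t+Δt) − SPD(t)} / {SPD(t)·Δt}` with Δt = 100 a, exposes the booms
and busts of prehistoric demography.  Band-pass filtered (130 a
smoothing, 1500 a detrending), the growth rate of Holocene Europe
oscillates with multicentennial periods, and the question this package
operationalizes is whether those oscillations are internally generated
(endogenous boom/bust dynamics with a characteristic lag) or paced by
external forcing (climate stability, solar irradiance) — and how to
measure "paced" honestly.

The package implements the full computational chain:

- **calibration** — date ingestion and deduplication, density-dependent
  precision filtering, non-normalized calibration against a tabulated
  curve, per-site binning, SPD construction, and a calibration-artifact
  control that quantifies what a curve plateau alone would do to the
  growth rate;
- **growth** — RGR, the standard smoothing/detrending/normalization
  chain, and boom/bust event densities from independent occupation
  series;
- **synchrony** — periodograms, trimmed (extremal-quartile) correlation
  r_T, the taper-weighted **phase overlap** statistic (100 % for
  identical series, ~50 % for unrelated ones), and the
  strong-synchrony / antiphase / intermediate classification;
- **regionalize** — site-level spatial permutation tests per 400 a
  slice with FDR control, penalized k-means regionalization, and
  area-weighted continental averages;
- **proxy_align** — reference-free multi-record chronology alignment by
  pairwise dynamic time warping with a hard ±150 a displacement cap;
- **climate_stability** — PCA proxy stacking, the sign-reversed
  rate-of-change stability index, segment merging, and comparison
  forcings (solar irradiance, tree-ring homogeneity);
- **logit_model** — boom/bust logistic regression in three variants:
  endogenous (1V: lagged RGR), exogenous (2V: stability + solar), and
  combined (3V), with hindcasts expressed as `2·p̂ − 1`;
- **synthetic_data** — seed-deterministic generators for dates, curves,
  proxies and forcings whose defaults are the study conditions;
- **pipeline** — one configuration in, a manifest of delimited-text
  artifacts out.

## Worked example

`examples/01_spd_growth.py` generates 20,000 synthetic dates whose true
growth rate carries 360/500/680 a cycles, rebuilds the SPD, and reads
the cycles back off the periodogram:

```
scenario window: 9800-3000 cal BP, 20000 dates at 250 sites
RGR slices: 67 defined bins of 100 a
configured cycle periods: 360 a, 500 a, 680 a
recovered dominant periods: 372.2 a, 478.6 a, 670.0 a
Rayleigh resolution: 1.47e-04 1/a
```

All three periods come back within one Rayleigh bin of the truth.
`examples/02_synchrony.py` shows the synchrony statistics on controlled
cases:

```
x vs itself            : overlap = 100.00%, r_T = +1.000, label = strong synchrony
x vs its negation      : overlap =   0.00%, r_T = -1.000, label = antiphase
Monte-Carlo baseline over 200 independent pairs: 50.04% (sd 6.63)
```

and `examples/03_proxy_alignment.py` demonstrates the chronology
alignment: twelve proxies distorted by up to 150 a go from 0.619 to
0.978 first-three-component explained variance, with no applied
displacement exceeding the 150 a cap.  The remaining examples cover the
stability index, the logistic boom/bust models (a known law
`β = (0.0, 0.5, 1.3, 1.0)` is recovered as
`(-0.047 ± 0.114, +0.120 ± 0.118, +1.591 ± 0.157, +0.993 ± 0.137)` with a
98.2 % hindcast phase overlap), spatial regionalization, and the full
pipeline.

## Reproduction

The suite in `tests/` covers every module with unit and property tests,
plus `tests/test_acceptance.py`, which pins the shipped guarantees:
exact phase-overlap self-calibration, the uncorrelated-noise baseline,
end-to-end cycle recovery, alignment gain across seeds, logistic-law
recovery, and closed-form spot checks.

The two calibration targets can be recomputed from scratch, at any
seed, with:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports the self phase-overlap of a preprocessed series (`t1`)
and the Monte-Carlo mean overlap of 200 independent preprocessed noise
pairs (`t2`) as JSON.

## Layout

```
src/paleocycles/     the library
tests/               pytest suite (unit + property + acceptance)
examples/            one narrative script per capability
scripts/acceptance.py  recompute the calibration targets
docs/methods.md      models, parameters, numerical choices, limitations
```
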