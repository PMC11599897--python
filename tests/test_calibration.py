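"""Ingestion, precision filtering, calibration and SPD construction."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleocycles import (CalibrationCurve, RadiocarbonDate, artifact_rgr,
                         calibrate_date, filter_by_precision, ingest_dates,
                         precision_threshold, spd)
from paleocycles.calibration import date_density
from paleocycles.grids import aggregate

from conftest import make_dates


def frame(rows):
    return pd.DataFrame(rows, columns=["lab_id", "c14_age", "c14_sd",
                                       "lon", "lat", "site_id"])


class TestIngest:
    def test_exact_duplicates_collapse(self):
        df = frame([["A", 4500, 30, 10.0, 50.0, "s1"],
                    ["B", 4500, 30, 10.0, 50.0, "s1"]])
        assert len(ingest_dates(df)) == 1

    def test_empty_table(self):
        assert ingest_dates(frame([])) == []

    def test_dedup_key_excludes_site_and_lab(self):
        # same measurement reported under three site labels is one record
        df = frame([["A", 4500, 30, 10.0, 50.0, "s1"],
                    ["B", 4500, 30, 10.0, 50.0, "s2"],
                    ["C", 4500, 30, 10.0, 50.0, "s3"]])
        assert len(ingest_dates(df)) == 1

    def test_distinct_measurements_kept(self):
        df = frame([["A", 4500, 30, 10.0, 50.0, "s1"],
                    ["B", 4500, 40, 10.0, 50.0, "s1"],
                    ["C", 4510, 30, 10.0, 50.0, "s1"]])
        assert len(ingest_dates(df)) == 3

    def test_idempotent(self):
        df = frame([["A", 4500, 30, 10.0, 50.0, "s1"],
                    ["B", 4500, 30, 10.0, 50.0, "s1"],
                    ["C", 4600, 25, 11.0, 51.0, "s2"]])
        once = ingest_dates(df)
        twice = ingest_dates(frame(
            [[d.lab_id, d.c14_age, d.c14_sd, d.lon, d.lat, d.site_id]
             for d in once]))
        assert [(d.c14_age, d.c14_sd, d.lon, d.lat) for d in once] == \
               [(d.c14_age, d.c14_sd, d.lon, d.lat) for d in twice]

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            ingest_dates(pd.DataFrame({"lab_id": ["A"]}))

    def test_unparsable_rows_skipped(self):
        df = frame([["A", 4500, 30, 10.0, 50.0, "s1"],
                    ["B", "old", 30, 10.0, 50.0, "s1"]])
        assert len(ingest_dates(df)) == 1

    def test_reads_delimited_text(self, tmp_path):
        p = tmp_path / "dates.csv"
        p.write_text("lab_id,c14_age,c14_sd,lon,lat,site_id\n"
                     "A,4500,30,10.0,50.0,s1\nB,4600,25,11.0,51.0,s2\n")
        assert len(ingest_dates(p)) == 2


class TestPrecisionFilter:
    @pytest.mark.parametrize("n,expected", [
        (0.0, 220.0),            # empty cell: loosest threshold
        (0.0405, 40.0),          # 220 - sqrt(8e5*0.0405) = 40 exactly
        (1.0, 40.0),             # saturated at the floor
    ])
    def test_threshold_values(self, n, expected):
        assert precision_threshold(n) == pytest.approx(expected)

    def test_threshold_monotone_and_bounded(self):
        ns = np.linspace(0, 0.2, 200)
        th = np.array([precision_threshold(n) for n in ns])
        assert np.all(np.diff(th) <= 1e-12)
        assert th.min() >= 40.0 and th.max() <= 220.0

    def test_filter_at_zero_density(self):
        keep = make_dates([4000], sd=200.0)
        drop = make_dates([4000], sd=230.0)
        out = filter_by_precision(keep + drop, density_map={})
        assert [d.c14_sd for d in out] == [200.0]

    def test_sd_above_220_always_removed(self):
        d = make_dates([4000], sd=250.0)
        assert filter_by_precision(d, density_map={}) == []

    def test_density_map_from_dates(self):
        # many dates in one 4-degree cell push the threshold below 100 a
        dates = make_dates(np.linspace(3000, 6000, 50), sd=90.0)
        dens = date_density(dates)
        assert len(dens) == 1
        n = next(iter(dens.values()))
        expected_keep = 90.0 <= precision_threshold(n)
        kept = filter_by_precision(dates)
        assert (len(kept) == len(dates)) == expected_keep


class TestCalibrate:
    def test_identity_curve_gaussian(self, identity_curve):
        d = calibrate_date(4500, 30, identity_curve, window=(5000, 4000))
        t = d.times
        # density is the Gaussian likelihood centred at 4500 with sd 30
        expected = stats.norm.pdf(t, 4500, 30)
        np.testing.assert_allclose(d.values, expected, rtol=1e-10)
        mass2s = d.values[(t >= 4440) & (t <= 4560)].sum() * d.step
        assert mass2s == pytest.approx(0.954, abs=0.01)

    def test_steep_curve_halves_calendar_width(self):
        # local slope 2 (14C a per cal a): dense numerical mapping gives a
        # calendar-domain sd of half the lab sd
        grid = np.arange(0, 10000, 5.0)
        curve = CalibrationCurve(grid, 2.0 * grid, np.zeros_like(grid))
        d = calibrate_date(4500, 30, curve, window=(3000, 1500), normalize=True)
        t = d.times
        mean = np.sum(t * d.values) * d.step
        sd = np.sqrt(np.sum((t - mean) ** 2 * d.values) * d.step)
        assert mean == pytest.approx(2250, abs=1)
        assert sd == pytest.approx(15, abs=0.5)

    def test_unnormalized_is_pointwise_likelihood(self, identity_curve):
        d = calibrate_date(4500, 30, identity_curve, window=(4700, 4300))
        like = stats.norm.pdf(identity_curve.mu(d.times), loc=4500, scale=30)
        np.testing.assert_allclose(d.values, like, rtol=1e-12)

    def test_normalized_mass_is_one(self, identity_curve):
        d = calibrate_date(4500, 30, identity_curve, window=(5500, 3500),
                           normalize=True)
        assert d.values.sum() * d.step == pytest.approx(1.0, rel=1e-9)

    def test_out_of_support_raises(self, identity_curve):
        with pytest.raises(ValueError, match="30000"):
            calibrate_date(30000, 30, identity_curve)


class TestSPD:
    def test_single_date_equals_density(self, identity_curve):
        dates = make_dates([4500])
        s = spd(dates, identity_curve, window=(5000, 4000))
        d = calibrate_date(4500, 30, identity_curve, window=(5000, 4000))
        np.testing.assert_allclose(s.values, d.values)

    def test_identical_dates_one_site_bin_averaged(self, identity_curve):
        # two duplicate measurements of one event count once, not twice
        dates = make_dates([4500, 4500])
        s = spd(dates, identity_curve, window=(5000, 4000))
        single = spd(make_dates([4500]), identity_curve, window=(5000, 4000))
        np.testing.assert_allclose(s.values, single.values)

    def test_distant_dates_one_site_sum(self, identity_curve):
        dates = make_dates([4200, 4800])      # 600 a apart: separate bins
        s = spd(dates, identity_curve, window=(5200, 3800))
        parts = sum(spd(make_dates([a]), identity_curve,
                        window=(5200, 3800)).values for a in (4200, 4800))
        np.testing.assert_allclose(s.values, parts)

    def test_gaussian_mixture_oracle(self, identity_curve, rng):
        # distinct sites, zero curve error: SPD is exactly the sum of
        # per-date Gaussian likelihoods
        ages = rng.uniform(4000, 8000, 40)
        dates = [make_dates([a], site=f"s{i}")[0] for i, a in enumerate(ages)]
        s = spd(dates, identity_curve, window=(8500, 3500))
        oracle = np.zeros(len(s))
        for a in ages:
            oracle += stats.norm.pdf(s.times, a, 30.0)
        np.testing.assert_allclose(s.values, oracle, rtol=1e-9)

    def test_uniform_dates_give_flat_spd(self, identity_curve, rng):
        # Monte-Carlo: dates uniform in calendar time through the identity
        # curve produce an SPD flat to within sampling error
        n = 3000
        ages = rng.uniform(4000, 9000, n)
        dates = [make_dates([a], site=f"s{i % 300}")[0]
                 for i, a in enumerate(ages)]
        s = aggregate(spd(dates, identity_curve, window=(9000, 4000)), 100)
        interior = s.values[5:-5]
        cv = interior.std() / interior.mean()
        assert cv < 0.15

    def test_empty_input_raises(self, identity_curve):
        with pytest.raises(ValueError):
            spd([], identity_curve, window=(5000, 4000))


class TestArtifactRGR:
    def test_identity_curve_flat(self, identity_curve):
        art = artifact_rgr(identity_curve, (8000, 4000), n_dates=2000)
        v = art.values[np.isfinite(art.values)][3:-3]
        assert np.abs(v).max() < 2e-4    # flat 14C input maps to flat SPD

    def test_flat_c14_is_artifact_free_without_normalization(self):
        # the sum of unit-mass likelihoods over a uniform 14C grid is
        # constant in calendar time even across a plateau: the
        # non-normalized pipeline shows no calibration artifact
        curve = self._plateau_curve()
        art = artifact_rgr(curve, (8500, 4500), n_dates=3000,
                           normalize=False)
        v = art.values[np.isfinite(art.values)]
        assert np.abs(v).max() < 2e-4

    @staticmethod
    def _plateau_curve():
        grid = np.arange(0, 12000, 10.0)
        mu = np.where(grid < 6000, grid,
                      np.where(grid < 6600, 6000.0, grid - 600.0))
        mu = mu + np.linspace(0, 1e-3, len(grid))  # keep strictly monotone
        return CalibrationCurve(grid, mu, np.zeros_like(grid))

    def test_plateau_creates_paired_excursion_when_normalized(self):
        # per-date normalization deflates densities spread across the
        # plateau and inflates its flanks: the artifact growth rate
        # swings positive and negative around the plateau
        curve = self._plateau_curve()
        art = artifact_rgr(curve, (8500, 4500), n_dates=3000)
        v = art.values
        t = art.times
        near = np.isfinite(v) & (np.abs(t - 6300) < 800)
        far = np.isfinite(v) & (np.abs(t - 6300) > 1500)
        assert v[near].max() > 10 * np.abs(v[far]).max()
        assert v[near].min() < -10 * np.abs(v[far]).max()
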