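"""Contracts of the synthetic driver generators."""

import numpy as np
import pytest

from termiteflux import (
    WorldConfig,
    EFGeneratorConfig,
    gen_monthly_temperature,
    gen_landcover,
    gen_cropland_fraction,
    gen_gpp,
    gen_ef_sample,
    gen_soil_sink,
    gen_region_mask,
    ef_summary,
    area_weighted_total,
)
from termiteflux.landcover import NATURAL_CLASSES
from termiteflux.synthetic import ocean_mask, ef_sample_to_csv, ef_sample_from_csv


class TestTemperature:
    def test_equatorial_cells_warm_all_year(self, world):
        months = gen_monthly_temperature(world, world.year_start)
        land = ~ocean_mask(world.spec)
        eq_rows = np.abs(world.spec.lat_centers) < 10
        for m in months:
            vals = m.values[eq_rows][land[eq_rows]]
            assert np.all((vals >= 20.0) & (vals <= 30.0))

    def test_polar_band_below_habitat_threshold_at_baseline(self, world):
        months = gen_monthly_temperature(world, world.year_start)
        land = ~ocean_mask(world.spec)
        polar = np.abs(world.spec.lat_centers) > 80
        tmin = np.min(np.stack([m.values for m in months]), axis=0)
        assert np.all(tmin[polar][land[polar]] < -8.0)

    def test_deterministic_given_seed(self, world):
        a = gen_monthly_temperature(world, 2003)
        b = gen_monthly_temperature(world, 2003)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.values, fb.values)

    def test_hemispheric_phase_opposition(self, world):
        months = gen_monthly_temperature(world, world.year_start)
        jan, jul = months[0].values, months[6].values
        north = world.spec.lat_centers > 45
        south = world.spec.lat_centers < -45
        land = ~ocean_mask(world.spec)
        assert np.nanmean(jul[north][land[north]]) > np.nanmean(jan[north][land[north]])
        assert np.nanmean(jan[south][land[south]]) > np.nanmean(jul[south][land[south]])

    def test_warming_trend_shifts_later_years(self):
        w = WorldConfig(year_start=2000, year_end=2100, warming_rate=0.5, seed=1)
        early = gen_monthly_temperature(w, 2000)
        late = gen_monthly_temperature(w, 2100)
        d = np.nanmean(np.stack([l.values - e.values for l, e in zip(late, early)]))
        assert d == pytest.approx(0.5 * 10, abs=0.1)  # 10 decades

    def test_year_outside_range_rejected(self, world):
        with pytest.raises(ValueError):
            gen_monthly_temperature(world, world.year_end + 1)

    def test_ocean_cells_missing(self, world):
        months = gen_monthly_temperature(world, world.year_start)
        assert np.all(np.isnan(months[0].values[ocean_mask(world.spec)]))


class TestLandCover:
    def test_all_fifteen_classes_present(self, world):
        census = gen_landcover(world).census()
        assert set(census) == set(NATURAL_CLASSES)

    def test_deep_tropics_are_evergreen_forest(self, world):
        lc = gen_landcover(world)
        rows = np.abs(world.spec.lat_centers) < 7.5
        codes = lc.codes[rows][~lc.missing[rows]]
        assert np.all(codes == lc.code_of("tropical_evergreen_forest"))

    def test_high_latitudes_are_density_zero_classes(self, world):
        lc = gen_landcover(world)
        rows = np.abs(world.spec.lat_centers) > 75
        codes = lc.codes[rows][~lc.missing[rows]]
        allowed = {lc.code_of("tundra"), lc.code_of("polar_desert")}
        assert set(np.unique(codes)) <= allowed

    def test_static_in_time(self, world):
        a, b = gen_landcover(world), gen_landcover(world)
        np.testing.assert_array_equal(a.codes, b.codes)


class TestCropland:
    def test_in_unit_interval(self, world):
        f = gen_cropland_fraction(world, world.year_start).values
        ok = ~np.isnan(f)
        assert np.all((f[ok] >= 0) & (f[ok] <= 1))

    def test_zero_trend_constant_over_years(self):
        w = WorldConfig(year_start=2000, year_end=2010, cropland_trend=0.0)
        a = gen_cropland_fraction(w, 2000)
        b = gen_cropland_fraction(w, 2010)
        np.testing.assert_array_equal(a.values, b.values)

    def test_positive_trend_non_decreasing_in_tropics(self):
        w = WorldConfig(year_start=2000, year_end=2050, cropland_trend=0.02)
        rows = np.abs(w.spec.lat_centers) < 20
        prev = gen_cropland_fraction(w, 2000).values[rows]
        for year in (2010, 2030, 2050):
            cur = gen_cropland_fraction(w, year).values[rows]
            ok = ~np.isnan(cur)
            assert np.all(cur[ok] >= prev[ok] - 1e-12)
            prev = cur


class TestGPP:
    def test_polar_desert_zero(self, world):
        gpp = gen_gpp(world, world.year_start)
        lc = gen_landcover(world)
        cells = lc.cells_of("polar_desert")
        assert np.all(gpp.values[cells] == 0.0)

    def test_fertilization_multiplier_is_exact_with_same_seed(self, world):
        base = gen_gpp(world, world.year_start, fertilization=1.0)
        fert = gen_gpp(world, world.year_start, fertilization=1.29)
        pos = ~np.isnan(base.values) & (base.values > 0)
        np.testing.assert_allclose(
            fert.values[pos] / base.values[pos], 1.29, rtol=1e-12
        )

    def test_deterministic_given_seed(self, world):
        a = gen_gpp(world, world.year_start)
        b = gen_gpp(world, world.year_start)
        np.testing.assert_array_equal(a.values, b.values)

    def test_tropical_forest_magnitude(self, world):
        gpp = gen_gpp(world, world.year_start)
        lc = gen_landcover(world)
        vals = gpp.values[lc.cells_of("tropical_evergreen_forest")]
        assert 2000 < np.nanmean(vals) < 3000


class TestEFSample:
    def test_moments_match_published_summary_at_large_n(self):
        ds = gen_ef_sample(EFGeneratorConfig(n=100_000, seed=5))
        s = ef_summary(ds)
        se_mean = s.sd / np.sqrt(len(ds))
        assert abs(s.mean - 3.81) < 3 * se_mean
        # moment-based standard error of the sample s.d.
        v = ds.values
        m4 = np.mean((v - v.mean()) ** 4)
        se_sd = np.sqrt(max(m4 - s.sd**4, 0.0) / len(v)) / (2 * s.sd)
        assert abs(s.sd - 4.10) < 3 * se_sd

    def test_range_respected(self):
        for seed in range(3):
            ds = gen_ef_sample(EFGeneratorConfig(n=10_000, seed=seed))
            assert ds.values.min() >= 0.0
            assert ds.values.max() <= 25.26

    def test_zero_fraction_one_gives_all_zeros(self):
        ds = gen_ef_sample(EFGeneratorConfig(n=1, zero_fraction=1.0))
        assert ds.values.tolist() == [0.0]

    def test_contains_exact_zeros_at_default_fraction(self):
        ds = gen_ef_sample(EFGeneratorConfig(n=10_000, seed=3))
        frac = np.mean(ds.values == 0.0)
        assert 0.03 < frac < 0.07

    def test_deterministic_given_seed(self):
        a = gen_ef_sample(EFGeneratorConfig(n=1000, seed=9))
        b = gen_ef_sample(EFGeneratorConfig(n=1000, seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_infeasible_targets_rejected(self):
        # an s.d. far beyond what the truncation bound allows
        with pytest.raises(ValueError, match="attainable|feasible"):
            gen_ef_sample(EFGeneratorConfig(n=10, target_mean=3.81, target_sd=40.0))

    def test_csv_round_trip(self, tmp_path):
        ds = gen_ef_sample(EFGeneratorConfig(n=100, seed=2))
        path = tmp_path / "ef.csv"
        ef_sample_to_csv(ds, path)
        back = ef_sample_from_csv(path)
        np.testing.assert_allclose(back.values, ds.values)


class TestSoilSink:
    def test_normalized_to_prescribed_total(self, world):
        sink = gen_soil_sink(world, world.year_start, total_tg=31.6)
        assert area_weighted_total(sink) == pytest.approx(31.6, rel=1e-6)

    def test_zero_total_gives_zero_field(self, world):
        sink = gen_soil_sink(world, world.year_start, total_tg=0.0)
        assert np.nansum(sink.values) == 0.0

    def test_negative_total_rejected(self, world):
        with pytest.raises(ValueError):
            gen_soil_sink(world, world.year_start, total_tg=-1.0)

    def test_positive_over_land(self, world):
        sink = gen_soil_sink(world, world.year_start)
        land = ~ocean_mask(world.spec)
        assert np.all(sink.values[land] > 0)


def test_region_mask_partitions_land(world):
    mask = gen_region_mask(world.spec)
    land = ~ocean_mask(world.spec)
    labelled = np.zeros(world.spec.shape, dtype=int)
    for lab in mask.label_set:
        labelled += mask.region(lab).astype(int)
    assert np.all(labelled[land] == 1)
    assert np.all(labelled[~land] == 0)


def test_unknown_world_config_key_named_in_error():
    with pytest.raises(ValueError, match="warmingrate"):
        WorldConfig.from_dict({"warmingrate": 0.3})
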