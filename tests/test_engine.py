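"""Emission arithmetic, the ensemble, and budget-context conversions.

The vectorized engine is checked against an independent per-cell scalar
loop built from the same published constants, and ensemble means are
checked against their analytic expectation.
"""

import numpy as np
import pytest

from termiteflux import (
    GridField,
    WorldConfig,
    DensityConfig,
    DensityTable,
    EFDataset,
    DriverBundle,
    cell_flux,
    run_member,
    run_ensemble,
    offset_fraction,
    net_flux_field,
    ch4_to_co2eq_carbon,
    min_monthly_temperature,
    potential_habitat_mask,
    tropical_density,
    prescribed_ef_table,
    gen_ef_sample,
    EFGeneratorConfig,
)
from termiteflux.grid import band_areas
from termiteflux.landcover import LandCoverMap, NATURAL_CLASSES, CROPLAND


class TestCellFlux:
    def test_tropical_evergreen_hand_arithmetic(self):
        # 11 g m^-2 * 5.9 ug g^-1 h^-1 * 8760 h * 1e-6 = 0.5685 g m^-2 yr^-1
        flux = cell_flux(11.0, 5.9, 3.815, 3.45, 0.0, True)
        assert flux == pytest.approx(0.568524, rel=1e-9)

    def test_pure_cropland_hand_arithmetic(self):
        flux = cell_flux(11.0, 5.9, 3.815, 3.45, 1.0, True)
        assert flux == pytest.approx(3.815 * 3.45 * 8760e-6, rel=1e-9)
        assert flux == pytest.approx(0.11530, rel=1e-4)

    def test_outside_habitat_is_zero(self):
        assert cell_flux(11.0, 5.9, 3.815, 3.45, 0.2, False) == 0.0

    def test_cropland_weighting_is_linear(self):
        lo = cell_flux(11.0, 5.9, 3.815, 3.45, 0.0, True)
        hi = cell_flux(11.0, 5.9, 3.815, 3.45, 1.0, True)
        mid = cell_flux(11.0, 5.9, 3.815, 3.45, 0.5, True)
        assert mid == pytest.approx((lo + hi) / 2, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cell_flux(-1.0, 5.9, 3.815, 3.45, 0.0, True)
        with pytest.raises(ValueError):
            cell_flux(11.0, 5.9, 3.815, 3.45, 1.5, True)


def brute_force_total(drivers, ef_assignment, density_config, table, threshold=-8.0):
    """Independent per-cell scalar-loop estimate of the global total (Tg)."""
    spec = drivers.spec
    areas = band_areas(spec)
    tropical = density_config.gpp_responsive_classes
    total_g = 0.0
    for i in range(spec.n_lat):
        for j in range(spec.n_lon):
            code = drivers.landcover.codes[i, j]
            if code < 0:
                continue
            months = [m.values[i, j] for m in drivers.temperature_months]
            if any(np.isnan(months)):
                continue
            in_habitat = min(months) > threshold
            cls = drivers.landcover.classes[code]
            rho = table[cls]
            if density_config.use_gpp and cls in tropical:
                gpp = (
                    np.nan if drivers.gpp is None else drivers.gpp.values[i, j]
                )
                if np.isfinite(gpp):
                    rho = tropical_density(gpp, density_config)
            f = drivers.cropland_fraction.values[i, j]
            flux = cell_flux(
                rho, ef_assignment[cls], table[CROPLAND], ef_assignment[CROPLAND],
                f, in_habitat,
            )
            total_g += flux * areas[i] * 1e6
    return total_g * 1e-12


class TestRunMember:
    def test_matches_brute_force_scalar_loop(self, drivers):
        cfg, table = DensityConfig(), DensityTable()
        assignment = prescribed_ef_table()
        _, total, _ = run_member(drivers, assignment, cfg, table)
        expected = brute_force_total(drivers, assignment, cfg, table)
        assert abs(total - expected) / expected < 1e-9

    def test_matches_brute_force_without_gpp(self, drivers):
        cfg, table = DensityConfig(use_gpp=False), DensityTable()
        assignment = prescribed_ef_table()
        _, total, _ = run_member(drivers, assignment, cfg, table)
        expected = brute_force_total(drivers, assignment, cfg, table)
        assert abs(total - expected) / expected < 1e-9

    def test_zero_density_world_emits_nothing(self, drivers):
        table = DensityTable({c: 0.0 for c in NATURAL_CLASSES + (CROPLAND,)})
        _, total, _ = run_member(
            drivers, prescribed_ef_table(), DensityConfig(use_gpp=False), table
        )
        assert total == 0.0

    def test_doubling_every_ef_doubles_the_total(self, drivers):
        assignment = prescribed_ef_table()
        doubled = {k: 2 * v for k, v in assignment.items()}
        _, t1, _ = run_member(drivers, assignment)
        _, t2, _ = run_member(drivers, doubled)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_regional_totals_partition_global(self, drivers):
        _, total, regional = run_member(drivers, prescribed_ef_table())
        assert regional  # the synthetic bundle carries regions
        assert abs(sum(regional.values()) - total) / total < 1e-9

    def test_flux_zero_outside_habitat_and_nonnegative(self, drivers):
        field, _, _ = run_member(drivers, prescribed_ef_table())
        tmin = min_monthly_temperature(drivers.temperature_months)
        mask = potential_habitat_mask(tmin)
        vals = field.flux.values
        assert np.all(np.nan_to_num(vals) >= 0)
        outside = ~mask & ~np.isnan(vals)
        assert np.all(vals[outside] == 0.0)


def single_class_bundle(world, rho_class="tropical_evergreen_forest"):
    """A one-class, no-cropland, no-GPP world with everything in habitat."""
    spec = world.spec
    codes = np.full(spec.shape, NATURAL_CLASSES.index(rho_class))
    months = [GridField(spec, np.full(spec.shape, 20.0), "degC") for _ in range(12)]
    return DriverBundle(
        year=2001,
        temperature_months=months,
        landcover=LandCoverMap(spec, codes),
        cropland_fraction=GridField(spec, np.zeros(spec.shape), "1"),
    )


class TestRunEnsemble:
    def test_single_value_dataset_is_degenerate(self, drivers):
        res = run_ensemble(drivers, EFDataset([2.5]), n=10, seed=0)
        assert res.sd == 0.0
        assignment = {c: 2.5 for c in NATURAL_CLASSES + (CROPLAND,)}
        _, total, _ = run_member(drivers, assignment)
        assert res.mean == pytest.approx(total, rel=1e-9)

    def test_mean_recovers_analytic_expectation(self, world):
        """On a one-class world the expected total is mean(EF) x biomass-area."""
        drivers = single_class_bundle(world)
        ds = gen_ef_sample(EFGeneratorConfig(n=2000, seed=21))
        n = 1000
        res = run_ensemble(
            drivers, ds, n=n, seed=1, density_config=DensityConfig(use_gpp=False)
        )
        areas_m2 = band_areas(world.spec).sum() * world.spec.n_lon * 1e6
        expected = ds.values.mean() * 11.0 * 8760e-6 * areas_m2 * 1e-12
        se = res.member_totals.std(ddof=1) / np.sqrt(n)
        assert abs(res.mean - expected) < 3 * se

    def test_same_seed_reproduces_member_totals(self, drivers, ef_dataset):
        a = run_ensemble(drivers, ef_dataset, n=50, seed=9)
        b = run_ensemble(drivers, ef_dataset, n=50, seed=9)
        np.testing.assert_array_equal(a.member_totals, b.member_totals)

    def test_fast_path_equals_full_member_run(self, drivers):
        """The per-class-integral shortcut must agree with the full grid path."""
        ds = EFDataset([4.0])  # pins every class EF, so paths are comparable
        res = run_ensemble(drivers, ds, n=1, seed=0)
        assignment = {c: 4.0 for c in NATURAL_CLASSES + (CROPLAND,)}
        _, total, regional = run_member(drivers, assignment)
        assert res.member_totals[0] == pytest.approx(total, rel=1e-9)
        for lab, val in res.regional_means.items():
            assert val == pytest.approx(regional[lab], rel=1e-9)

    def test_density_scaling_scales_every_member(self, drivers, ef_dataset):
        cfg = DensityConfig(use_gpp=False)  # so every density comes from the table
        table = DensityTable()
        scaled = DensityTable({k: 3.0 * v for k, v in table.values.items()})
        a = run_ensemble(drivers, ef_dataset, n=20, seed=4, density_config=cfg, table=table)
        b = run_ensemble(drivers, ef_dataset, n=20, seed=4, density_config=cfg, table=scaled)
        np.testing.assert_allclose(b.member_totals, 3.0 * a.member_totals, rtol=1e-9)

    def test_empty_or_invalid_args_rejected(self, drivers, ef_dataset):
        with pytest.raises(ValueError):
            run_ensemble(drivers, ef_dataset, n=0, seed=0)


class TestBudgetContext:
    def test_offset_fraction_headline_ratio(self):
        # 14.8 Tg emission against a 31.6 Tg soil sink -> ~47 %
        pct = offset_fraction(14.8, 31.6)
        assert pct == pytest.approx(46.8, abs=0.05)
        assert round(pct) == 47

    def test_offset_edge_cases(self):
        assert offset_fraction(5.0, 5.0) == 100.0
        assert offset_fraction(0.0, 31.6) == 0.0
        with pytest.raises(ValueError):
            offset_fraction(1.0, 0.0)

    def test_net_flux_sign_convention(self, coarse_spec):
        from termiteflux.engine import EmissionField

        emission = EmissionField(
            GridField(coarse_spec, np.full(coarse_spec.shape, 0.2), "g CH4 m-2 yr-1"),
            year=2020,
        )
        sink = GridField(coarse_spec, np.full(coarse_spec.shape, 0.3), "g CH4 m-2 yr-1")
        net = net_flux_field(emission, sink)
        assert np.allclose(net.values, -0.1)

    def test_net_flux_on_synthetic_world_has_both_signs(self, world, drivers):
        from termiteflux import gen_soil_sink

        field, _, _ = run_member(drivers, prescribed_ef_table())
        sink = gen_soil_sink(world, world.year_start)
        net = net_flux_field(field, sink)
        vals = net.values[~np.isnan(net.values)]
        assert np.any(vals > 0) and np.any(vals < 0)

    def test_gwp_conversion_hand_arithmetic(self):
        # 0.5 Tg CH4 at 100-yr GWP 27.0 -> 0.5 * 27 * 12/44 = 3.68 Tg C
        assert ch4_to_co2eq_carbon(0.5, 100) == pytest.approx(3.6818, abs=1e-3)
        assert round(ch4_to_co2eq_carbon(0.5, 100)) == 4
        assert ch4_to_co2eq_carbon(1.0, 20) == pytest.approx(21.736, abs=1e-2)
        assert ch4_to_co2eq_carbon(0.0, 20) == 0.0
        with pytest.raises(KeyError):
            ch4_to_co2eq_carbon(1.0, 50)
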