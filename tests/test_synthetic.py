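"""Generator contracts: determinism, parameter recovery, series structure."""

import math

import numpy as np
import pandas as pd
import pytest

import sporesalt as ss


class TestParticleTable:
    def test_single_class_mixture(self):
        cfg = ss.GeneratorConfig(n_particles=10, mixture={"fungal_spore": 1.0},
                                 seed=1)
        tab = ss.gen_particle_table(cfg)
        assert len(tab) == 10
        assert tab["morphology"].isin(ss.SPORE_MORPHOLOGIES).all()
        assert tab["diameter_um"].between(1.0, 6.0).all()
        assert (tab["true_class"] == "fungal_spore").all()

    def test_seeded_byte_reproducibility(self):
        cfg = ss.GeneratorConfig(n_particles=50, mixture=ss.COARSE_MIXTURE, seed=9)
        a = ss.gen_particle_table(cfg)
        b = ss.gen_particle_table(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_atomic_fractions_sum_to_one(self, coarse_table):
        sums = coarse_table[list(ss.ELEMENTS)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_diameter_area_consistency(self, coarse_table):
        d = 2 * np.sqrt(coarse_table["area_um2"] / math.pi)
        np.testing.assert_allclose(d, coarse_table["diameter_um"], rtol=1e-12)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ss.GeneratorConfig(n_particles=10, mixture={"dust": 0.5})

    def test_unknown_class_rejected(self):
        cfg = ss.GeneratorConfig(n_particles=10, mixture={"kryptonite": 1.0})
        with pytest.raises(KeyError):
            ss.gen_particle_table(cfg)

    def test_class_recovery_within_three_binomial_ses(self, coarse_table,
                                                      coarse_results):
        """Classifier output reproduces the configured mixture fractions."""
        n = len(coarse_results)
        frac = coarse_results["composition_class"].value_counts(normalize=True)
        for label in ("na_rich", "dust", "sulfate", "carbonaceous"):
            p = ss.COARSE_MIXTURE[label]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(frac.get(label, 0.0) - p) <= 3 * se
        p = ss.COARSE_MIXTURE["fungal_spore"]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(coarse_results["is_fungal_spore"].mean() - p) <= 3 * se


class TestHydrationGenerator:
    def test_identity_growth_masks_equal(self):
        pair = ss.gen_hydration_pair(1.0, noise_sd=0.0)
        m_dry, a_dry = ss.detect_particle(pair.frame_dry)
        m_wet, a_wet = ss.detect_particle(pair.frame_wet)
        assert a_dry == a_wet
        assert (m_dry == m_wet).all()

    def test_wet_area_scales_as_gf_squared(self):
        """Oracle: count pixels in the generated masks directly."""
        pair = ss.gen_hydration_pair(2.0, dry_radius_px=20.0)
        n_dry = (pair.frame_dry > 0.5).sum()
        n_wet = (pair.frame_wet > 0.5).sum()
        assert n_wet / n_dry == pytest.approx(4.0, rel=0.02)

    def test_sub_unity_growth_rejected(self):
        with pytest.raises(ValueError):
            ss.gen_hydration_pair(0.9)

    def test_seeded_determinism(self):
        a = ss.gen_hydration_pair(1.5, noise_sd=0.05, seed=3)
        b = ss.gen_hydration_pair(1.5, noise_sd=0.05, seed=3)
        np.testing.assert_array_equal(a.frame_dry, b.frame_dry)
        np.testing.assert_array_equal(a.frame_wet, b.frame_wet)


class TestStxmGenerator:
    def test_identity_ratio(self):
        dry, wet = ss.gen_stxm_pair(1.0)
        assert wet.integrated_od() == pytest.approx(dry.integrated_od())

    def test_intensities_obey_beer_lambert(self):
        dry, _ = ss.gen_stxm_pair(2.0)
        np.testing.assert_allclose(dry.intensity,
                                   np.asarray(dry.i0) * np.exp(-dry.od))

    def test_sub_unity_ratio_rejected(self):
        with pytest.raises(ValueError):
            ss.gen_stxm_pair(0.5)


class TestConcentrationSeries:
    def test_degenerate_constant_series(self):
        cfg = ss.SeriesConfig(n_days=20, spore_lognormal=(1.0, 1.0),
                              seasalt_lognormal=(0.3, 1.0),
                              scavenging_prob=0.0, season="dry", seed=0)
        s = ss.gen_concentration_series(cfg)
        assert (s["spore_ugm3"] == 1.0).all()
        assert (s["seasalt_ugm3"] == 0.3).all()
        f = ss.sodium_fraction(s["spore_ugm3"].to_numpy(),
                               s["seasalt_ugm3"].to_numpy())
        assert np.ptp(f) == 0.0  # every daily budget fraction identical

    def test_positive_and_deterministic(self):
        cfg = ss.SeriesConfig(n_days=100, seed=5)
        a = ss.gen_concentration_series(cfg)
        b = ss.gen_concentration_series(cfg)
        assert (a["spore_ugm3"] > 0).all() and (a["seasalt_ugm3"] > 0).all()
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_geometric_mean_recovers_median(self):
        cfg = ss.SeriesConfig(n_days=2000, season="dry", scavenging_prob=0.0,
                              seed=8)
        s = ss.gen_concentration_series(cfg)
        med, gsd = cfg.spore_lognormal
        gmean = math.exp(np.log(s["spore_ugm3"]).mean())
        se = math.log(gsd) / math.sqrt(cfg.n_days)
        assert abs(math.log(gmean) - math.log(med)) <= 3 * se

    def test_wet_season_seasalt_depleted(self):
        base = dict(n_days=300, seed=5)
        wet = ss.gen_concentration_series(ss.SeriesConfig(season="wet", **base))
        dry = ss.gen_concentration_series(ss.SeriesConfig(season="dry", **base))
        assert wet["seasalt_ugm3"].median() < dry["seasalt_ugm3"].median()

    def test_nighttime_enhancement_ratio(self, hourly_series):
        s = hourly_series
        night = (s["hour"] >= 18) | (s["hour"] < 6)
        ratio = (s.loc[night, "spore_ugm3"].mean()
                 / s.loc[~night, "spore_ugm3"].mean())
        assert ratio == pytest.approx(2.0)  # configured diurnal amplitude

    def test_hourly_mean_preserves_daily_value(self):
        cfg = ss.SeriesConfig(n_days=5, seed=2)
        daily = ss.gen_concentration_series(cfg)
        hourly = ss.gen_concentration_series(cfg, hourly=True)
        by_day = hourly.groupby("date")["spore_ugm3"].mean()
        np.testing.assert_allclose(by_day.to_numpy(),
                                   daily["spore_ugm3"].to_numpy())

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            ss.SeriesConfig(spore_lognormal=(0.0, 2.0))

    def test_spore_mass_number_conversion(self):
        # pi/6 * 4^3 = 33.51 pg per spore at unit density
        n = ss.spore_mass_to_number(1.0)
        assert float(n) == pytest.approx(1e6 / 33.5103, rel=1e-4)


class TestGridSeries:
    def test_single_cell_matches_plain_series(self):
        cfg = ss.SeriesConfig(n_days=30, seed=7)
        grid = ss.gen_grid_series(1, cfg)
        plain = ss.gen_concentration_series(cfg)
        pd.testing.assert_frame_equal(grid, plain)

    def test_seeded_determinism(self):
        cfg = ss.SeriesConfig(n_days=30, seed=7)
        a = ss.gen_grid_series(3, cfg)
        b = ss.gen_grid_series(3, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_doubled_seasalt_lowers_threshold_statistic(self):
        """Monotonicity oracle on the budget formula: more sea salt in a
        cell means fewer days with spores supplying >=50% of sodium."""
        cfg = ss.SeriesConfig(n_days=200, seed=13)
        grid = ss.gen_grid_series(4, cfg, gradient=[1.0, 1.0, 2.0, 2.0])
        table = ss.grid_map(grid)
        low = table[table["cell_id"].isin([0, 1])]["pct_days_ge_threshold"].mean()
        high = table[table["cell_id"].isin([2, 3])]["pct_days_ge_threshold"].mean()
        assert high < low
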