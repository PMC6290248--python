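"""Generators: weather, field sampling, cold-room treatments, depletion."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from conftest import make_cal
from wincarb.calibrate import objective
from wincarb.synthetic import (
    CC_DURATIONS,
    CC_TEMPERATURES,
    FieldGenConfig,
    WeatherGenConfig,
    default_true_params,
    generate_cc_experiment,
    generate_depleted_scenario,
    generate_field_dataset,
    generate_weather,
)


class TestWeather:
    def test_degenerate_config_gives_constant_series(self):
        cfg = WeatherGenConfig(n_days=50, annual_amplitude=0.0, noise_sd=0.0)
        w = generate_weather(cfg)
        assert (w["tmean"] == cfg.annual_mean).all()
        assert (w["tmax"] - w["tmin"] == cfg.diurnal_range).all()

    def test_seed_reproducibility(self):
        a = generate_weather(WeatherGenConfig(seed=3))
        b = generate_weather(WeatherGenConfig(seed=3))
        c = generate_weather(WeatherGenConfig(seed=4))
        pd.testing.assert_frame_equal(a, b)
        assert not a["tmean"].equals(c["tmean"])

    def test_residual_autocorrelation_matches_config(self):
        cfg = WeatherGenConfig(n_days=3650, ar1=0.6, seed=1)
        w = generate_weather(cfg)
        doy = pd.to_datetime(w["date"]).dt.dayofyear.to_numpy(dtype=float)
        seasonal = cfg.annual_mean + cfg.annual_amplitude * np.cos(
            2 * np.pi * (doy - 196.0) / 365.25
        )
        res = w["tmean"].to_numpy() - seasonal
        rho = np.corrcoef(res[:-1], res[1:])[0, 1]
        assert rho == pytest.approx(0.6, abs=0.1)
        assert res.std() == pytest.approx(cfg.noise_sd, rel=0.15)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            WeatherGenConfig(n_days=0)
        with pytest.raises(ValueError):
            WeatherGenConfig(ar1=1.0)


class TestFieldDataset:
    def test_zero_noise_observations_lie_on_latent_trajectory(self, zero_noise_season):
        ds = zero_noise_season
        merged = ds.observations.merge(ds.latent, on="date", suffixes=("_o", "_l"))
        np.testing.assert_allclose(merged["gfs_o"], merged["gfs_l"], atol=1e-12)
        np.testing.assert_allclose(merged["starch_o"], merged["starch_l"], atol=1e-12)
        np.testing.assert_allclose(merged["wc_o"], merged["wc_l"], atol=1e-12)

    def test_objective_at_truth_is_zero_on_zero_noise_data(self, zero_noise_season):
        cal = make_cal(zero_noise_season)
        assert objective(default_true_params(), [cal]) == 0.0

    def test_noise_magnitude_matches_config(self):
        devs = []
        for seed in range(12):
            cfg = FieldGenConfig(sd_gfs=5.0, sd_starch=0.0, sd_wc=0.0, sd_fh=0.0,
                                 seed=seed)
            w = generate_weather(WeatherGenConfig(start="2008-08-01", seed=0))
            ds = generate_field_dataset(w, cfg)
            m = ds.observations.merge(ds.latent, on="date", suffixes=("_o", "_l"))
            devs.extend((m["gfs_o"] - m["gfs_l"]).to_numpy())
        assert np.mean(np.square(devs)) == pytest.approx(25.0, rel=0.35)

    def test_latent_trajectory_shows_winter_interconversion_pattern(
        self, zero_noise_season
    ):
        """Starch falls and GFS rises into midwinter, then both reverse."""
        lat = zero_noise_season.latent
        i_min = int(lat["starch"].idxmin())
        assert 0 < i_min < len(lat) - 30  # midwinter minimum, not an endpoint
        assert lat["starch"].iloc[i_min] < 0.35 * lat["starch"].iloc[0]
        assert lat["gfs"].iloc[i_min] > 2.0 * lat["gfs"].iloc[0]
        assert lat["starch"].iloc[-1] > lat["starch"].iloc[i_min] + 10
        assert lat["gfs"].iloc[-1] < lat["gfs"].max() - 10

    def test_generation_is_reproducible(self):
        w = generate_weather(WeatherGenConfig(start="2008-08-01", seed=2))
        a = generate_field_dataset(w, FieldGenConfig(seed=5))
        b = generate_field_dataset(w, FieldGenConfig(seed=5))
        pd.testing.assert_frame_equal(a.observations, b.observations)


class TestControlledConditions:
    def test_default_grid_and_durations(self, zero_noise_season):
        date = zero_noise_season.latent["date"].iloc[60]
        table = generate_cc_experiment(zero_noise_season, date)
        assert sorted(set(table["temperature"])) == sorted(CC_TEMPERATURES)
        assert sorted(set(table["duration"])) == sorted(CC_DURATIONS)
        assert len(table) == 7 * 2

    def test_zero_duration_leaves_state_unchanged(self, zero_noise_season):
        date = zero_noise_season.latent["date"].iloc[60]
        table = generate_cc_experiment(zero_noise_season, date, durations=(0,))
        assert (table["gfs"] == table["gfs0"]).all()
        assert (table["dgfs_norm"] == 0.0).all()

    def test_cold_treatment_hydrolyses_starch_into_gfs(self, zero_noise_season):
        # at the cold-hydrolysis optimum, starch falls and GFS rises
        date = zero_noise_season.latent["date"].iloc[60]
        tp = default_true_params()
        table = generate_cc_experiment(
            zero_noise_season, date, temps=(tp.k1c.mu,), durations=(7,)
        )
        assert (table["gfs"] > table["gfs0"]).all()
        assert (table["starch"] < table["starch0"]).all()

    def test_date_outside_window_rejected(self, zero_noise_season):
        with pytest.raises(ValueError, match="outside"):
            generate_cc_experiment(zero_noise_season, "1999-01-01")


class TestDepletedScenario:
    def test_fraction_bounds(self):
        cfg = FieldGenConfig()
        assert generate_depleted_scenario(cfg, 0.0) == cfg
        depleted = generate_depleted_scenario(cfg, 1.0)
        assert depleted.init_state.starch == 0.0
        assert depleted.init_state.gfs == cfg.init_state.gfs
        with pytest.raises(ValueError):
            generate_depleted_scenario(cfg, 1.5)

    def test_depleted_run_differs_only_through_initial_state(self):
        w = generate_weather(WeatherGenConfig(start="2008-08-01", seed=2))
        base = FieldGenConfig(seed=5)
        depl = generate_depleted_scenario(base, 0.6)
        a = generate_field_dataset(w, base)
        b = generate_field_dataset(w, depl)
        pd.testing.assert_frame_equal(a.wc_truth, b.wc_truth)
        assert b.init.starch == pytest.approx(0.4 * a.init.starch)
        assert not np.allclose(a.latent["starch"], b.latent["starch"])
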