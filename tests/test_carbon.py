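"""Daily state updates, mass balance and the three model variants."""

import numpy as np
import pandas as pd
import pytest

from conftest import variant_params
from wincarb.carbon import CarbonState, ModelParams, interpolate_wc, simulate, step
from wincarb.kinetics import ReactionParams, RespirationParams
from wincarb.phenology import accumulate_phenology
from wincarb.synthetic import WeatherGenConfig, generate_weather


def _flat_reaction(k, km=None):
    return ReactionParams(k_trans=k, d_endo=0.0, d_eco=0.0, mu=5.0, sigma=100.0, km=km)


def _params(variant, k1c, k1m, k2, r_max=0.0, km=None):
    return ModelParams(
        variant=variant,
        k1c=_flat_reaction(k1c, km),
        k1m=_flat_reaction(k1m, km),
        k2=_flat_reaction(k2, km),
        resp=RespirationParams(r_max=r_max, a3=-8.0, b3=0.9, q10=2.0),
    )


class TestInterpolateWc:
    dates = pd.to_datetime(["2008-10-01", "2008-11-01"])

    def test_exact_at_knots_and_linear_between(self):
        assert interpolate_wc(self.dates, [0.8, 1.0], "2008-10-01") == 0.8
        mid = pd.Timestamp("2008-10-16")  # halfway through the 31-day gap
        assert interpolate_wc(self.dates, [0.8, 1.0], mid) == pytest.approx(
            0.8 + 0.2 * 15 / 31
        )

    def test_holds_nearest_outside_span_with_warning(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            assert interpolate_wc(self.dates, [0.8, 1.0], "2008-09-01") == 0.8

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            interpolate_wc([], [], "2008-10-01")


class TestStep:
    def test_no_fluxes_leave_state_unchanged(self):
        s0 = CarbonState(gfs=40.0, starch=80.0)
        for variant in ("simple", "intermediate"):
            p = _params(variant, 0.0, 0.0, 0.0, r_max=0.0)
            s1, r, fl = step(s0, 5.0, 0.9, 0.5, p)
            assert (s1.gfs, s1.starch, r, fl) == (40.0, 80.0, 0.0, False)

    def test_substrate_limitation_kills_hydrolysis(self):
        p = _params("intermediate", 0.05, 0.02, 0.0, r_max=0.0)
        s1, r, _ = step(CarbonState(gfs=40.0, starch=0.0), 5.0, 0.9, 0.5, p)
        assert s1.gfs == 40.0 and s1.starch == 0.0 and r == 0.0

    def test_interior_step_nsc_declines_by_respiration(self):
        p = _params("intermediate", 0.02, 0.01, 0.015, r_max=1.0)
        s0 = CarbonState(gfs=50.0, starch=70.0)
        s1, r, fl = step(s0, 10.0, 0.9, 0.5, p)
        assert not fl
        assert s1.nsc - s0.nsc == pytest.approx(-r, abs=1e-12)

    def test_flooring_scales_fluxes_and_keeps_pools_nonnegative(self):
        # zero-order fluxes overdraw a nearly empty GFS pool
        p = _params("simple", 0.0, 0.0, 5.0, r_max=5.0)
        s0 = CarbonState(gfs=2.0, starch=10.0)
        s1, r, fl = step(s0, 5.0, 0.9, 0.5, p)
        assert fl
        assert s1.gfs >= 0.0 and s1.starch >= 0.0
        assert r < 5.0  # realized respiration below the potential rate
        assert s1.nsc - s0.nsc == pytest.approx(-r, abs=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            _params("fancy", 0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def season():
    weather = generate_weather(WeatherGenConfig(start="2008-08-01", seed=7))
    pheno = accumulate_phenology(weather)
    sel = slice(75, 75 + 240)  # 240 leafless days from mid-October
    w = weather.iloc[sel].reset_index(drop=True)
    p = pheno.iloc[sel].reset_index(drop=True)
    d0 = w["date"].iloc[0]
    wc = pd.DataFrame(
        {"date": [d0, d0 + pd.Timedelta(days=240)], "wc": [0.85, 1.0]}
    )
    return w, wc, p


def test_one_day_series_gives_length_two_trajectory(season):
    w, wc, p = season
    params = variant_params("intermediate")
    init = CarbonState(gfs=30.0, starch=95.0)
    traj = simulate(w.iloc[:1], wc, p.iloc[:1], init, params)
    assert len(traj) == 2
    expected, r, _ = step(
        init, float(w["tmean"].iloc[0]), float(traj["wc"].iloc[0]),
        float(p["ps"].iloc[0]), params,
    )
    assert traj["gfs"].iloc[1] == pytest.approx(expected.gfs, abs=1e-12)
    assert traj["starch"].iloc[1] == pytest.approx(expected.starch, abs=1e-12)
    assert traj["respiration"].iloc[0] == pytest.approx(r, abs=1e-12)


def test_constant_cold_week_matches_manual_steps(season):
    _, wc, _ = season
    params = variant_params("intermediate")
    d0 = pd.Timestamp("2008-10-15")
    w = pd.DataFrame(
        {"date": pd.date_range(d0, periods=7), "tmin": -3.0, "tmean": -3.0, "tmax": -3.0}
    )
    p = pd.DataFrame({"date": w["date"], "ps": np.full(7, 0.4)})
    state = CarbonState(gfs=30.0, starch=95.0)
    traj = simulate(w, wc, p, state, params)
    for t in range(7):
        state, _, _ = step(state, -3.0, float(traj["wc"].iloc[t]), 0.4, params)
    assert traj["gfs"].iloc[-1] == pytest.approx(state.gfs, abs=1e-12)
    assert traj["starch"].iloc[-1] == pytest.approx(state.starch, abs=1e-12)


@pytest.mark.parametrize("variant", ["simple", "intermediate", "complete"])
def test_mass_balance_over_a_season(season, variant):
    """Absent flooring, NSC declines by exactly the realized respiration."""
    w, wc, p = season
    traj = simulate(w, wc, p, CarbonState(gfs=30.0, starch=95.0), variant_params(variant))
    nsc = (traj["gfs"] + traj["starch"]).to_numpy()
    dnsc = np.diff(nsc)
    r = traj["respiration"].to_numpy()[:-1]
    interior = ~traj["floored"].to_numpy()[:-1]
    assert interior.sum() > 100
    np.testing.assert_allclose(dnsc[interior], -r[interior], atol=1e-10)
    # cumulative NSC loss equals summed realized respiration even with flooring
    assert nsc[0] - nsc[-1] == pytest.approx(traj["respiration"].sum(), abs=1e-8)


def test_complete_reduces_to_intermediate_at_large_km(season):
    w, wc, p = season
    inter = variant_params("intermediate")
    km = 1e6

    def as_complete(rp):
        return ReactionParams(
            k_trans=rp.k_trans * km, d_endo=rp.d_endo * km, d_eco=rp.d_eco * km,
            mu=rp.mu, sigma=rp.sigma, km=km,
        )

    comp = ModelParams(
        variant="complete",
        k1c=as_complete(inter.k1c),
        k1m=as_complete(inter.k1m),
        k2=as_complete(inter.k2),
        resp=inter.resp,
    )
    init = CarbonState(gfs=30.0, starch=95.0)
    ti = simulate(w, wc, p, init, inter)
    tc = simulate(w, wc, p, init, comp)
    np.testing.assert_allclose(tc["gfs"], ti["gfs"], rtol=0.01)
    np.testing.assert_allclose(tc["starch"], ti["starch"], rtol=0.01, atol=0.3)


def test_simulation_is_deterministic(season):
    w, wc, p = season
    params = variant_params("intermediate")
    init = CarbonState(gfs=30.0, starch=95.0)
    t1 = simulate(w, wc, p, init, params)
    t2 = simulate(w, wc, p, init, params)
    pd.testing.assert_frame_equal(t1, t2)


def test_date_misalignment_rejected(season):
    w, wc, p = season
    with pytest.raises(ValueError, match="align"):
        simulate(w.iloc[:-1], wc, p, CarbonState(gfs=30, starch=95),
                 variant_params("intermediate"))


def test_model_params_km_consistency():
    tp = variant_params("intermediate")
    with pytest.raises(ValueError, match="km"):
        ModelParams(variant="complete", k1c=tp.k1c, k1m=tp.k1m, k2=tp.k2, resp=tp.resp)
    cp = variant_params("complete")
    with pytest.raises(ValueError, match="km"):
        ModelParams(variant="simple", k1c=cp.k1c, k1m=cp.k1m, k2=cp.k2, resp=cp.resp)
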