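"""Shared fixtures: synthetic seasons and the heavyweight calibration fits.

The expensive multistart fits are session-scoped so the recovery,
discrimination and self-consistency checks share work.
"""

from __future__ import annotations

import pytest

from wincarb.calibrate import CalibrationDataset, fit
from wincarb.carbon import ModelParams
from wincarb.kinetics import ReactionParams
from wincarb.synthetic import (
    FieldGenConfig,
    WeatherGenConfig,
    default_true_params,
    generate_field_dataset,
    generate_weather,
    multi_season_datasets,
)


def make_cal(ds, role: str = "calibration") -> CalibrationDataset:
    """Wrap a synthetic FieldDataset for the calibration machinery."""
    return CalibrationDataset(
        weather=ds.weather,
        pheno=ds.pheno,
        wc_obs=ds.observations[["date", "wc"]],
        init=ds.init,
        observations=ds.observations,
        role=role,
    )


def variant_params(variant: str) -> ModelParams:
    """Ground-truth-shaped parameters expressed in each variant's units.

    The intermediate truth rates (day^-1) are converted to zero-order
    fluxes (x a typical 60 mg/g substrate pool) for the simple variant and
    to maximal velocities (x Km + typical pool, Km = 300) for the complete
    one, so all three produce comparable seasonal dynamics.
    """
    tp = default_true_params()
    if variant == "intermediate":
        return tp

    def scaled(rp: ReactionParams, factor: float, km: float | None) -> ReactionParams:
        return ReactionParams(
            k_trans=rp.k_trans * factor,
            d_endo=rp.d_endo * factor,
            d_eco=rp.d_eco * factor,
            mu=rp.mu,
            sigma=rp.sigma,
            km=km,
        )

    if variant == "simple":
        f, km = 60.0, None
    elif variant == "complete":
        f, km = 360.0, 300.0
    else:
        raise ValueError(variant)
    return ModelParams(
        variant=variant,
        k1c=scaled(tp.k1c, f, km),
        k1m=scaled(tp.k1m, f, km),
        k2=scaled(tp.k2, f, km),
        resp=tp.resp,
    )


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def zero_noise_season():
    cfg = FieldGenConfig(sd_gfs=0.0, sd_starch=0.0, sd_wc=0.0, sd_fh=0.0)
    weather = generate_weather(WeatherGenConfig(start="2008-08-01", seed=0))
    return generate_field_dataset(weather, cfg)


@pytest.fixture(scope="session")
def noisy_seasons():
    """Three independent seasons with monthly sampling and 5 mg/g pool noise."""
    return multi_season_datasets(3, seed=1)


@pytest.fixture(scope="session")
def recovery_fit(noisy_seasons):
    """Intermediate-variant fit of all three noisy seasons (10 LHS starts)."""
    cals = [make_cal(d) for d in noisy_seasons]
    return fit(cals, "intermediate", n_starts=10, max_evals=8000, seed=1)


@pytest.fixture(scope="session")
def depleted_validation_season():
    """A held-out season from NSC-depleted branches (defoliation emulation).

    Depletion is the discriminating challenge: zero-order fluxes calibrated
    on normal pools overshoot when the starting pools are small, whereas
    substrate-limited fluxes scale down automatically."""
    from wincarb.synthetic import generate_depleted_scenario

    wcfg = WeatherGenConfig(start="2011-08-01", seed=1 * 1009 + 6)
    fcfg = generate_depleted_scenario(FieldGenConfig(seed=1 * 1013 + 7), 0.6)
    return generate_field_dataset(generate_weather(wcfg), fcfg)


@pytest.fixture(scope="session")
def discrimination_fits(noisy_seasons, depleted_validation_season):
    """All three variants fitted to the three normal seasons, with the
    depleted season held out for validation."""
    cal = [make_cal(d) for d in noisy_seasons]
    val = [make_cal(depleted_validation_season, role="validation")]
    out = {}
    for variant in ("simple", "intermediate", "complete"):
        out[variant] = fit(cal + val, variant, n_starts=10, max_evals=8000, seed=1)
    return out
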