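"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the two data sources the model is
designed for: a multi-year orchard series (roughly monthly destructive
sampling of branch GFS, starch, water content and frost hardiness, driven
by mid-latitude temperate weather) and the cold-room experiment (detached
branches held at constant temperatures from -3 to +25 degC for 7 and ~20
days at three phenological dates).  All outputs are pure functions of
their configuration, including the seed.

The default ground truth uses the intermediate (substrate-limited) model
variant with temperature optima inside the published seasonal-response
ranges: cold hydrolysis at -0.1 degC, mild hydrolysis at 17 degC and
re-synthesis at 13 degC, and a respiration Q10 of 2.64.  Under the default
weather these parameters reproduce the canonical winter pattern - starch
falls and soluble sugars rise into midwinter, then the conversion reverses
during late winter - which is asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .carbon import CarbonState, ModelParams, simulate
from .frost import FHParams, predict_fh
from .kinetics import ReactionParams, RespirationParams
from .phenology import PhenologyParams, accumulate_phenology, forcing_increment, chilling_increment

__all__ = [
    "WeatherGenConfig",
    "FieldGenConfig",
    "FieldDataset",
    "default_true_params",
    "generate_weather",
    "generate_field_dataset",
    "multi_season_datasets",
    "generate_cc_experiment",
    "generate_depleted_scenario",
]

CC_TEMPERATURES = (-3.0, 1.0, 5.0, 10.0, 15.0, 20.0, 25.0)
CC_DURATIONS = (7, 20)


def default_true_params(variant: str = "intermediate") -> ModelParams:
    """Ground-truth kinetic parameters of the synthetic orchard.

    Rates are per day (intermediate variant).  Stage differences are set so
    cold hydrolysis dominates endodormancy, mild hydrolysis is strongest in
    autumn, and re-synthesis switches on during ecodormancy.
    """
    if variant != "intermediate":
        raise ValueError("ground truth is defined for the intermediate variant")
    return ModelParams(
        variant="intermediate",
        k1c=ReactionParams(k_trans=0.045, d_endo=0.01, d_eco=-0.05, mu=-0.1, sigma=5.0),
        k1m=ReactionParams(k_trans=0.012, d_endo=-0.06, d_eco=0.0, mu=17.0, sigma=5.0),
        k2=ReactionParams(k_trans=0.012, d_endo=0.012, d_eco=0.06, mu=13.0, sigma=5.0),
        resp=RespirationParams(r_max=1.2, a3=-8.0, b3=0.9, q10=2.64),
    )


@dataclass(frozen=True)
class WeatherGenConfig:
    """Seasonal sinusoid plus AR(1) day-to-day noise, central-France-like."""

    start: str = "2008-01-01"
    n_days: int = 540
    annual_mean: float = 11.0
    annual_amplitude: float = 8.5
    diurnal_range: float = 8.0
    noise_sd: float = 3.5
    ar1: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.annual_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise SD must be nonnegative")
        if not 0 <= self.ar1 < 1:
            raise ValueError("lag-1 autocorrelation must be in [0, 1)")


def generate_weather(cfg: WeatherGenConfig = WeatherGenConfig()) -> pd.DataFrame:
    """Daily weather frame with columns date, tmin, tmean, tmax."""
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = cfg.annual_mean + cfg.annual_amplitude * np.cos(
        2.0 * np.pi * (doy - 196.0) / 365.25
    )
    eps = np.zeros(cfg.n_days)
    if cfg.noise_sd > 0:
        innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar1**2)
        eps[0] = rng.normal(0.0, cfg.noise_sd)
        shocks = rng.normal(0.0, innov_sd, size=cfg.n_days)
        for t in range(1, cfg.n_days):
            eps[t] = cfg.ar1 * eps[t - 1] + shocks[t]
    tmean = seasonal + eps
    half = cfg.diurnal_range / 2.0
    return pd.DataFrame(
        {"date": dates, "tmin": tmean - half, "tmean": tmean, "tmax": tmean + half}
    )


@dataclass(frozen=True)
class FieldGenConfig:
    """Roughly monthly destructive sampling of one latent branch trajectory.

    ``wc_knots`` are (day offset from the first observation, g water per g
    DM) pairs defining the piecewise-linear seasonal water-content profile;
    ``start_offset`` places the first autumn observation that many days
    after the chilling start day (day-of-year 244).
    """

    true_params: ModelParams = field(default_factory=default_true_params)
    fh_params: FHParams = field(default_factory=FHParams)
    init_state: CarbonState = CarbonState(gfs=30.0, starch=95.0)
    wc_knots: tuple = ((0, 0.85), (60, 0.75), (120, 0.70), (180, 0.90), (240, 1.05))
    start_offset: int = 45
    sampling_interval: int = 30
    sd_gfs: float = 5.0
    sd_starch: float = 5.0
    sd_wc: float = 0.03
    sd_fh: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_gfs, self.sd_starch, self.sd_wc, self.sd_fh) < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class FieldDataset:
    """Noisy observations plus the noiseless latent truth behind them."""

    observations: pd.DataFrame  # date, gfs, starch, wc, fh
    latent: pd.DataFrame  # daily trajectory incl. fh column
    weather: pd.DataFrame  # window used for simulation
    pheno: pd.DataFrame  # aligned phenology window
    wc_truth: pd.DataFrame  # noiseless wc knots (date, wc)
    init: CarbonState


def generate_field_dataset(
    weather: pd.DataFrame,
    cfg: FieldGenConfig = FieldGenConfig(),
    pheno_params: PhenologyParams = PhenologyParams(),
) -> FieldDataset:
    """Run the full truth chain over one season and sample it.

    The season is keyed to the first occurrence of the chilling start day
    in ``weather``; the simulation window runs from the first observation
    (``start_offset`` days later) to budburst (PS = 2) or the end of the
    weather series.
    """
    rng = np.random.default_rng(cfg.seed)
    pheno_full = accumulate_phenology(weather, pheno_params)
    dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    doy = dates.dt.dayofyear.to_numpy()
    i0 = int(np.flatnonzero(doy == pheno_params.start_doy)[0]) + cfg.start_offset
    if i0 >= len(dates):
        raise ValueError("weather too short for the requested start offset")
    bud = np.flatnonzero(pheno_full["ps"].to_numpy() >= 2.0)
    i1 = int(bud[0]) + 1 if len(bud) else len(dates)
    if i1 - i0 < 2 * cfg.sampling_interval:
        raise ValueError("simulation window too short to sample")

    w = weather.iloc[i0:i1].reset_index(drop=True)
    p = pheno_full.iloc[i0:i1].reset_index(drop=True)
    d0 = dates.iloc[i0]
    wc_truth = pd.DataFrame(
        {
            "date": [d0 + pd.Timedelta(days=int(off)) for off, _ in cfg.wc_knots],
            "wc": [v for _, v in cfg.wc_knots],
        }
    )
    latent = simulate(w, wc_truth, p, cfg.init_state, cfg.true_params)
    latent = latent.assign(
        fh=predict_fh(
            np.maximum(latent["gfs"].to_numpy(), 1e-9),
            np.maximum(latent["wc"].to_numpy(), 1e-9),
            cfg.fh_params,
        )
    )

    n_window = i1 - i0
    samp_off = np.arange(0, n_window, cfg.sampling_interval)
    lat = latent.iloc[samp_off]
    obs = pd.DataFrame(
        {
            "date": lat["date"].to_numpy(),
            "gfs": np.maximum(
                lat["gfs"].to_numpy() + rng.normal(0, cfg.sd_gfs, len(samp_off)), 0.5
            ),
            "starch": np.maximum(
                lat["starch"].to_numpy() + rng.normal(0, cfg.sd_starch, len(samp_off)),
                0.0,
            ),
            "wc": np.maximum(
                lat["wc"].to_numpy() + rng.normal(0, cfg.sd_wc, len(samp_off)), 0.05
            ),
            "fh": lat["fh"].to_numpy() + rng.normal(0, cfg.sd_fh, len(samp_off)),
        }
    )
    return FieldDataset(
        observations=obs,
        latent=latent,
        weather=w,
        pheno=p,
        wc_truth=wc_truth,
        init=cfg.init_state,
    )


def multi_season_datasets(
    n_seasons: int,
    field_cfg: FieldGenConfig = FieldGenConfig(),
    weather_cfg: WeatherGenConfig = WeatherGenConfig(),
    seed: int = 0,
) -> list[FieldDataset]:
    """Independent seasons with season-specific weather and noise seeds.

    Season ``i`` uses weather starting 1 August of year ``2008 + i`` and
    runs for ``weather_cfg.n_days`` days (default 540, comfortably past
    budburst)."""
    out = []
    for i in range(n_seasons):
        wcfg = replace(weather_cfg, start=f"{2008 + i}-08-01", seed=seed * 1009 + 2 * i)
        fcfg = replace(field_cfg, seed=seed * 1013 + 2 * i + 1)
        out.append(generate_field_dataset(generate_weather(wcfg), fcfg))
    return out


def _continue_phenology(
    cu0: float, fu0: float, theta: float, n_days: int, params: PhenologyParams
) -> np.ndarray:
    """PS trajectory over a constant-temperature storage, continuing the
    field accumulation state (cu0, fu0)."""
    ps = np.empty(n_days)
    cu, fu = cu0, fu0
    for t in range(n_days):
        ps[t] = min(cu / params.cu_crit, 1.0) + min(fu / params.fu_crit, 1.0)
        if cu >= params.cu_crit:
            fu += forcing_increment(theta, params)
        else:
            cu += chilling_increment(theta, params)
    return ps


def generate_cc_experiment(
    field: FieldDataset,
    sampling_date,
    true_params: ModelParams | None = None,
    temps=CC_TEMPERATURES,
    durations=CC_DURATIONS,
    pheno_params: PhenologyParams = PhenologyParams(),
) -> pd.DataFrame:
    """Constant-temperature storage of detached branches.

    Branches are taken from the latent field trajectory at
    ``sampling_date``; during storage the water content is held at its
    sampling-day value (cut ends sealed) while dormancy continues to
    accumulate at the treatment temperature.  Returns one row per
    (temperature, duration) with final pools and normalized daily changes
    (dGFS/day / initial starch; dStarch/day / initial GFS).
    """
    from .carbon import _advance, _stage_series

    if true_params is None:
        true_params = default_true_params()
    lat = field.latent
    dates = pd.to_datetime(lat["date"])
    sel = np.flatnonzero(dates == pd.Timestamp(sampling_date))
    if len(sel) == 0:
        raise ValueError(f"{sampling_date} is outside the field simulation window")
    row = lat.iloc[int(sel[0])]
    prow = field.pheno.iloc[min(int(sel[0]), len(field.pheno) - 1)]
    gfs0, starch0, wc0 = float(row["gfs"]), float(row["starch"]), float(row["wc"])
    cu0, fu0 = float(prow["cu"]), float(prow["fu"])

    records = []
    for theta in temps:
        for dur in durations:
            ps = _continue_phenology(cu0, fu0, theta, max(int(dur), 1), pheno_params)
            th = np.full(max(int(dur), 1), float(theta))
            k1c = _stage_series(true_params.k1c, th, ps)
            k1m = _stage_series(true_params.k1m, th, ps)
            k2 = _stage_series(true_params.k2, th, ps)
            from .kinetics import respiration_rate

            r_pot = respiration_rate(th, np.full_like(th, wc0), true_params.resp)
            g, s = gfs0, starch0
            for t in range(int(dur)):
                g, s, _, _ = _advance(g, s, k1c[t], k1m[t], k2[t], r_pot[t], true_params)
            dur_eff = max(int(dur), 1)
            records.append(
                {
                    "temperature": float(theta),
                    "duration": int(dur),
                    "gfs0": gfs0,
                    "starch0": starch0,
                    "gfs": g,
                    "starch": s,
                    "dgfs_norm": ((g - gfs0) / dur_eff / starch0) if int(dur) else 0.0,
                    "dstarch_norm": ((s - starch0) / dur_eff / gfs0) if int(dur) else 0.0,
                }
            )
    return pd.DataFrame(records)


def generate_depleted_scenario(
    cfg: FieldGenConfig, fraction: float = 0.6
) -> FieldGenConfig:
    """Config variant emulating the defoliated (NSC-depleted) trees:
    initial starch reduced by ``fraction``, everything else equal."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    init = cfg.init_state
    return replace(
        cfg, init_state=CarbonState(gfs=init.gfs, starch=init.starch * (1.0 - fraction))
    )
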