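"""Daily simulation of the starch / soluble-sugar balance of a dormant branch.

Three nested model variants share the same state (GFS and starch pools,
mg per g dry matter) and differ only in how the catalytic rates act on the
pools:

* ``simple`` - zero-order fluxes: hydrolysis ``H = k1c + k1m`` and
  re-synthesis ``S = k2`` are rates in mg gDM^-1 day^-1, independent of the
  pools.
* ``intermediate`` - first-order in substrate: ``H = (k1c + k1m) * Starch``
  and ``S = k2 * GFS`` with the k's in day^-1.
* ``complete`` - Michaelis-Menten: ``H = [v1c/(Km1c + Starch) +
  v1m/(Km1m + Starch)] * Starch`` and ``S = v2/(Km2 + GFS) * GFS``, where
  each maximal velocity v follows the same temperature-by-stage law as the
  corresponding k.

The daily update is

    GFS(t+1)    = GFS(t)    + H - S - R
    Starch(t+1) = Starch(t) - (GFS(t+1) - GFS(t)) - R

so that, whenever no pool is exhausted, total non-structural carbohydrate
(NSC = GFS + starch) declines by exactly the respiration R of that day.
Respiration is drawn from the GFS pool.  When a day's demanded out-fluxes
exceed a pool, the out-fluxes of that pool are rescaled by the ratio
available/demanded, which keeps both pools nonnegative and preserves the
NSC balance with the realized (reduced) respiration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import ReactionParams, RespirationParams, respiration_rate

__all__ = [
    "CarbonState",
    "ModelParams",
    "VARIANTS",
    "interpolate_wc",
    "step",
    "simulate",
]

VARIANTS = ("simple", "intermediate", "complete")


@dataclass(frozen=True)
class CarbonState:
    """GFS and starch pools, mg per g dry matter."""

    gfs: float
    starch: float

    def __post_init__(self) -> None:
        if self.gfs < 0 or self.starch < 0:
            raise ValueError("carbon pools must be nonnegative")

    @property
    def nsc(self) -> float:
        return self.gfs + self.starch


@dataclass(frozen=True)
class ModelParams:
    """Everything the optimiser fits: one reaction block per catalytic
    activity plus the respiration block.

    The free-parameter count is 19 for the simple and intermediate variants
    (5 per reaction + 4 respiration) and 22 for the complete variant (one
    Michaelis constant per reaction on top).
    """

    variant: str
    k1c: ReactionParams
    k1m: ReactionParams
    k2: ReactionParams
    resp: RespirationParams

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")
        kms = [self.k1c.km, self.k1m.km, self.k2.km]
        if self.variant == "complete":
            if any(km is None for km in kms):
                raise ValueError("complete variant requires km on all three reactions")
        elif any(km is not None for km in kms):
            raise ValueError(f"{self.variant} variant must not carry km")

    @property
    def n_free(self) -> int:
        return 22 if self.variant == "complete" else 19


def interpolate_wc(obs_dates, obs_wc, days):
    """Water content linearly interpolated between sampling dates.

    Outside the observed span the nearest observed value is held, with a
    warning.  ``days`` may be a scalar date or a date array.
    """
    obs_dates = pd.to_datetime(pd.Series(obs_dates)).to_numpy()
    obs_wc = np.asarray(obs_wc, dtype=float)
    if len(obs_dates) == 0:
        raise ValueError("no water-content observations to interpolate")
    order = np.argsort(obs_dates)
    obs_dates, obs_wc = obs_dates[order], obs_wc[order]
    scalar = np.ndim(days) == 0 and not isinstance(days, (list, tuple))
    q = pd.to_datetime(pd.Series([days] if scalar else days)).to_numpy()
    if (q < obs_dates[0]).any() or (q > obs_dates[-1]).any():
        warnings.warn(
            "water content extrapolated by holding the nearest observation",
            stacklevel=2,
        )
    t0 = obs_dates[0]
    x = (q - t0) / np.timedelta64(1, "D")
    xp = (obs_dates - t0) / np.timedelta64(1, "D")
    out = np.interp(x, xp, obs_wc)
    return float(out[0]) if scalar else out


def _stage_series(rp: ReactionParams, theta: np.ndarray, ps: np.ndarray) -> np.ndarray:
    """Vectorised catalytic-rate law over aligned theta/PS arrays."""
    endo = ps < 1.0
    a = np.where(endo, (rp.k_trans + rp.d_endo) / 2.0, (rp.k_trans + rp.d_eco) / 2.0)
    b = np.where(endo, (rp.k_trans - rp.d_endo) / 2.0, (rp.k_trans - rp.d_eco) / 2.0)
    gauss = np.exp(-((theta - rp.mu) ** 2) / (rp.sigma * 2.0 * np.pi))
    return np.maximum(0.0, (a * ps + b) * gauss)


def _advance(
    gfs: float,
    starch: float,
    k1c: float,
    k1m: float,
    k2: float,
    r_pot: float,
    params: ModelParams,
) -> tuple[float, float, float, bool]:
    """One daily update from precomputed rate coefficients.

    Returns (gfs', starch', realized respiration, floored?).
    """
    variant = params.variant
    if variant == "simple":
        h = k1c + k1m
        s = k2
    elif variant == "intermediate":
        h = (k1c + k1m) * starch
        s = k2 * gfs
    else:  # complete
        h = (
            k1c / (params.k1c.km + starch) + k1m / (params.k1m.km + starch)
        ) * starch
        s = k2 / (params.k2.km + gfs) * gfs

    floored = False
    if h > starch:
        h = starch  # hydrolysis limited by the starch pool
        floored = True
    out = s + r_pot
    if out > gfs:
        scale = gfs / out if out > 0 else 0.0
        s *= scale
        r = r_pot * scale
        floored = True
    else:
        r = r_pot
    new_gfs = gfs + h - s - r
    new_starch = starch - h + s
    # guard against tiny negative round-off
    return max(new_gfs, 0.0), max(new_starch, 0.0), r, floored


def step(
    state: CarbonState,
    theta: float,
    wc: float,
    ps: float,
    params: ModelParams,
) -> tuple[CarbonState, float, bool]:
    """Advance the state by one day; returns (new state, realized
    respiration, whether any flux was rescaled by pool exhaustion)."""
    from .kinetics import catalytic_rate

    k1c = catalytic_rate(theta, ps, params.k1c)
    k1m = catalytic_rate(theta, ps, params.k1m)
    k2 = catalytic_rate(theta, ps, params.k2)
    r_pot = respiration_rate(theta, wc, params.resp)
    g, s, r, fl = _advance(state.gfs, state.starch, k1c, k1m, k2, r_pot, params)
    return CarbonState(gfs=g, starch=s), r, fl


def simulate(
    weather: pd.DataFrame,
    wc_obs: pd.DataFrame,
    pheno: pd.DataFrame,
    init: CarbonState,
    params: ModelParams,
) -> pd.DataFrame:
    """Run the daily carbon balance over a weather window.

    ``weather`` and ``pheno`` must cover the same dates; ``wc_obs`` is a
    frame with ``date`` and ``wc`` columns used for linear interpolation.
    The trajectory has one row per weather day plus a terminal row holding
    the state after the final day; row 0 equals ``init`` exactly.
    """
    from .phenology import daily_mean_temperature

    w_dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    p_dates = pd.to_datetime(pheno["date"]).reset_index(drop=True)
    if len(w_dates) != len(p_dates) or not (w_dates == p_dates).all():
        raise ValueError("weather and phenology series are not date-aligned")

    theta = daily_mean_temperature(weather)
    ps = pheno["ps"].to_numpy(dtype=float)
    n = len(theta)
    all_dates = pd.DatetimeIndex(
        list(w_dates) + [w_dates.iloc[-1] + pd.Timedelta(days=1)]
    )
    wc = interpolate_wc(wc_obs["date"], wc_obs["wc"], all_dates)

    k1c = _stage_series(params.k1c, theta, ps)
    k1m = _stage_series(params.k1m, theta, ps)
    k2 = _stage_series(params.k2, theta, ps)
    r_pot = respiration_rate(theta, wc[:n], params.resp)

    gfs = np.empty(n + 1)
    starch = np.empty(n + 1)
    resp = np.zeros(n + 1)
    floored = np.zeros(n + 1, dtype=bool)
    gfs[0], starch[0] = init.gfs, init.starch
    g, s = init.gfs, init.starch
    for t in range(n):
        g, s, r, fl = _advance(g, s, k1c[t], k1m[t], k2[t], r_pot[t], params)
        gfs[t + 1], starch[t + 1] = g, s
        resp[t] = r  # respiration realized during day t
        floored[t] = fl

    return pd.DataFrame(
        {
            "date": all_dates,
            "theta": np.append(theta, np.nan),
            "wc": wc,
            "ps": np.append(ps, ps[-1] if n else np.nan),
            "gfs": gfs,
            "starch": starch,
            "respiration": resp,
            "floored": floored,
        }
    )
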