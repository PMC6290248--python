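"""Dormancy phenology: chilling units, forcing units and the stage index.

The walnut dormancy model is sequential: endodormancy is released by
accumulated chilling (an inverse-Richardson function of daily mean
temperature), after which ecodormancy is released by accumulated forcing
(a temperature sigmoid).  The phenological stage index PS runs from 0
(onset of endodormancy) through 1 (endo-to-eco transition) to 2 (budburst)
and is the ratio of thermal time to thermal requirement in each phase:

    PS = min(CU/CU_crit, 1) + min(FU/FU_crit, 1)

Chilling starts accumulating on a fixed calendar day (day of year ``T0``,
default 244, i.e. 1 September), from zero; forcing starts on the first day
after CU reaches ``CU_crit``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhenologyParams",
    "chilling_increment",
    "forcing_increment",
    "accumulate_phenology",
]


@dataclass(frozen=True)
class PhenologyParams:
    """Constants of the sequential chilling/forcing dormancy model.

    Defaults are the published walnut (cv. Franquette) values: chilling
    accumulates linearly between ``t_high`` (26.7 degC, no chilling above)
    and ``t_low`` (3.1 degC, maximal chilling below), from day of year 244;
    forcing follows a sigmoid with midpoint ``t50`` = 13.46 degC and slope
    0.244 per degC.
    """

    start_doy: int = 244
    t_low: float = 3.1
    t_high: float = 26.7
    cu_crit: float = 2298.8
    slp: float = 0.244
    t50: float = 13.46
    fu_crit: float = 21.2

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")
        if self.cu_crit <= 0 or self.fu_crit <= 0:
            raise ValueError("cu_crit and fu_crit must be positive")
        if self.slp <= 0:
            raise ValueError("slp must be positive (forcing increases with temperature)")


def chilling_increment(theta, params: PhenologyParams = PhenologyParams()):
    """Daily chilling-unit increment at mean temperature ``theta`` (degC).

    ``max(min(T_high - theta, T_high - T_low), 0)``: zero above ``t_high``,
    a plateau of ``t_high - t_low`` below ``t_low``, linear in between.
    Accepts scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite temperature in chilling_increment")
    inc = np.maximum(np.minimum(params.t_high - theta, params.t_high - params.t_low), 0.0)
    return inc if inc.ndim else float(inc)


def forcing_increment(theta, params: PhenologyParams = PhenologyParams()):
    """Daily forcing-unit increment: logistic in ``theta``, in (0, 1)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite temperature in forcing_increment")
    inc = 1.0 / (1.0 + np.exp(-params.slp * (theta - params.t50)))
    return inc if inc.ndim else float(inc)


def daily_mean_temperature(weather: pd.DataFrame) -> np.ndarray:
    """Mean temperature column, falling back to (tmin + tmax)/2 per row."""
    if "tmean" in weather.columns:
        tmean = weather["tmean"].to_numpy(dtype=float)
        missing = ~np.isfinite(tmean)
        if missing.any():
            tmean = tmean.copy()
            tmean[missing] = (
                weather["tmin"].to_numpy(dtype=float)[missing]
                + weather["tmax"].to_numpy(dtype=float)[missing]
            ) / 2.0
        return tmean
    return (
        weather["tmin"].to_numpy(dtype=float) + weather["tmax"].to_numpy(dtype=float)
    ) / 2.0


def _check_daily(dates: pd.Series) -> None:
    d = pd.to_datetime(dates)
    if len(d) > 1:
        steps = np.diff(d.to_numpy()).astype("timedelta64[D]").astype(int)
        if np.any(steps != 1):
            raise ValueError("weather dates must be strictly increasing with daily step")


def accumulate_phenology(
    weather: pd.DataFrame,
    params: PhenologyParams = PhenologyParams(),
    stop_at_budburst: bool = False,
) -> pd.DataFrame:
    """Accumulate CU, FU and PS over a daily weather series.

    Chilling accumulates from the first day whose day-of-year equals
    ``params.start_doy`` (CU = 0 on that day's increment start, i.e. the
    increment of the start day is counted).  Forcing starts on the first
    day after CU has reached ``cu_crit``.  For PS the chilling term is
    capped at 1; the returned ``cu`` column is the raw, uncapped sum for
    diagnostics.

    Parameters
    ----------
    weather
        DataFrame with ``date`` and temperature columns (``tmean`` or
        ``tmin``/``tmax``), strictly daily.
    stop_at_budburst
        If true the series ends on the first day with PS = 2.

    Returns
    -------
    DataFrame with columns ``date, theta, cu, fu, ps``.
    """
    if len(weather) == 0:
        raise ValueError("empty weather series")
    dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    _check_daily(dates)
    doy = dates.dt.dayofyear.to_numpy()
    start_idx = np.flatnonzero(doy == params.start_doy)
    if len(start_idx) == 0:
        raise ValueError(
            f"weather series never reaches day-of-year {params.start_doy} (T0)"
        )
    i0 = int(start_idx[0])

    theta = daily_mean_temperature(weather)
    n = len(dates)
    cu = np.zeros(n)
    fu = np.zeros(n)
    ps = np.zeros(n)

    cu_inc = chilling_increment(theta, params)
    fu_inc = forcing_increment(theta, params)

    # State recorded on day t is the accumulation *before* day t's weather
    # acts, so CU = 0 on the start day and the forcing sum first appears the
    # day after endodormancy release.
    running_cu = 0.0
    running_fu = 0.0
    end = n
    for t in range(i0, n):
        cu[t] = running_cu
        fu[t] = running_fu
        ps[t] = min(running_cu / params.cu_crit, 1.0) + min(
            running_fu / params.fu_crit, 1.0
        )
        if stop_at_budburst and ps[t] >= 2.0:
            end = t + 1
            break
        if running_cu >= params.cu_crit:
            running_fu += fu_inc[t]
        else:
            running_cu += cu_inc[t]

    out = pd.DataFrame(
        {"date": dates, "theta": theta, "cu": cu, "fu": fu, "ps": ps}
    ).iloc[:end]
    return out.reset_index(drop=True)
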