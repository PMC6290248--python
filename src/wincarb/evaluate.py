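"""Goodness-of-fit metrics, temperature-window correlation scan and the
three-Gaussian decomposition of controlled-temperature response curves.

Model efficiency (Nash-Sutcliffe form) and RMSE:

    Eff  = (SS_tot - SS_res) / SS_tot        RMSE = sqrt(SS_res / n)

where SS_tot is the sum of squares of the observations about their mean.
Metrics computed on calibration data are labelled RMSE, on held-out data
RMSEP.

The window scan reproduces the memory-effect analysis: each physiological
sample is paired with the daily minimum / mean / maximum temperature
averaged over the trailing w days (w = 0 is the sampling day itself), and
Pearson's rho is computed per (statistic, w); frost hardiness in walnut is
most correlated with the 22-day mean of daily maxima.

The response-curve decomposition describes the normalized GFS change of
detached branches held at constant temperatures as a superposition of
three Gaussian components: two positive (cold- and mild-temperature
hydrolysis) and one negative (re-synthesis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "efficiency",
    "rmse",
    "window_correlation_scan",
    "fit_three_gaussian_response",
    "GaussianComponent",
    "ThreeGaussianFit",
]


def efficiency(observed, simulated) -> float:
    """Model efficiency; 1 = perfect, 0 = no better than the observed mean."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if len(obs) != len(sim) or len(obs) < 2:
        raise ValueError("need equal-length series with at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series has zero variance: Eff undefined")
    ss_res = float(np.sum((obs - sim) ** 2))
    return (ss_tot - ss_res) / ss_tot


def rmse(observed, simulated) -> float:
    """Root mean square error, in the units of the variable."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if len(obs) != len(sim) or len(obs) == 0:
        raise ValueError("need equal-length, nonempty series")
    return float(np.sqrt(np.mean((obs - sim) ** 2)))


def trailing_mean(weather: pd.DataFrame, column: str, date, window: int) -> float:
    """Mean of a daily weather column over the w days ending at ``date``
    (w >= 1: days date-w+1 .. date inclusive; w = 0: that day's value)."""
    dates = pd.to_datetime(weather["date"])
    date = pd.Timestamp(date)
    if window == 0:
        sel = dates == date
    else:
        sel = (dates > date - pd.Timedelta(days=window)) & (dates <= date)
    vals = weather.loc[sel.to_numpy(), column].to_numpy(dtype=float)
    need = 1 if window == 0 else window
    if len(vals) < need:
        return np.nan
    return float(vals.mean())


def window_correlation_scan(
    weather: pd.DataFrame,
    obs_dates,
    obs_values,
    statistics: tuple[str, ...] = ("min", "mean", "max"),
    windows=range(0, 31),
) -> pd.DataFrame:
    """Pearson correlation of a physiological variable against trailing
    temperature means, for each statistic and window length.

    Returns a frame with columns ``statistic, window, rho, p, n`` and the
    attribute ``scan.attrs['best']`` holding the (statistic, window) pair
    maximizing \\|rho\\|.  Sample dates lacking full weather history for a
    window are dropped for that window; a constant predictor yields a
    missing rho.
    """
    colmap = {"min": "tmin", "mean": "tmean", "max": "tmax"}
    obs_dates = pd.to_datetime(pd.Series(obs_dates)).reset_index(drop=True)
    obs_values = np.asarray(obs_values, dtype=float)
    rows = []
    for stat in statistics:
        col = colmap[stat]
        for w in windows:
            x = np.array(
                [trailing_mean(weather, col, d, w) for d in obs_dates], dtype=float
            )
            ok = np.isfinite(x) & np.isfinite(obs_values)
            n = int(ok.sum())
            if n < 3 or np.ptp(x[ok]) == 0:
                rows.append((stat, w, np.nan, np.nan, n))
                continue
            r, p = stats.pearsonr(x[ok], obs_values[ok])
            rows.append((stat, w, float(r), float(p), n))
    scan = pd.DataFrame(rows, columns=["statistic", "window", "rho", "p", "n"])
    valid = scan.dropna(subset=["rho"])
    if len(valid):
        best = valid.loc[valid["rho"].abs().idxmax()]
        scan.attrs["best"] = (str(best["statistic"]), int(best["window"]))
    return scan


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float
    mu: float
    sigma: float


@dataclass(frozen=True)
class ThreeGaussianFit:
    cold_hydrolysis: GaussianComponent
    mild_hydrolysis: GaussianComponent
    resynthesis: GaussianComponent
    rmse: float

    def predict(self, temps):
        return three_gaussian_curve(
            np.asarray(temps, dtype=float),
            *_components_to_vector(self),
        )


def _gauss(theta, mu, sigma):
    return np.exp(-((theta - mu) ** 2) / (2.0 * sigma**2))


def three_gaussian_curve(theta, a1c, mu1c, s1c, a1m, mu1m, s1m, a2, mu2, s2):
    """Two positive hydrolysis components minus one re-synthesis component."""
    return (
        a1c * _gauss(theta, mu1c, s1c)
        + a1m * _gauss(theta, mu1m, s1m)
        - a2 * _gauss(theta, mu2, s2)
    )


def _components_to_vector(fit: ThreeGaussianFit):
    c, m, r = fit.cold_hydrolysis, fit.mild_hydrolysis, fit.resynthesis
    return (c.amplitude, c.mu, c.sigma, m.amplitude, m.mu, m.sigma, r.amplitude, r.mu, r.sigma)


def fit_three_gaussian_response(
    temps,
    response,
    x0=None,
    n_starts: int = 8,
    seed: int = 0,
) -> ThreeGaussianFit:
    """Least-squares decomposition of a temperature-response curve into
    three Gaussian components (amplitudes constrained nonnegative).

    ``temps`` are treatment temperatures (degC), ``response`` the
    normalized daily change (e.g. dGFS/day divided by initial starch).
    At least 7 distinct temperatures are required.  Starting points for
    the component optima default to the biologically expected values
    (~0, ~17 and ~13 degC); additional randomized restarts guard against
    local minima.
    """
    temps = np.asarray(temps, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(np.unique(temps)) < 7:
        raise ValueError("need at least 7 distinct treatment temperatures")
    if len(temps) != len(response):
        raise ValueError("temps and response must have equal length")

    if np.allclose(response, 0.0):
        return ThreeGaussianFit(
            GaussianComponent(0.0, 0.0, 5.0),
            GaussianComponent(0.0, 17.0, 5.0),
            GaussianComponent(0.0, 13.0, 5.0),
            rmse=0.0,
        )

    span = float(np.max(np.abs(response)))
    lo = np.array([0.0, -8.0, 0.5, 0.0, 10.0, 0.5, 0.0, 5.0, 0.5])
    hi = np.array([10 * span, 8.0, 30.0, 10 * span, 30.0, 30.0, 10 * span, 25.0, 30.0])
    if x0 is None:
        x0 = np.array([span, 0.0, 4.0, span, 17.0, 4.0, span, 13.0, 3.0])
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)

    def residuals(v):
        return three_gaussian_curve(temps, *v) - response

    rng = np.random.default_rng(seed)
    best = None
    starts = [x0] + [lo + rng.random(9) * (hi - lo) for _ in range(n_starts - 1)]
    for s in starts:
        try:
            sol = optimize.least_squares(residuals, s, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("three-Gaussian response fit did not converge")
    v = best.x
    fit_rmse = float(np.sqrt(np.mean(residuals(v) ** 2)))
    return ThreeGaussianFit(
        cold_hydrolysis=GaussianComponent(*map(float, v[0:3])),
        mild_hydrolysis=GaussianComponent(*map(float, v[3:6])),
        resynthesis=GaussianComponent(*map(float, v[6:9])),
        rmse=fit_rmse,
    )
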