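"""Osmo-hydric frost hardiness: FH = a * ln(GFS) / WC + b.

Frost hardiness (FH) is the highest temperature (degC, typically negative;
lower = hardier) inducing frost damage.  Freezing-point depression scales
with solute concentration per unit water, so FH is modelled as linear in
ln(GFS)/WC, the log soluble-sugar pool per unit water content.  The two
coefficients are calibrated by ordinary least squares against measured FH;
the published walnut-branch values are a = -5.32 and b = 1.71.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FHParams", "predict_fh", "calibrate_fh", "FHFit"]


@dataclass(frozen=True)
class FHParams:
    """Slope (degC per ln(mg gDM^-1) per (g g^-1)^-1) and intercept (degC)."""

    a: float = -5.32
    b: float = 1.71


@dataclass(frozen=True)
class FHFit:
    params: FHParams
    r2: float
    rmse: float
    n: int


def predict_fh(gfs, wc, p: FHParams = FHParams()):
    """Frost hardiness (degC) from GFS (mg gDM^-1) and WC (g g^-1)."""
    gfs = np.asarray(gfs, dtype=float)
    wc = np.asarray(wc, dtype=float)
    if np.any(gfs <= 0):
        raise ValueError("gfs must be strictly positive (log undefined)")
    if np.any(wc <= 0):
        raise ValueError("wc must be strictly positive")
    fh = p.a * np.log(gfs) / wc + p.b
    return fh if fh.ndim else float(fh)


def calibrate_fh(fh, gfs, wc) -> FHFit:
    """Least-squares calibration of the osmo-hydric coefficients.

    Regresses measured frost hardiness on x = ln(GFS)/WC; needs at least
    three valid pairs with nonzero variance in x.
    """
    fh = np.asarray(fh, dtype=float)
    gfs = np.asarray(gfs, dtype=float)
    wc = np.asarray(wc, dtype=float)
    if not (len(fh) == len(gfs) == len(wc)):
        raise ValueError("fh, gfs and wc must have equal length")
    ok = np.isfinite(fh) & np.isfinite(gfs) & np.isfinite(wc)
    fh, gfs, wc = fh[ok], gfs[ok], wc[ok]
    if len(fh) < 3:
        raise ValueError("need at least 3 valid (fh, gfs, wc) pairs")
    if np.any(gfs <= 0) or np.any(wc <= 0):
        raise ValueError("gfs and wc must be strictly positive")
    x = np.log(gfs) / wc
    if np.ptp(x) == 0:
        raise ValueError("ln(GFS)/WC is constant: slope not identifiable")
    res = stats.linregress(x, fh)
    pred = res.slope * x + res.intercept
    rmse = float(np.sqrt(np.mean((fh - pred) ** 2)))
    return FHFit(
        params=FHParams(a=float(res.slope), b=float(res.intercept)),
        r2=float(res.rvalue**2),
        rmse=rmse,
        n=len(fh),
    )
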