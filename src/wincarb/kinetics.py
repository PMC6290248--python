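"""Temperature- and stage-dependent rate laws for starch-sugar metabolism.

Three catalytic activities drive the interconversion of starch and soluble
sugars (GFS) in the dormant branch: cold-active hydrolysis (``k1c``,
optimum near 0 degC), mild-temperature hydrolysis (``k1m``, optimum near
17 degC) and starch re-synthesis (``k2``, optimum near 13 degC).  Each rate
is the product of a linear function of the phenological stage PS and a
symmetric Gaussian in temperature, clamped at zero:

    k_i(theta, PS) = max[0, (a_i * PS + b_i) * exp(-(theta - mu_i)^2 / (sigma_i * 2 pi))]

The stage coefficients (a_i, b_i) take different values during endo- and
ecodormancy but are reparameterised through the rate at the transition,
``k_trans = a + b`` in both phases, so that the rate is continuous at
PS = 1.  ``sigma`` is a free fitted width parameter; the denominator is
``sigma * 2 pi`` rather than the classical ``2 sigma^2``, which leaves the
functional family unchanged and only alters the interpretation of sigma.

Respiration is a zero-order (substrate-independent) drain, logistic in
water content and Q10-exponential in temperature:

    R = R_max / (1 + exp(a3 * (WC - b3))) * Q10^((theta - T_ref)/10)

with T_ref fixed at 15 degC.  With ``a3 < 0`` respiration increases with
water content, as observed in hydrated branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReactionParams",
    "RespirationParams",
    "stage_coefficients",
    "catalytic_rate",
    "respiration_rate",
]


@dataclass(frozen=True)
class ReactionParams:
    """Parameters of one catalytic activity.

    ``k_trans`` is the rate at the endo/eco transition (PS = 1); ``d_endo``
    and ``d_eco`` are the differences a - b in each phase; ``mu`` (degC) is
    the optimal temperature; ``sigma`` the Gaussian width parameter.
    ``km`` (mg per g DM) is the Michaelis half-saturation constant, used by
    the complete model variant only.

    Units of ``k_trans``/``d_*`` depend on the model variant: mg gDM^-1
    day^-1 for the simple variant (zero-order fluxes), day^-1 for the
    intermediate variant (first-order in substrate) and mg gDM^-1 day^-1
    as a maximal velocity v_max for the complete variant.
    """

    k_trans: float
    d_endo: float
    d_eco: float
    mu: float
    sigma: float
    km: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k_trans < 0:
            raise ValueError("k_trans must be nonnegative")
        if self.km is not None and self.km <= 0:
            raise ValueError("km must be positive when present")


@dataclass(frozen=True)
class RespirationParams:
    r_max: float
    a3: float
    b3: float
    q10: float
    t_ref: float = 15.0

    def __post_init__(self) -> None:
        if self.r_max < 0:
            raise ValueError("r_max must be nonnegative")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")


def stage_coefficients(rp: ReactionParams, ps: float) -> tuple[float, float]:
    """Phase-resolved (a, b) of the linear stage factor ``a * PS + b``.

    Endodormancy (PS < 1): a = (k_trans + d_endo)/2, b = (k_trans - d_endo)/2.
    Ecodormancy (PS >= 1): same construction with d_eco.  Both phases give
    a + b = k_trans, so the rate is continuous at the transition.
    """
    if not 0.0 <= ps <= 2.0:
        raise ValueError(f"phenological stage {ps} outside [0, 2]")
    d = rp.d_endo if ps < 1.0 else rp.d_eco
    return (rp.k_trans + d) / 2.0, (rp.k_trans - d) / 2.0


def catalytic_rate(theta, ps: float, rp: ReactionParams):
    """Catalytic rate at temperature ``theta`` (degC) and stage ``ps``.

    Vectorised over ``theta``; the stage must be scalar.
    """
    a, b = stage_coefficients(rp, ps)
    theta = np.asarray(theta, dtype=float)
    gauss = np.exp(-((theta - rp.mu) ** 2) / (rp.sigma * 2.0 * np.pi))
    rate = np.maximum(0.0, (a * ps + b) * gauss)
    return rate if rate.ndim else float(rate)


def respiration_rate(theta, wc, rparams: RespirationParams):
    """Respiration (mg gDM^-1 day^-1) at temperature ``theta`` and water
    content ``wc`` (g water per g DM)."""
    theta = np.asarray(theta, dtype=float)
    wc = np.asarray(wc, dtype=float)
    if np.any(wc < 0):
        raise ValueError("water content must be nonnegative")
    r = (
        rparams.r_max
        / (1.0 + np.exp(rparams.a3 * (wc - rparams.b3)))
        * rparams.q10 ** ((theta - rparams.t_ref) / 10.0)
    )
    return r if r.ndim else float(r)
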