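"""Characteristic-plot regression: -R*T*ln(K) against complex concentration.

The slope of the line is the solvation free energy change per molar of
complex (dG_solv) and the intercept is the standard-state free energy
(dG_standard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .thermo import Conditions, EquilibriumPoint, effective_deltaG

__all__ = ["SolvationFit", "fit_solvation_line", "per_base_pair"]


@dataclass(frozen=True)
class SolvationFit:
    """Slope/intercept of the characteristic plot with regression errors."""

    dG_solv: float
    dG_standard: float
    se_slope: float
    se_intercept: float
    r_squared: float
    n_points: int
    weighted: bool = False


def fit_solvation_line(
    points: list[EquilibriumPoint],
    cond: Conditions,
    weighting: str = "none",
) -> SolvationFit:
    """Least squares of y = -R*T*ln(K) on x = complex concentration.

    ``weighting='inverse_variance'`` uses replicate dispersions: K_sd is
    propagated to the y scale by the delta method (sigma_y = R*T*K_sd/K)
    and the fit weighted by 1/sigma_y**2.  Default is ordinary least
    squares.
    """
    if weighting not in ("none", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    temps = {p.temperature_K for p in points}
    if len(temps) > 1:
        raise ValueError(f"points span multiple temperatures: {sorted(temps)}")
    (T,) = temps
    if not np.isclose(T, cond.temperature_K, atol=1e-9):
        raise ValueError(
            f"points at {T} K but conditions specify {cond.temperature_K} K"
        )

    x = np.array([p.complex_conc for p in points])
    y = np.array([effective_deltaG(p.K, cond) for p in points])
    if np.ptp(x) == 0:
        raise ValueError("all complex concentrations identical; fit is singular")

    X = sm.add_constant(x)
    if weighting == "inverse_variance":
        if any(p.K_sd is None for p in points):
            raise ValueError("inverse_variance weighting requires K_sd on every point")
        sigma_y = np.array([cond.RT * p.K_sd / p.K for p in points])
        if np.any(sigma_y <= 0):
            raise ValueError("K_sd must be positive for weighting")
        model = sm.WLS(y, X, weights=1.0 / sigma_y**2)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    return SolvationFit(
        dG_solv=float(slope),
        dG_standard=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_int),
        r_squared=float(res.rsquared),
        n_points=len(points),
        weighted=(weighting == "inverse_variance"),
    )


def per_base_pair(dG_solv: float, n_bp: int) -> float:
    """Normalize a total solvation free energy change by duplex length."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return dG_solv / n_bp
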