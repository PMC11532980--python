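"""Least-squares fitting of titration heats.

``fit_one_site_classical`` emulates instrument software: the constant-K
1:1 binding model with parameters (K, dH, n), where n scales the effective
cell concentration.  ``fit_governing_global`` fits the solvation-corrected
model (dG_standard, dG_solv, dH) directly to one enthalpogram; the two free
energies are weakly identifiable from a single titration, which is why the
characteristic-plot regression across concentrations exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .solver import BindingSystem, classical_Z, solve_Z
from .thermo import Conditions, GoverningParams
from .titration import InjectionSchedule, build_schedule_totals

__all__ = [
    "OneSiteFit",
    "GoverningFit",
    "UnidentifiableFitError",
    "fit_one_site_classical",
    "fit_governing_global",
]


class UnidentifiableFitError(RuntimeError):
    """Heats carry no binding signal (e.g. all zero)."""


@dataclass
class OneSiteFit:
    K_app: float
    dH_app: float
    n_stoich: float
    rss: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    residuals: np.ndarray | None = field(default=None, repr=False)


@dataclass
class GoverningFit:
    params: GoverningParams
    dH: float
    rss: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    residuals: np.ndarray | None = field(default=None, repr=False)


def _prepare_heats(
    heats: np.ndarray,
    schedule: InjectionSchedule,
    exclude_first: bool,
    background: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align heats to per-injection totals, optionally dropping injection 1."""
    heats = np.asarray(heats, dtype=float)
    if len(heats) != schedule.n_injections:
        raise ValueError(
            f"{len(heats)} heats but schedule has {schedule.n_injections} injections"
        )
    heats = heats - background
    Xt, Mt = build_schedule_totals(schedule)
    keep = np.ones(len(heats), dtype=bool)
    if exclude_first:
        keep[0] = False
    # residuals are minimized on the kcal-per-mole-of-injectant scale so
    # the optimizer's gradient tolerances see O(1..100) numbers instead of
    # the ~1e-5 kcal raw heats
    moles = schedule.injection_volumes() * schedule.syringe_conc
    return heats, Xt, Mt, keep, moles


def _classical_q(
    Xt: np.ndarray, Mt: np.ndarray, K: float, dH: float, n: float, cell_volume: float
) -> np.ndarray:
    Z = np.array(
        [classical_Z(BindingSystem(x, n * m), K) for x, m in zip(Xt, Mt)]
    )
    return dH * np.diff(Z, prepend=0.0) * cell_volume


def _param_se(res, n_obs: int) -> dict:
    """Asymptotic standard errors from the least-squares Jacobian."""
    n_par = len(res.x)
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return {"diag": np.sqrt(np.clip(np.diag(cov), 0, None))}
    except np.linalg.LinAlgError:
        return {"diag": np.full(n_par, np.nan)}


def fit_one_site_classical(
    heats,
    schedule: InjectionSchedule,
    cond: Conditions,
    init: dict | None = None,
    exclude_first: bool = False,
    background: float = 0.0,
) -> OneSiteFit:
    """Fit (K, dH, n) of the classical constant-K 1:1 model to heats (kcal).

    Mirrors instrument-software behavior: n rescales the effective cell
    concentration, and the model heat of injection i is
    ``dH * (Z_i - Z_{i-1}) * V_cell`` with Z from the closed-form quadratic.
    """
    heats, Xt, Mt, keep, moles = _prepare_heats(heats, schedule, exclude_first, background)
    if keep.sum() < 5:
        raise ValueError("need at least 5 usable injections")
    if np.allclose(heats[keep], 0.0):
        raise UnidentifiableFitError("all heats are zero; K is unidentifiable")

    V = schedule.cell_volume
    init = init or {}
    n0 = float(init.get("n", 1.0))
    dH0 = float(init.get("dH", heats[keep][0] / moles[keep][0]))
    lnK0 = math.log(init["K"]) if "K" in init else None

    def resid(x):
        lnK, dH, n = x
        q = _classical_q(Xt, Mt, math.exp(lnK), dH, n, V)
        return ((q - heats) / moles)[keep]

    # coarse grid on ln K (dH profiled linearly) picks the start when the
    # caller gives none; mimics the steepest-slope initialization idea
    if lnK0 is None:
        best = None
        for lnK_try in np.log(10.0 ** np.arange(2.0, 10.1, 0.5)):
            u = (_classical_q(Xt, Mt, math.exp(lnK_try), 1.0, n0, V) / moles)[keep]
            denom = float(u @ u)
            if denom == 0.0:
                continue
            y = (heats / moles)[keep]
            dH_prof = float(u @ y) / denom
            rss = float(np.sum((dH_prof * u - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, lnK_try, dH_prof)
        if best is None:
            raise UnidentifiableFitError("model heats vanish for all trial K")
        _, lnK0, dH0 = best

    res = least_squares(
        resid,
        x0=[lnK0, dH0, n0],
        bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, 10.0]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    se = _param_se(res, int(keep.sum()))
    lnK, dH, n = res.x
    q_fit = _classical_q(Xt, Mt, math.exp(lnK), dH, n, V)
    return OneSiteFit(
        K_app=math.exp(lnK),
        dH_app=float(dH),
        n_stoich=float(n),
        rss=float(np.sum((q_fit - heats)[keep] ** 2)),
        se={"lnK": se["diag"][0], "dH": se["diag"][1], "n": se["diag"][2]},
        converged=bool(res.success),
        residuals=res.fun,
    )


def fit_governing_global(
    heats,
    schedule: InjectionSchedule,
    cond: Conditions,
    init: dict | None = None,
    fix_dG_solv: float | None = None,
    exclude_first: bool = False,
    background: float = 0.0,
) -> GoverningFit:
    """Fit (dG_standard, dG_solv, dH) of the solvation-corrected model.

    ``fix_dG_solv`` pins the slope parameter (at 0.0 this reduces to the
    classical one-site model with n = 1).  A single titration constrains
    the two free energies only weakly; a warning says so when both float.
    """
    heats, Xt, Mt, keep, moles = _prepare_heats(heats, schedule, exclude_first, background)
    if keep.sum() < 5:
        raise ValueError("need at least 5 usable injections")
    if np.allclose(heats[keep], 0.0):
        raise UnidentifiableFitError("all heats are zero; parameters unidentifiable")

    if fix_dG_solv is None:
        warnings.warn(
            "dG_standard and dG_solv are weakly identifiable from a single "
            "titration; prefer the multi-concentration characteristic-plot "
            "regression",
            UserWarning,
            stacklevel=2,
        )

    V = schedule.cell_volume
    init = init or {}
    dG0_0 = float(init.get("dG_standard", -8.0))
    dGS_0 = float(init.get("dG_solv", 0.0)) if fix_dG_solv is None else fix_dG_solv
    dH0 = float(init.get("dH", heats[keep][0] / moles[keep][0]))

    def model_q(dG0, dGS, dH):
        params = GoverningParams(dG0, dGS)
        Z = np.array(
            [solve_Z(BindingSystem(x, m), params, cond) for x, m in zip(Xt, Mt)]
        )
        return dH * np.diff(Z, prepend=0.0) * V

    if fix_dG_solv is None:
        def resid(x):
            return ((model_q(x[0], x[1], x[2]) - heats) / moles)[keep]
        x0 = [dG0_0, dGS_0, dH0]
    else:
        def resid(x):
            return ((model_q(x[0], fix_dG_solv, x[1]) - heats) / moles)[keep]
        x0 = [dG0_0, dH0]

    res = least_squares(resid, x0=x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    se = _param_se(res, int(keep.sum()))
    if fix_dG_solv is None:
        params = GoverningParams(float(res.x[0]), float(res.x[1]))
        dH = float(res.x[2])
        se_map = {"dG_standard": se["diag"][0], "dG_solv": se["diag"][1], "dH": se["diag"][2]}
    else:
        params = GoverningParams(float(res.x[0]), fix_dG_solv)
        dH = float(res.x[1])
        se_map = {"dG_standard": se["diag"][0], "dH": se["diag"][1]}
    q_fit = model_q(params.dG_standard, params.dG_solv, dH)
    return GoverningFit(
        params=params,
        dH=dH,
        rss=float(np.sum((q_fit - heats)[keep] ** 2)),
        se=se_map,
        converged=bool(res.success),
        residuals=res.fun,
    )
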