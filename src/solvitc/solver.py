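"""Root solving for the equilibrium complex concentration Z.

Replaces the symbolic-algebra step of the original workflow with
derivative-free bracketing on the open interval (0, min(Xt, Mt)), where the
governing residual spans +inf to -inf and therefore guarantees a sign
change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .thermo import Conditions, GoverningParams, governing_residual

__all__ = [
    "BindingSystem",
    "SolverSettings",
    "MultipleRootsWarning",
    "InfeasibleParamsError",
    "solve_Z",
    "classical_Z",
    "K_at_equilibrium",
]


class MultipleRootsWarning(UserWarning):
    """Raised when more than one sign change is bracketed (dG_solv < 0)."""


class InfeasibleParamsError(RuntimeError):
    """No sign change found after edge-guarded bracketing."""


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations for a 1:1 titration point (molar).

    ``Xt`` is the total injected species, ``Mt`` the total cell species;
    the free species are ``Xt - Z`` and ``Mt - Z`` by mass balance.
    """

    Xt: float
    Mt: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Xt) and self.Xt >= 0):
            raise ValueError(f"Xt must be >= 0, got {self.Xt}")
        if not (math.isfinite(self.Mt) and self.Mt > 0):
            raise ValueError(f"Mt must be > 0, got {self.Mt}")


@dataclass(frozen=True)
class SolverSettings:
    abs_tol: float = 1e-15
    max_iter: int = 200
    edge_guard: float = 1e-12
    #: grid resolution used to hunt for multiple sign changes when dG_solv < 0
    scan_points: int = 4096

    def __post_init__(self) -> None:
        if self.abs_tol <= 0:
            raise ValueError("abs_tol must be positive")
        if not (0 < self.edge_guard < 0.5):
            raise ValueError("edge_guard must be in (0, 0.5)")


DEFAULT_SETTINGS = SolverSettings()


def _residual(Z: float, system: BindingSystem, params: GoverningParams, cond: Conditions) -> float:
    return governing_residual(Z, system.Xt, system.Mt, params, cond)


def _newton_polish(
    z: float,
    lo: float,
    hi: float,
    system: BindingSystem,
    params: GoverningParams,
    cond: Conditions,
    n_steps: int = 3,
) -> float:
    """Sharpen a bracketed root to near machine precision.

    K = Z/((Xt-Z)(Mt-Z)) amplifies absolute error in Z near saturation, so
    the bisection tolerance alone is not enough for downstream invariants;
    a few damped Newton steps on the analytic derivative fix that.
    """
    for _ in range(n_steps):
        g = _residual(z, system, params, cond)
        dg = (
            -cond.RT * (1.0 / z + 1.0 / (system.Xt - z) + 1.0 / (system.Mt - z))
            - params.dG_solv
        )
        if dg == 0.0:
            break
        step = g / dg
        z_new = z - step
        if not (lo < z_new < hi):
            break
        z = z_new
        if abs(step) <= abs(z) * 1e-16:
            break
    return z


def solve_Z(
    system: BindingSystem,
    params: GoverningParams,
    cond: Conditions,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> float:
    """Solve the governing equation for the equilibrium complex concentration.

    Returns Z in (0, min(Xt, Mt)).  For ``dG_solv >= 0`` the residual is
    strictly decreasing and the root unique; for ``dG_solv < 0`` all
    bracketed sign changes are located on a scan grid, the smallest root is
    returned, and a :class:`MultipleRootsWarning` lists the rest.

    ``Xt = 0`` short-circuits to ``Z = 0`` (no titrant, no complex).
    """
    if system.Xt == 0.0:
        return 0.0
    m = min(system.Xt, system.Mt)
    lo = settings.edge_guard * m
    hi = (1.0 - settings.edge_guard) * m

    f = lambda Z: _residual(Z, system, params, cond)

    if params.dG_solv >= 0:
        brackets = [(lo, hi)]
    else:
        # negative dG_solv can make the residual non-monotone: scan for all
        # sign changes
        grid = np.linspace(lo, hi, settings.scan_points)
        vals = np.array([f(z) for z in grid])
        sign_flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        brackets = [(grid[i], grid[i + 1]) for i in sign_flips]
        if not brackets:
            brackets = [(lo, hi)]

    roots: list[float] = []
    for a, b in brackets:
        fa, fb = f(a), f(b)
        if fa == 0.0:
            roots.append(a)
            continue
        if fb == 0.0:
            roots.append(b)
            continue
        if fa * fb > 0:
            continue
        z = brentq(f, a, b, xtol=settings.abs_tol, maxiter=settings.max_iter)
        roots.append(_newton_polish(z, a, b, system, params, cond))

    if not roots:
        raise InfeasibleParamsError(
            f"no sign change of the governing residual on ({lo:g}, {hi:g}) "
            f"for Xt={system.Xt:g}, Mt={system.Mt:g}, params={params}"
        )
    roots.sort()
    if len(roots) > 1:
        warnings.warn(
            f"governing equation has {len(roots)} roots {roots}; "
            "returning the smallest",
            MultipleRootsWarning,
            stacklevel=2,
        )
    return roots[0]


def classical_Z(system: BindingSystem, K: float, cond: Conditions | None = None) -> float:
    """Closed-form 1:1 complex concentration at constant K.

    The smaller root of ``Z^2 - (Xt + Mt + 1/K) Z + Xt*Mt = 0``, evaluated
    in the numerically stable product form.  This is the ``dG_solv = 0``
    limit of the governing equation and serves as its oracle.
    """
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"K must be positive and finite, got {K}")
    if system.Xt == 0.0:
        return 0.0
    b = system.Xt + system.Mt + 1.0 / K
    disc = b * b - 4.0 * system.Xt * system.Mt
    if disc < 0:  # impossible for valid inputs; guard against rounding
        disc = 0.0
    # smaller quadratic root via 2c/(b + sqrt(disc)) to avoid cancellation
    return 2.0 * system.Xt * system.Mt / (b + math.sqrt(disc))


def K_at_equilibrium(system: BindingSystem, Z: float) -> float:
    """Equilibrium quotient K = Z / ((Xt - Z)(Mt - Z)) at the root Z."""
    m = min(system.Xt, system.Mt)
    if not (0.0 < Z < m):
        raise ValueError(f"Z must lie strictly inside (0, {m}), got {Z}")
    return Z / ((system.Xt - Z) * (system.Mt - Z))
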