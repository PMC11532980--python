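"""Core thermodynamic types and the algebraic forms of the governing equation.

The governing relationship extends the classical expression
``dG_standard = -R*T*ln(K)`` with a term linear in the equilibrium complex
concentration::

    dG_standard = -R*T*ln(K) - [AB] * dG_solv

All concentrations are molar and enter logarithms as dimensionless numbers
via division by the 1 M reference, so ``dG_solv`` carries units of
kcal/mol per molar of complex and the product ``[AB]*dG_solv`` is kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT_KCAL",
    "Conditions",
    "GoverningParams",
    "EquilibriumPoint",
    "celsius_to_kelvin",
    "mM_to_M",
    "K_from_deltaG",
    "effective_deltaG",
    "governing_residual",
]

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT_KCAL = 1.9872e-3


def celsius_to_kelvin(temp_C: float) -> float:
    """Convert a Celsius temperature to Kelvin."""
    return temp_C + 273.15


def mM_to_M(conc_mM: float) -> float:
    """Convert millimolar to molar."""
    return conc_mM * 1e-3


@dataclass(frozen=True)
class Conditions:
    """Temperature and gas constant for an equilibrium calculation."""

    temperature_K: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature_K) and self.temperature_K > 0):
            raise ValueError(f"temperature_K must be positive, got {self.temperature_K}")
        if not (math.isfinite(self.gas_constant) and self.gas_constant > 0):
            raise ValueError(f"gas_constant must be positive, got {self.gas_constant}")

    @classmethod
    def from_celsius(cls, temp_C: float, gas_constant: float = GAS_CONSTANT_KCAL) -> "Conditions":
        return cls(temperature_K=celsius_to_kelvin(temp_C), gas_constant=gas_constant)

    @property
    def RT(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature_K


@dataclass(frozen=True)
class GoverningParams:
    """The (dG_standard, dG_solv) pair that parameterizes an equilibrium.

    ``dG_standard`` is the standard-state free energy (kcal/mol, the
    intercept of the characteristic plot); ``dG_solv`` is the solvation
    free energy change per molar of complex (kcal/mol/M, the slope).
    ``dG_solv`` may be positive, zero, or negative.
    """

    dG_standard: float
    dG_solv: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG_standard):
            raise ValueError(f"dG_standard must be finite, got {self.dG_standard}")
        if not math.isfinite(self.dG_solv):
            raise ValueError(f"dG_solv must be finite, got {self.dG_solv}")


@dataclass(frozen=True)
class EquilibriumPoint:
    """One (K, [AB], T) observation — the unit of the characteristic plot.

    ``K`` is the molar-based equilibrium quotient (dimensionless via the
    1 M reference), ``complex_conc`` the matched equilibrium complex
    concentration in molar, and ``K_sd`` an optional replicate dispersion.
    """

    K: float
    complex_conc: float
    temperature_K: float = 298.15
    K_sd: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.K) and self.K > 0):
            raise ValueError(f"K must be positive and finite, got {self.K}")
        if not (math.isfinite(self.complex_conc) and self.complex_conc >= 0):
            raise ValueError(f"complex_conc must be non-negative, got {self.complex_conc}")
        if self.K_sd is not None and not (math.isfinite(self.K_sd) and self.K_sd >= 0):
            raise ValueError(f"K_sd must be non-negative when present, got {self.K_sd}")
        if not (math.isfinite(self.temperature_K) and self.temperature_K > 0):
            raise ValueError(f"temperature_K must be positive, got {self.temperature_K}")


def K_from_deltaG(dG_standard: float, cond: Conditions) -> float:
    """Equilibrium quotient implied by the classical relation.

    Returns ``exp(-dG_standard / (R*T))``; strictly decreasing in
    ``dG_standard``.
    """
    if not math.isfinite(dG_standard):
        raise ValueError(f"dG_standard must be finite, got {dG_standard}")
    return math.exp(-dG_standard / cond.RT)


def effective_deltaG(K: float, cond: Conditions) -> float:
    """The y-axis value of the characteristic plot: ``-R*T*ln(K)``."""
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"K must be positive and finite, got {K}")
    return -cond.RT * math.log(K)


def governing_residual(
    Z: float,
    Xt: float,
    Mt: float,
    params: GoverningParams,
    cond: Conditions,
) -> float:
    """Residual of the governing equation at complex concentration Z.

    g(Z) = -R*T*ln[ Z / ((Xt-Z)(Mt-Z)) ] - Z*dG_solv - dG_standard

    The equilibrium concentration Z* is the root g(Z*) = 0.  g diverges to
    +inf as Z -> 0+ and to -inf as Z -> min(Xt, Mt)-, so a sign change is
    guaranteed on the open interval.
    """
    m = min(Xt, Mt)
    if not (0.0 < Z < m):
        raise ValueError(f"Z must lie in the open interval (0, {m}), got {Z}")
    log_Q = math.log(Z) - math.log(Xt - Z) - math.log(Mt - Z)
    return -cond.RT * log_Q - Z * params.dG_solv - params.dG_standard
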