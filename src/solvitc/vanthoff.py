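"""Base-unstacking correction of measured free energies and van't Hoff fits.

Single-stranded oligonucleotides retain intramolecular base stacking whose
temperature-dependent free energy (dG_un = dH_un - T*dS_un, per strand) must
be removed, scaled by the stacked fraction f, before measured hybridization
free energies at different temperatures share a common (fully unstacked)
starting state:

    dG_corrected = dG_itc - f * (dG_un strand A + dG_un strand B)

The corrected values then support a van't Hoff analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .thermo import Conditions

__all__ = [
    "UnstackingParams",
    "UnstackingRow",
    "VantHoffFit",
    "unstacking_G",
    "correct_deltaG",
    "build_unstacking_row",
    "vant_hoff_fit",
]


@dataclass(frozen=True)
class UnstackingParams:
    """Per-strand unstacking enthalpy (kcal/mol) and entropy (kcal/mol/K)."""

    dH_un: float
    dS_un: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dH_un) and math.isfinite(self.dS_un)):
            raise ValueError("unstacking parameters must be finite")


@dataclass(frozen=True)
class UnstackingRow:
    """One temperature row of the stacking-correction table."""

    temperature_K: float
    dG_un_strand_a: float
    dG_un_strand_b: float
    f_stacked: float
    dG_itc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_stacked <= 1.0):
            raise ValueError(f"f_stacked must be in [0, 1], got {self.f_stacked}")

    @property
    def dG_un_sum(self) -> float:
        return self.dG_un_strand_a + self.dG_un_strand_b

    @property
    def dG_corrected(self) -> float:
        return correct_deltaG(self.dG_itc, self.f_stacked, self.dG_un_sum)


@dataclass(frozen=True)
class VantHoffFit:
    dH_vh: float
    dS_vh: float
    se_dH: float
    se_dS: float
    r_squared: float
    mode: str


def unstacking_G(params: UnstackingParams, T: float) -> float:
    """Unstacking free energy dH_un - T*dS_un at temperature T (Kelvin)."""
    if T <= 0:
        raise ValueError("T must be positive")
    return params.dH_un - T * params.dS_un


def correct_deltaG(dG_itc: float, f_stacked: float, dG_un_sum: float) -> float:
    """Remove the stacked-fraction-weighted unstacking free energy."""
    if not (0.0 <= f_stacked <= 1.0):
        raise ValueError(f"f_stacked must be in [0, 1], got {f_stacked}")
    return dG_itc - f_stacked * dG_un_sum


def build_unstacking_row(
    strand_a: UnstackingParams,
    strand_b: UnstackingParams,
    temperature_K: float,
    f_stacked: float,
    dG_itc: float,
) -> UnstackingRow:
    """Assemble a correction row from per-strand parameters."""
    return UnstackingRow(
        temperature_K=temperature_K,
        dG_un_strand_a=unstacking_G(strand_a, temperature_K),
        dG_un_strand_b=unstacking_G(strand_b, temperature_K),
        f_stacked=f_stacked,
        dG_itc=dG_itc,
    )


def vant_hoff_fit(
    rows: list[tuple[float, float]],
    cond: Conditions,
    mode: str = "lnK_vs_invT",
) -> VantHoffFit:
    """Extract enthalpy and entropy from (temperature_K, dG) pairs.

    ``lnK_vs_invT`` (default, the canonical van't Hoff plot): each dG is
    converted to ln K = -dG/(R*T) and regressed on 1/T; then
    dH = -R*slope and dS = R*intercept.

    ``dG_vs_T``: dG is regressed on T directly via dG = dH - T*dS.
    """
    if mode not in ("lnK_vs_invT", "dG_vs_T"):
        raise ValueError(f"unknown mode {mode!r}")
    T = np.array([r[0] for r in rows], dtype=float)
    dG = np.array([r[1] for r in rows], dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    R = cond.gas_constant

    if mode == "lnK_vs_invT":
        x = 1.0 / T
        y = -dG / (R * T)
    else:
        x = T
        y = dG

    if len(T) > 2:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        se_slope, se_intercept = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    else:
        slope, intercept = np.polyfit(x, y, 1)
        se_slope = se_intercept = float("nan")
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if mode == "lnK_vs_invT":
        return VantHoffFit(
            dH_vh=-R * slope,
            dS_vh=R * intercept,
            se_dH=R * se_slope,
            se_dS=R * se_intercept,
            r_squared=r2,
            mode=mode,
        )
    return VantHoffFit(
        dH_vh=float(intercept),
        dS_vh=float(-slope),
        se_dH=se_intercept,
        se_dS=se_slope,
        r_squared=r2,
        mode=mode,
    )
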