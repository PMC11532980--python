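"""Two-state folding under the solvation-corrected governing equation.

For a unimolecular U <-> F equilibrium the governing relationship becomes

    dG_standard = -R*T*ln(f_F / (1 - f_F)) - f_F * P_total * dG_solv

so the fraction folded f_F depends on total protein concentration whenever
dG_solv != 0.  Near-UV CD spectra taken at constant concentration *
pathlength provide the readout: a two-state system predicts each spectrum
is a linear mix of folded and unfolded basis spectra weighted by f_F.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .solver import MultipleRootsWarning
from .thermo import Conditions, GoverningParams

__all__ = [
    "FoldingSystem",
    "CdSpectrum",
    "solve_folding_fraction",
    "predict_cd",
    "concentration_independence_stat",
    "mg_per_ml_to_molar",
]

#: default molar mass used for mg/mL -> molar conversion (bovine
#: alpha-lactalbumin, 123 residues); a package default, not a measured input
DEFAULT_MOLAR_MASS = 14178.0


def mg_per_ml_to_molar(conc_mg_ml: float, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert a mg/mL protein concentration to molar."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    return conc_mg_ml / molar_mass


@dataclass(frozen=True)
class FoldingSystem:
    """Total protein concentration (molar) and governing parameters.

    The folding direction is U -> F, so positive dG_solv penalizes folding
    at higher protein concentration.
    """

    P_total: float
    params: GoverningParams
    molar_mass: float = DEFAULT_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.P_total <= 0:
            raise ValueError("P_total must be positive")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")

    @classmethod
    def from_mg_per_ml(
        cls,
        conc_mg_ml: float,
        params: GoverningParams,
        molar_mass: float = DEFAULT_MOLAR_MASS,
    ) -> "FoldingSystem":
        return cls(mg_per_ml_to_molar(conc_mg_ml, molar_mass), params, molar_mass)


@dataclass(frozen=True)
class CdSpectrum:
    """A near-UV CD wavelength scan with its concentration and pathlength."""

    wavelength_nm: np.ndarray
    ellipticity: np.ndarray
    conc_mg_ml: float
    pathlength_cm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength_nm", np.asarray(self.wavelength_nm, float))
        object.__setattr__(self, "ellipticity", np.asarray(self.ellipticity, float))
        if self.wavelength_nm.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity grids differ in shape")
        if self.conc_mg_ml <= 0 or self.pathlength_cm <= 0:
            raise ValueError("conc and pathlength must be positive")

    @property
    def conc_pathlength(self) -> float:
        """Beer's-law product c*l; constant across a comparison series."""
        return self.conc_mg_ml * self.pathlength_cm


def _folding_residual(f: float, system: FoldingSystem, cond: Conditions) -> float:
    p = system.params
    return (
        -cond.RT * math.log(f / (1.0 - f))
        - f * system.P_total * p.dG_solv
        - p.dG_standard
    )


def solve_folding_fraction(
    system: FoldingSystem,
    cond: Conditions,
    edge_guard: float = 1e-14,
    scan_points: int = 4096,
) -> float:
    """Fraction folded f_F in (0, 1) solving the two-state governing equation.

    The residual runs from +inf at f -> 0 to -inf at f -> 1, so a root
    always exists; it is unique for dG_solv >= 0.  For dG_solv < 0 the
    smallest root is returned with a :class:`MultipleRootsWarning` when
    several sign changes are found.
    """
    f = lambda x: _folding_residual(x, system, cond)
    lo, hi = edge_guard, 1.0 - edge_guard
    if system.params.dG_solv >= 0:
        return brentq(f, lo, hi, xtol=1e-15)
    grid = np.linspace(lo, hi, scan_points)
    vals = np.array([f(x) for x in grid])
    flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(flips) == 0:
        return brentq(f, lo, hi, xtol=1e-15)
    roots = sorted(
        brentq(f, grid[i], grid[i + 1], xtol=1e-15) for i in flips
    )
    if len(roots) > 1:
        warnings.warn(
            f"folding equation has {len(roots)} roots; returning the smallest",
            MultipleRootsWarning,
            stacklevel=2,
        )
    return roots[0]


def predict_cd(
    f_F: float, basis_folded: CdSpectrum, basis_unfolded: CdSpectrum
) -> CdSpectrum:
    """Two-state spectral mix: f_F*folded + (1 - f_F)*unfolded, pointwise."""
    if not np.array_equal(basis_folded.wavelength_nm, basis_unfolded.wavelength_nm):
        raise ValueError("basis spectra are on different wavelength grids")
    mixed = f_F * basis_folded.ellipticity + (1.0 - f_F) * basis_unfolded.ellipticity
    return CdSpectrum(
        wavelength_nm=basis_folded.wavelength_nm.copy(),
        ellipticity=mixed,
        conc_mg_ml=basis_folded.conc_mg_ml,
        pathlength_cm=basis_folded.pathlength_cm,
    )


def concentration_independence_stat(
    spectra: list[CdSpectrum],
    native: CdSpectrum | None = None,
    unfolded: CdSpectrum | None = None,
    rtol_cl: float = 1e-6,
) -> float:
    """Spread of a concentration series, normalized to the two-state span.

    Returns ``max over wavelengths of (range across spectra)`` divided by
    the maximum |native - unfolded| signal difference (when bases are
    given; otherwise by the maximum absolute signal in the series).  Values
    near zero support a concentration-independent equilibrium, i.e.
    dG_solv ~ 0.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    grid = spectra[0].wavelength_nm
    cl = spectra[0].conc_pathlength
    for s in spectra[1:]:
        if not np.array_equal(s.wavelength_nm, grid):
            raise ValueError("spectra are on different wavelength grids")
        if not math.isclose(s.conc_pathlength, cl, rel_tol=rtol_cl):
            raise ValueError(
                f"conc*pathlength differs across series: {s.conc_pathlength} vs {cl}"
            )
    stack = np.vstack([s.ellipticity for s in spectra])
    spread = float(np.max(stack.max(axis=0) - stack.min(axis=0)))
    if native is not None and unfolded is not None:
        span = float(np.max(np.abs(native.ellipticity - unfolded.ellipticity)))
    else:
        span = float(np.max(np.abs(stack)))
    if span == 0.0:
        return 0.0
    return spread / span
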