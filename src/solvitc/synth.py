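"""Seeded synthetic-data generators for every pipeline stage.

Noise models match the error structure of each measurement: additive
Gaussian on injection heats, multiplicative lognormal on equilibrium
quotients, additive Gaussian on CD ellipticities.  A fixed seed gives
identical output on rerun.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .folding import CdSpectrum, FoldingSystem, solve_folding_fraction
from .thermo import Conditions, EquilibriumPoint, GoverningParams
from .titration import InjectionSchedule, TitrationTrace, simulate_titration

__all__ = [
    "SynthConfig",
    "gen_itc_experiment",
    "gen_K_series",
    "gen_cd_series",
    "make_cd_bases",
]


@dataclass(frozen=True)
class SynthConfig:
    """Truth parameters, noise levels, and seed for the generators."""

    seed: int = 0
    params: GoverningParams = field(default_factory=lambda: GoverningParams(-9.30, 4600.0))
    dH_true: float = -47.0
    heat_noise_sd: float = 0.0  # kcal, additive per injection
    K_lognormal_sd: float = 0.0  # sd of ln K, multiplicative
    cd_noise_sd: float = 0.0  # signal units, additive per wavelength
    schedule: InjectionSchedule = field(default_factory=InjectionSchedule)
    conditions: Conditions = field(default_factory=Conditions)

    def __post_init__(self) -> None:
        for name in ("heat_noise_sd", "K_lognormal_sd", "cd_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_itc_experiment(config: SynthConfig) -> tuple[pd.DataFrame, TitrationTrace]:
    """Simulate a titration and emit a noisy heats table.

    Returns the table in the schema the fitting reader consumes
    (columns: injection, volume_uL, heat_kcal) together with the
    noise-free trace.
    """
    trace = simulate_titration(
        config.schedule, config.params, config.dH_true, config.conditions
    )
    rng = config.rng()
    heats = trace.q + rng.normal(0.0, config.heat_noise_sd, size=trace.n_injections) \
        if config.heat_noise_sd > 0 else trace.q.copy()
    table = pd.DataFrame(
        {
            "injection": np.arange(1, trace.n_injections + 1),
            "volume_uL": config.schedule.injection_volumes() * 1e6,
            "heat_kcal": heats,
        }
    )
    return table, trace


def gen_K_series(config: SynthConfig, conc_grid) -> list[EquilibriumPoint]:
    """Equilibrium quotients on a complex-concentration grid.

    Each K is the value the governing relationship implies at that complex
    concentration, K = exp[(-dG_standard - c*dG_solv)/(R*T)], with
    multiplicative lognormal noise of sd ``K_lognormal_sd`` on the log
    scale.
    """
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.ndim != 1 or len(conc_grid) == 0 or np.any(conc_grid < 0):
        raise ValueError("conc_grid must be a non-empty 1-D array of non-negative molar values")
    cond = config.conditions
    rng = config.rng()
    lnK = (-config.params.dG_standard - conc_grid * config.params.dG_solv) / cond.RT
    if config.K_lognormal_sd > 0:
        lnK = lnK + rng.normal(0.0, config.K_lognormal_sd, size=len(conc_grid))
    return [
        EquilibriumPoint(K=float(np.exp(l)), complex_conc=float(c),
                         temperature_K=cond.temperature_K)
        for l, c in zip(lnK, conc_grid)
    ]


def make_cd_bases(
    wavelength_nm=None,
    conc_mg_ml: float = 1.0,
    pathlength_cm: float = 1.0,
) -> tuple[CdSpectrum, CdSpectrum]:
    """Smooth synthetic folded/unfolded near-UV basis spectra.

    The folded basis has a pronounced negative band near 270 nm (tertiary
    structure signal); the unfolded basis is nearly flat.
    """
    if wavelength_nm is None:
        wavelength_nm = np.arange(250.0, 321.0, 1.0)
    wl = np.asarray(wavelength_nm, dtype=float)
    folded = -80.0 * np.exp(-((wl - 270.0) ** 2) / (2 * 12.0**2)) \
        - 25.0 * np.exp(-((wl - 292.0) ** 2) / (2 * 6.0**2))
    unfolded = -6.0 * np.exp(-((wl - 270.0) ** 2) / (2 * 20.0**2))
    mk = lambda e: CdSpectrum(wl, e, conc_mg_ml, pathlength_cm)
    return mk(folded), mk(unfolded)


def gen_cd_series(config: SynthConfig, conc_list) -> list[CdSpectrum]:
    """CD spectra across a mg/mL dilution series at constant conc*pathlength.

    For each concentration the fraction folded comes from the two-state
    governing equation under the config's parameters; the spectrum is the
    basis mix plus additive Gaussian noise.  Pathlengths are scaled so
    c*l is identical for every member of the series.
    """
    conc_list = np.asarray(conc_list, dtype=float)
    if np.any(conc_list <= 0):
        raise ValueError("concentrations must be positive")
    folded, unfolded = make_cd_bases()
    rng = config.rng()
    cl = 1.0  # cm * mg/mL, held constant across the series
    out: list[CdSpectrum] = []
    for c in conc_list:
        system = FoldingSystem.from_mg_per_ml(float(c), config.params)
        f_F = solve_folding_fraction(system, config.conditions)
        signal = f_F * folded.ellipticity + (1.0 - f_F) * unfolded.ellipticity
        if config.cd_noise_sd > 0:
            signal = signal + rng.normal(0.0, config.cd_noise_sd, size=len(signal))
        out.append(
            CdSpectrum(
                wavelength_nm=folded.wavelength_nm.copy(),
                ellipticity=signal,
                conc_mg_ml=float(c),
                pathlength_cm=cl / float(c),
            )
        )
    return out
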