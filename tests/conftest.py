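import numpy as np
import pytest

from solvitc import Conditions, GoverningParams, InjectionSchedule

R = 1.9872e-3


@pytest.fixture
def cond25():
    return Conditions(temperature_K=298.15)


@pytest.fixture
def modeled_schedule():
    """28 x 10 uL into 1.45 mL, syringe 10x the 0.20 mM cell concentration."""
    return InjectionSchedule(
        n_injections=28,
        injection_volume=10e-6,
        cell_volume=1.45e-3,
        syringe_conc=2.0e-3,
        cell_conc_initial=2.0e-4,
        dilution_mode="paper",
    )


@pytest.fixture
def modeled_params():
    return GoverningParams(dG_standard=-9.30, dG_solv=4000.0)


# Published unstacking-correction table used across the van't Hoff tests:
# temperature_C, dG_un strand a, dG_un strand b, sum, f_stacked, dG_itc,
# dG_corrected (all free energies kcal/mol).
CORRECTION_TABLE = [
    (10.0, 1.62, 1.65, 3.27, 1.0, -9.60, -12.87),
    (18.0, 1.45, 1.50, 2.95, 1.0, -9.76, -12.71),
    (25.0, 1.30, 1.37, 2.67, 0.97, -9.35, -11.94),
    (31.0, 1.18, 1.26, 2.44, 0.92, -8.82, -11.06),
]


@pytest.fixture
def correction_table():
    return CORRECTION_TABLE


def brute_force_root(Xt, Mt, dG0, dGS, T=298.15, n_grid=1_000_000):
    """Independent grid-scan oracle for the governing equation root.

    Evaluates g(Z) = -RT*ln(Z/((Xt-Z)(Mt-Z))) - Z*dGS - dG0 on a dense
    uniform grid of the open interval, locates the first sign change, and
    refines it by plain bisection on the same expression.  Shares no code
    with the package solver.
    """
    m = min(Xt, Mt)
    eps = m * 1e-9
    Z = np.linspace(eps, m - eps, n_grid)
    g = -R * T * (np.log(Z) - np.log(Xt - Z) - np.log(Mt - Z)) - Z * dGS - dG0
    flips = np.nonzero(np.sign(g[:-1]) != np.sign(g[1:]))[0]
    assert len(flips) >= 1, "oracle found no sign change"
    lo, hi = Z[flips[0]], Z[flips[0] + 1]

    def gz(z):
        return -R * T * (np.log(z) - np.log(Xt - z) - np.log(Mt - z)) - z * dGS - dG0

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gz(lo) * gz(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), len(flips)
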