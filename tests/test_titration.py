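import numpy as np
import pytest

from solvitc import (
    BindingSystem,
    Conditions,
    GoverningParams,
    InjectionSchedule,
    K_from_deltaG,
    brandts_complex_conc,
    build_schedule_totals,
    classical_Z,
    match_K_to_concentration,
    simulate_titration,
)


class TestBuildScheduleTotals:
    def test_paper_mode_constant_increment(self, modeled_schedule):
        Xt, Mt = build_schedule_totals(modeled_schedule)
        # hand calculation: i * (10 uL * 10*Mt) / (1.45 mL * Mt) per injection
        inc = 10e-6 * 2.0e-3 / 1.45e-3
        assert Xt == pytest.approx(inc * np.arange(1, 29))
        assert np.all(Mt == 2.0e-4)
        ratio = Xt / Mt
        assert ratio[0] == pytest.approx(0.06897, abs=1e-5)
        assert ratio[13] == pytest.approx(0.9655, abs=1e-4)  # i = 14
        assert ratio[14] == pytest.approx(1.034, abs=1e-3)  # i = 15

    def test_first_injection_override(self):
        s = InjectionSchedule(first_injection_volume=2e-6)
        Xt, _ = build_schedule_totals(s)
        inc = 10e-6 * s.syringe_conc / s.cell_volume
        assert Xt[0] == pytest.approx(2e-6 * s.syringe_conc / s.cell_volume)
        assert Xt[1] - Xt[0] == pytest.approx(inc)

    def test_displacement_dilutes_cell_species(self, modeled_schedule):
        from dataclasses import replace

        disp = replace(modeled_schedule, dilution_mode="displacement")
        Xt, Mt = build_schedule_totals(disp)
        assert np.all(np.diff(Mt) < 0)
        assert Mt[0] == pytest.approx(2.0e-4 * (1 - 10e-6 / 1.45e-3))

    def test_displacement_converges_to_paper_for_small_volumes(self):
        # same total titrant delivered in vanishingly small injections
        base = dict(cell_volume=1.45e-3, syringe_conc=2.0e-3, cell_conc_initial=2.0e-4)
        paper = InjectionSchedule(n_injections=1, injection_volume=1e-9,
                                  dilution_mode="paper", **base)
        disp = InjectionSchedule(n_injections=1, injection_volume=1e-9,
                                 dilution_mode="displacement", **base)
        Xp, Mp = build_schedule_totals(paper)
        Xd, Md = build_schedule_totals(disp)
        assert Xd == pytest.approx(Xp, rel=1e-5)
        assert Md == pytest.approx(Mp, rel=1e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            InjectionSchedule(n_injections=0)
        with pytest.raises(ValueError):
            InjectionSchedule(dilution_mode="bogus")


class TestSimulateTitration:
    def test_zero_enthalpy_zero_heat(self, modeled_schedule, modeled_params, cond25):
        tr = simulate_titration(modeled_schedule, modeled_params, 0.0, cond25)
        assert np.all(tr.q == 0.0)
        assert np.all(tr.q_norm == 0.0)

    def test_zero_dGS_matches_classical_closed_form(self, modeled_schedule, cond25):
        dG0, dH = -8.60, -47.0
        tr = simulate_titration(modeled_schedule, GoverningParams(dG0, 0.0), dH, cond25)
        K = K_from_deltaG(dG0, cond25)
        Z_ref = np.array(
            [classical_Z(BindingSystem(x, m), K) for x, m in zip(tr.Xt, tr.Mt)]
        )
        q_ref = dH * np.diff(Z_ref, prepend=0.0) * modeled_schedule.cell_volume
        np.testing.assert_allclose(tr.q, q_ref, rtol=1e-8)

    def test_constant_K_when_dGS_zero(self, modeled_schedule, cond25):
        tr = simulate_titration(modeled_schedule, GoverningParams(-8.60, 0.0), -47.0, cond25)
        assert np.ptp(tr.K) / tr.K[0] < 1e-10

    def test_K_declines_before_equivalence(self, modeled_schedule, modeled_params, cond25):
        tr = simulate_titration(modeled_schedule, modeled_params, -47.0, cond25)
        pre = tr.K[tr.molar_ratio < 1.0]
        assert np.all(np.diff(pre) < 0)
        # near-constant plateau over the last five injections
        tail = tr.K[-5:]
        assert np.ptp(tail) / tail.mean() < 0.05

    def test_heat_conservation_paper_mode(self, modeled_schedule, modeled_params, cond25):
        dH = -47.0
        tr = simulate_titration(modeled_schedule, modeled_params, dH, cond25)
        assert tr.q.sum() == pytest.approx(dH * tr.Z[-1] * modeled_schedule.cell_volume)

    def test_Z_monotone_and_ratio_increasing(self, modeled_schedule, modeled_params, cond25):
        tr = simulate_titration(modeled_schedule, modeled_params, -47.0, cond25)
        assert np.all(np.diff(tr.Z) > 0)
        assert np.all(np.diff(tr.molar_ratio) > 0)


class TestMatchKToConcentration:
    def test_selects_last_pre_equivalence_injection(
        self, modeled_schedule, modeled_params, cond25
    ):
        tr = simulate_titration(modeled_schedule, modeled_params, -47.0, cond25)
        K, Z = match_K_to_concentration(tr)
        # i = 14 on the 0.069-per-injection ratio grid
        assert K == pytest.approx(tr.K[13])
        assert Z == pytest.approx(tr.Z[13])

    def test_single_injection_below_one(self, cond25, modeled_params):
        s = InjectionSchedule(n_injections=1, injection_volume=10e-6,
                              cell_volume=1.45e-3, syringe_conc=2.0e-3,
                              cell_conc_initial=2.0e-4)
        tr = simulate_titration(s, modeled_params, -47.0, cond25)
        K, Z = match_K_to_concentration(tr)
        assert K == pytest.approx(tr.K[0])

    def test_all_ratios_above_one_rejected(self, cond25, modeled_params):
        s = InjectionSchedule(n_injections=2, injection_volume=200e-6,
                              cell_volume=1.45e-3, syringe_conc=2.0e-3,
                              cell_conc_initial=2.0e-5)
        tr = simulate_titration(s, modeled_params, -47.0, cond25)
        with pytest.raises(ValueError, match="mismatch"):
            match_K_to_concentration(tr)

    def test_brandts_convention(self):
        assert brandts_complex_conc(1.0e-3) == pytest.approx(9.0e-4)
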