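import math

import numpy as np
import pytest

from solvitc import (
    CdSpectrum,
    Conditions,
    FoldingSystem,
    GoverningParams,
    concentration_independence_stat,
    make_cd_bases,
    mg_per_ml_to_molar,
    predict_cd,
    solve_folding_fraction,
)

R = 1.9872e-3


def brute_force_fraction(dG0, dGS, P_total, T=298.15, n_grid=2_000_000):
    """Grid-scan oracle for the two-state governing equation root."""
    f = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = -R * T * np.log(f / (1 - f)) - f * P_total * dGS - dG0
    idx = np.nonzero(np.sign(g[:-1]) != np.sign(g[1:]))[0]
    assert len(idx) >= 1
    return 0.5 * (f[idx[0]] + f[idx[0] + 1])


class TestSolveFoldingFraction:
    def test_midpoint(self, cond25):
        sys_ = FoldingSystem(1e-3, GoverningParams(0.0, 0.0))
        assert solve_folding_fraction(sys_, cond25) == pytest.approx(0.5, abs=1e-12)

    def test_classical_closed_form_at_zero_dGS(self, cond25):
        for dG0 in (-2.0, -0.5, 0.3, 1.7):
            K = math.exp(-dG0 / cond25.RT)
            expected = K / (1 + K)
            for P in (1e-5, 1e-3):
                sys_ = FoldingSystem(P, GoverningParams(dG0, 0.0))
                assert solve_folding_fraction(sys_, cond25) == pytest.approx(
                    expected, rel=1e-10
                )

    def test_independent_of_P_at_zero_dGS(self, cond25):
        params = GoverningParams(-0.8, 0.0)
        fs = [
            solve_folding_fraction(FoldingSystem(P, params), cond25)
            for P in np.geomspace(7e-5, 7e-3, 6)
        ]
        assert np.ptp(fs) < 1e-12

    def test_decreasing_in_P_for_positive_dGS(self, cond25):
        params = GoverningParams(-0.8, 500.0)
        fs = [
            solve_folding_fraction(FoldingSystem(P, params), cond25)
            for P in np.geomspace(7e-5, 7e-3, 6)
        ]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_increasing_in_P_for_negative_dGS(self, cond25):
        params = GoverningParams(0.3, -400.0)
        fs = [
            solve_folding_fraction(FoldingSystem(P, params), cond25)
            for P in np.geomspace(7e-5, 7e-3, 6)
        ]
        assert all(a < b for a, b in zip(fs, fs[1:]))

    def test_against_grid_scan_oracle(self, cond25):
        for dG0, dGS, P in [(-0.8, 500.0, 1e-3), (0.2, 1200.0, 5e-3), (-1.5, 0.0, 1e-4)]:
            f_oracle = brute_force_fraction(dG0, dGS, P)
            sys_ = FoldingSystem(P, GoverningParams(dG0, dGS))
            assert solve_folding_fraction(sys_, cond25) == pytest.approx(
                f_oracle, abs=5e-6
            )

    def test_mg_ml_conversion(self):
        assert mg_per_ml_to_molar(14.178, 14178.0) == pytest.approx(1e-3)
        sys_ = FoldingSystem.from_mg_per_ml(100.0, GoverningParams(-0.8, 0.0))
        assert sys_.P_total == pytest.approx(100.0 / 14178.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            FoldingSystem(0.0, GoverningParams(-1.0, 0.0))


class TestPredictCd:
    def test_endpoints(self):
        folded, unfolded = make_cd_bases()
        np.testing.assert_array_equal(
            predict_cd(1.0, folded, unfolded).ellipticity, folded.ellipticity
        )
        np.testing.assert_array_equal(
            predict_cd(0.0, folded, unfolded).ellipticity, unfolded.ellipticity
        )

    def test_midpoint_is_mean(self):
        folded, unfolded = make_cd_bases()
        mixed = predict_cd(0.5, folded, unfolded)
        np.testing.assert_allclose(
            mixed.ellipticity, 0.5 * (folded.ellipticity + unfolded.ellipticity)
        )

    def test_grid_mismatch_rejected(self):
        folded, _ = make_cd_bases()
        other = CdSpectrum(np.arange(260.0, 300.0), np.zeros(40), 1.0, 1.0)
        with pytest.raises(ValueError, match="grid"):
            predict_cd(0.5, folded, other)

    def test_isodichroic_points_conserved(self):
        # wavelengths where both bases agree stay fixed for every mix
        wl = np.arange(250.0, 321.0)
        a = np.sin(wl / 10.0)
        b = a.copy()
        b[10:] += 1.0  # bases agree on the first 10 wavelengths only
        fold = CdSpectrum(wl, a, 1.0, 1.0)
        unfold = CdSpectrum(wl, b, 1.0, 1.0)
        for f in (0.1, 0.35, 0.9):
            mixed = predict_cd(f, fold, unfold)
            np.testing.assert_allclose(mixed.ellipticity[:10], a[:10])


class TestConcentrationIndependenceStat:
    def test_identical_spectra(self):
        folded, _ = make_cd_bases()
        spectra = [
            CdSpectrum(folded.wavelength_nm, folded.ellipticity, c, 1.0 / c)
            for c in (1.0, 10.0, 100.0)
        ]
        assert concentration_independence_stat(spectra) == 0.0

    def test_inconsistent_conc_pathlength_rejected(self):
        folded, _ = make_cd_bases()
        spectra = [
            CdSpectrum(folded.wavelength_nm, folded.ellipticity, 1.0, 1.0),
            CdSpectrum(folded.wavelength_nm, folded.ellipticity, 10.0, 1.0),
        ]
        with pytest.raises(ValueError, match="pathlength"):
            concentration_independence_stat(spectra)

    def test_zero_for_zero_dGS_series(self, cond25):
        from solvitc import SynthConfig, gen_cd_series

        cfg = SynthConfig(seed=1, params=GoverningParams(-0.8, 0.0))
        spectra = gen_cd_series(cfg, [1.0, 5.0, 20.0, 100.0])
        assert concentration_independence_stat(spectra) < 1e-10

    def test_positive_and_growing_with_dGS(self, cond25):
        from solvitc import SynthConfig, gen_cd_series

        stats = []
        for dGS in (500.0, 2000.0):
            cfg = SynthConfig(seed=1, params=GoverningParams(-0.8, dGS))
            spectra = gen_cd_series(cfg, [1.0, 5.0, 20.0, 100.0])
            stats.append(concentration_independence_stat(spectra))
        assert stats[0] > 0
        assert stats[1] > stats[0]
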