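"""Isodesmic self-association: closed forms, invariants, parameter recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from nmrbind import (
    DilutionExperiment,
    DomainError,
    ProtonShiftSeries,
    SimulationConfig,
    fit_isodesmic,
    monomer_concentration,
    observed_dilution_shift,
    oligomer_distribution,
    predict_dilution_shift,
    simulate_dilution,
)

log_ka = st.floats(-2.0, 1.0)   # Ka = 10**x in mM^-1
log_l0 = st.floats(-2.5, 0.5)   # L0 = 10**x in mM


class TestMonomerConcentration:
    @pytest.mark.parametrize("ka, l0, expected", [
        (0.0, 2.0, 2.0),          # no association
        (1.0, 2.0, 0.5),          # 0.5 / (1 - 0.5)**2 == 2
        (0.0, 0.003, 0.003),
    ])
    def test_closed_form_examples(self, ka, l0, expected):
        assert monomer_concentration(ka, l0) == pytest.approx(expected, rel=1e-12)

    @given(log_ka, log_l0)
    def test_matches_numerical_root(self, lka, ll0):
        """Closed form agrees with brentq on L0 = [L]/(1 - Ka*[L])**2."""
        ka, l0 = 10.0 ** lka, 10.0 ** ll0
        f = lambda l: l / (1.0 - ka * l) ** 2 - l0
        hi = min(l0, 1.0 / ka * (1 - 1e-12))
        root = brentq(f, 1e-16, hi, xtol=1e-300, rtol=1e-15)
        assert monomer_concentration(ka, l0) == pytest.approx(root, rel=1e-10)

    def test_mass_balance_residual(self):
        for ka, l0 in [(0.5, 1.2), (1.71, 0.9), (10.0, 1.0)]:
            l = monomer_concentration(ka, l0)
            assert l / (1.0 - ka * l) ** 2 == pytest.approx(l0, rel=1e-10)

    def test_saturation_limit_monotone(self):
        kas = np.geomspace(0.1, 1e4, 30)
        mono = np.array([monomer_concentration(k, 2.0) for k in kas])
        assert np.all(np.diff(mono) < 0) and mono[-1] < 1e-3

    @pytest.mark.parametrize("ka, l0", [(-1.0, 1.0), (1.0, -1.0),
                                        (np.nan, 1.0), (1.0, 0.0)])
    def test_domain_errors(self, ka, l0):
        with pytest.raises(DomainError):
            monomer_concentration(ka, l0)


class TestOligomerDistribution:
    def test_geometric_ladder(self):
        np.testing.assert_allclose(oligomer_distribution(1.0, 2.0, 3),
                                   [0.5, 0.25, 0.125], rtol=1e-12)

    def test_no_association_is_pure_monomer(self):
        np.testing.assert_array_equal(oligomer_distribution(0.0, 1.0, 5),
                                      [1.0, 0.0, 0.0, 0.0, 0.0])

    @given(log_ka, log_l0)
    def test_mass_conservation(self, lka, ll0):
        """sum(n * [L_n]) reproduces L0 once the ladder is summed far enough."""
        ka, l0 = 10.0 ** lka, 10.0 ** ll0
        if ka * l0 > 10.0:
            return
        conc = oligomer_distribution(ka, l0, 200)
        n = np.arange(1, 201)
        assert abs(float(n @ conc) - l0) < 1e-6


class TestPredictDilutionShift:
    def test_monomer_and_stacking_limits(self):
        assert predict_dilution_shift(0.0, 1.0, 1.0) == 0.0
        assert predict_dilution_shift(1e6, 1.0, 1.0) == pytest.approx(1.0, abs=1e-3)

    def test_derived_value(self):
        # Ka*L0 = 2 -> 2 * (2 / (1 + 3))**2 = 0.5
        assert predict_dilution_shift(1.0, 2.0, 1.0) == pytest.approx(0.5, rel=1e-12)

    @given(log_ka, log_l0)
    def test_equals_ka_times_free_monomer(self, lka, ll0):
        """The isotherm factor is algebraically Ka*[L]."""
        ka, l0 = 10.0 ** lka, 10.0 ** ll0
        lhs = predict_dilution_shift(ka, l0, 1.0)
        assert lhs == pytest.approx(ka * monomer_concentration(ka, l0), rel=1e-12)

    def test_strictly_increasing_in_l0_and_ka(self):
        grid = np.geomspace(0.003, 1.2, 40)
        d = predict_dilution_shift(1.71, grid, 0.6)
        assert np.all(np.diff(d) > 0)
        kas = np.geomspace(0.01, 100, 40)
        d = np.array([predict_dilution_shift(k, 0.5, 0.6) for k in kas])
        assert np.all(np.diff(d) > 0)
        assert np.all(d >= 0) and np.all(d <= 0.6)

    def test_negative_delta_max_flips_sign(self):
        assert predict_dilution_shift(1.0, 2.0, -0.5) == pytest.approx(-0.25)


class TestFitIsodesmic:
    def test_noiseless_round_trip_recovers_truth(self):
        cfg = SimulationConfig(model="dilution", true_params={"Ka": 1.71},
                               noise_sd=0.0)
        fit = fit_isodesmic(simulate_dilution(cfg))
        assert fit.Ka_mean_mM_inv == pytest.approx(1.71, rel=1e-6)
        # per-proton shift parameters come back too, with their signs
        by_label = {p.proton_label: p for p in fit.per_proton}
        assert by_label["H12"].delta_max_ppm == pytest.approx(0.65, rel=1e-5)
        assert by_label["H23"].delta_max_ppm == pytest.approx(-0.08, rel=1e-4)

    def test_global_mode_shares_ka(self):
        cfg = SimulationConfig(model="dilution", true_params={"Ka": 0.70},
                               noise_sd=0.0)
        fit = fit_isodesmic(simulate_dilution(cfg), mode="global")
        assert fit.Ka_mean_mM_inv == pytest.approx(0.70, rel=1e-6)
        assert len({p.Ka_mM_inv for p in fit.per_proton}) == 1

    @pytest.mark.parametrize("true_ka, printed_pm", [(1.71, 0.24), (0.70, 0.38)])
    def test_noisy_recovery_within_reported_spread(self, true_ka, printed_pm):
        """At 0.002 ppm shift noise on the 12-point dilution design, the
        pooled Ka lands within the experiment's own reported spread."""
        cfg = SimulationConfig(model="dilution", true_params={"Ka": true_ka},
                               seed=7)
        fit = fit_isodesmic(simulate_dilution(cfg))
        assert abs(fit.Ka_mean_mM_inv - true_ka) < printed_pm

    def test_monte_carlo_bias_small(self):
        """Ka_mean is unbiased to within 5% over replicate simulations."""
        panel = {"H12": (8.28, 0.65), "H14": (7.52, 0.62)}
        est = []
        for rep in range(200):
            cfg = SimulationConfig(model="dilution",
                                   true_params={"Ka": 1.71, "protons": panel},
                                   seed=10_000 + rep)
            est.append(fit_isodesmic(simulate_dilution(cfg)).Ka_mean_mM_inv)
        assert abs(np.mean(est) - 1.71) < 0.05 * 1.71

    def test_noise_floor_exclusion_is_flagged(self):
        cfg = SimulationConfig(model="dilution", true_params={"Ka": 1.71},
                               noise_sd=0.0)
        exp = simulate_dilution(cfg)
        with pytest.warns(UserWarning, match="noise floor"):
            fit = fit_isodesmic(exp, noise_floor_ppm=0.05)
        assert "H23" in fit.excluded  # |swing| ~ 0.05 ppm at Ka=1.71
        assert all(p not in {"H12", "H14"} for p in fit.excluded)

    def test_requires_enough_points_and_span(self):
        s = ProtonShiftSeries("H1", [0.1, 0.2, 0.3], [1.0, 0.9, 0.8])
        with pytest.raises(ValueError, match="4 points"):
            fit_isodesmic(DilutionExperiment("c", (s,)))
        s = ProtonShiftSeries("H1", [0.1, 0.2, 0.3, 0.4], [1.0, 0.9, 0.8, 0.7])
        with pytest.raises(ValueError, match="decade"):
            fit_isodesmic(DilutionExperiment("c", (s,)))

    def test_series_validation(self):
        with pytest.raises(ValueError):
            ProtonShiftSeries("H1", [0.1, 0.1, 0.3], [1.0, 0.9, 0.8])
        with pytest.raises(ValueError):
            ProtonShiftSeries("H1", [-0.1, 0.2], [1.0, 0.9])
        with pytest.raises(ValueError):
            ProtonShiftSeries("H1", [0.1, 0.2], [np.inf, 0.9])
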