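"""1:1 binding titrations: equilibrium algebra, isotherm, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nmrbind import (
    DomainError,
    SimulationConfig,
    TitrationExperiment,
    bound_ligand_fraction,
    complex_concentration,
    fit_binding_titration,
    fit_isodesmic,
    free_dna_concentration,
    predict_observed_diffusion,
    predict_titration_shift,
    simulate_dilution,
    simulate_titration,
)
from nmrbind.dosy import DiffusionRecord, ka_from_diffusion

pos_conc = st.floats(0.01, 5.0)
ka_vals = st.floats(0.0, 50.0)


class TestFreeDnaConcentration:
    @pytest.mark.parametrize("ka, c_dna, c_l, expected", [
        (0.0, 1.0, 1.0, 1.0),                        # no binding
        (1.0, 1.0, 1.0, (np.sqrt(5) - 1) / 2),       # golden-ratio root
        (5.0, 1.0, 0.0, 1.0),                        # no ligand
    ])
    def test_quadratic_root_examples(self, ka, c_dna, c_l, expected):
        assert free_dna_concentration(ka, c_dna, c_l) == pytest.approx(
            expected, rel=1e-12)

    @given(ka_vals, pos_conc, pos_conc)
    def test_mass_action_and_mass_balances(self, ka, c_dna, c_l):
        """Back-substituted root satisfies Ka = [DNA.L]/([DNA][L]) and both
        totals to 1e-10 relative."""
        d = free_dna_concentration(ka, c_dna, c_l)
        complex_ = c_dna - d
        l_free = c_l - complex_
        assert max(0.0, c_dna - c_l) - 1e-12 <= d <= c_dna + 1e-12
        assert d + complex_ == pytest.approx(c_dna, rel=1e-10)
        assert l_free + complex_ == pytest.approx(c_l, rel=1e-10)
        if ka > 0 and d > 1e-12 and l_free > 1e-12:
            assert complex_ / (d * l_free) == pytest.approx(ka, rel=1e-8)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            free_dna_concentration(-1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            free_dna_concentration(1.0, -1.0, 1.0)


class TestPredictTitrationShift:
    def test_half_saturation(self):
        # Ka*[DNA] = 1 with total_approx: C_DNA = 1/Ka
        assert predict_titration_shift(2.0, 0.5, 0.1, 1.0,
                                       "total_approx") == pytest.approx(0.5)

    def test_derived_free_exact_value(self):
        got = predict_titration_shift(1.0, 1.0, 1.0, 1.0, "free_exact")
        d = (np.sqrt(5) - 1) / 2
        assert got == pytest.approx(d / (1 + d), rel=1e-12)

    def test_saturation_limit(self):
        assert predict_titration_shift(1.0, 1e6, 0.1, -0.4) == pytest.approx(
            -0.4, rel=1e-5)

    def test_bound_fraction_monotone_and_confined(self):
        c_dna = np.linspace(0.0, 3.0, 50)
        fb = bound_ligand_fraction(5.0, c_dna, np.full(50, 0.3))
        assert np.all(np.diff(fb) > 0) and fb[0] == 0.0 and fb[-1] < 1.0
        kas = np.linspace(0.1, 50, 50)
        fb = np.array([bound_ligand_fraction(k, 0.9, 0.3) for k in kas])
        assert np.all(np.diff(fb) > 0)

    def test_modes_agree_in_excess_dna(self):
        """Free and total conventions converge when DNA swamps the ligand."""
        ka, c_l = 0.5, 0.001  # Ka*C_L well under 0.1
        c_dna = 0.05          # >= 20x the ligand
        exact = predict_titration_shift(ka, c_dna, c_l, 1.0, "free_exact")
        approx = predict_titration_shift(ka, c_dna, c_l, 1.0, "total_approx")
        assert abs(exact - approx) / abs(exact) < 0.01


class TestFitBindingTitration:
    @pytest.mark.parametrize("true_ka", [5.00, 3.76])
    def test_noiseless_round_trip(self, true_ka):
        cfg = SimulationConfig(model="titration", true_params={"Ka": true_ka},
                               noise_sd=0.0)
        fit = fit_binding_titration(simulate_titration(cfg))
        assert fit.Ka_mean_mM_inv == pytest.approx(true_ka, rel=1e-6)

    @pytest.mark.parametrize("true_ka, printed_pm", [(5.00, 2.02), (3.76, 1.19)])
    def test_noisy_recovery_within_reported_spread(self, true_ka, printed_pm):
        cfg = SimulationConfig(model="titration", true_params={"Ka": true_ka},
                               seed=11)
        fit = fit_binding_titration(simulate_titration(cfg))
        assert abs(fit.Ka_mean_mM_inv - true_ka) < printed_pm

    def test_mode_equivalence_in_dna_excess(self):
        """With DNA far in excess, fitting with total instead of free duplex
        moves Ka by under 5%."""
        c_l = 0.005
        cfg = SimulationConfig(
            model="titration",
            true_params={"Ka": 2.0},
            design={"C_L_mM": c_l,
                    "C_DNA_mM": np.linspace(0.0, 0.6, 8)},
            noise_sd=0.0)
        exp = simulate_titration(cfg)
        ka_free = fit_binding_titration(exp, "free_exact").Ka_mean_mM_inv
        ka_total = fit_binding_titration(exp, "total_approx").Ka_mean_mM_inv
        assert abs(ka_free - ka_total) / ka_free < 0.05

    def test_agrees_with_diffusion_route_at_same_ka(self):
        """Titration-fitted Ka matches the diffusion-derived Ka when both
        observables are generated from the same equilibrium."""
        ka = 5.0
        cfg = SimulationConfig(model="titration", true_params={"Ka": ka},
                               seed=21)
        ka_titr = fit_binding_titration(simulate_titration(cfg)).Ka_mean_mM_inv
        dl, dd = predict_observed_diffusion(ka, 0.3, 0.9, 4.0e-10, 1.3e-10)
        ka_dosy = ka_from_diffusion(DiffusionRecord(
            "x", 0.3, 0.9, dl, dd, 4.0e-10, 1.3e-10)).Ka_mM_inv
        assert abs(ka_titr - ka_dosy) < 1.0  # within simulation scatter

    def test_self_association_baseline_drift_biases_fixed_baseline_fit(self):
        """A self-associating ligand's baseline drifts during the titration;
        a fixed-baseline fit is biased and the isodesmic correction, fed the
        free ligand's own dilution fit, removes most of that bias."""
        true_ka = 5.0
        self_assoc = {"H12": (1.71, 8.28, 0.65), "H14": (1.71, 7.52, 0.62)}
        cfg = SimulationConfig(
            model="titration",
            true_params={"Ka": true_ka,
                         "delta_complex": {"H12": -0.50, "H14": -0.45},
                         "delta_L": {"H12": 8.28, "H14": 7.52},
                         "self_association": self_assoc},
            noise_sd=0.0)
        exp = simulate_titration(cfg)
        plain = fit_binding_titration(exp)
        dil = fit_isodesmic(simulate_dilution(SimulationConfig(
            model="dilution",
            true_params={"Ka": 1.71,
                         "protons": {"H12": (8.28, 0.65), "H14": (7.52, 0.62)}},
            noise_sd=0.0)))
        corrected = fit_binding_titration(exp, baseline_correction=dil)
        err_plain = abs(plain.Ka_mean_mM_inv - true_ka)
        err_corr = abs(corrected.Ka_mean_mM_inv - true_ka)
        assert err_plain > 0.2          # the confound is material
        assert err_corr < 0.2 * err_plain

    def test_poor_saturation_warns(self):
        cfg = SimulationConfig(
            model="titration", true_params={"Ka": 0.05}, noise_sd=0.0)
        with pytest.warns(UserWarning, match="poorly constrained"):
            fit_binding_titration(simulate_titration(cfg))

    def test_experiment_validation(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            TitrationExperiment("c", "d", [0.3, 0.3], [0.6, 0.3],
                                {"H1": [7.0, 7.1]})
        with pytest.raises(ValueError, match="length"):
            TitrationExperiment("c", "d", [0.3, 0.3], [0.0, 0.3],
                                {"H1": [7.0]})
        exp = TitrationExperiment("c", "d", [0.3, 0.3, 0.3, 0.3],
                                  [0.1, 0.3, 0.6, 0.9],
                                  {"H1": [7.0, 6.9, 6.8, 6.7]})
        with pytest.raises(ValueError, match="baseline"):
            exp.delta_L("H1")
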