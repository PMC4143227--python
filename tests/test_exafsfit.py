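"""k-space shell refinement: recovery, uncertainties, model comparison."""

from dataclasses import replace

import numpy as np
import pytest

from hemexas import (
    ChiSpectrum,
    EXAFSModel,
    Shell,
    compare_models,
    fit_shells,
    model_chi,
    simulate_chi,
)
from conftest import noisy_copy


def perturbed_start(model, dr=0.05, sigma_factor=2.0):
    out = model
    for s in model.shells:
        out = out.replace_shell(s.label, r=s.r + dr, sigma2=s.sigma2 * sigma_factor)
    return out


def only_free(model, free):
    """Restrict refinable parameters: free maps label -> flags triple."""
    out = model
    for s in model.shells:
        out = out.replace_shell(
            s.label, free_flags=free.get(s.label, (False, False, False))
        )
    return out


class TestForwardSharing:
    def test_model_chi_is_the_generator(self):
        assert model_chi is simulate_chi


class TestFitRecovery:
    def test_noiseless_recovery_from_perturbed_start(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        """Distances within 0.01 A and disorder within 10% of truth when
        starting +0.05 A / x2 away, coordination numbers fixed."""
        start = perturbed_start(ligand_free_model)
        res = fit_shells(chi_ligand_free, start, funcs)
        for shell in ligand_free_model.shells:
            fitted = res.model[shell.label]
            assert fitted.r == pytest.approx(shell.r, abs=0.01)
            assert fitted.sigma2 == pytest.approx(shell.sigma2, rel=0.10)
        assert not res.at_bound

    def test_axial_oxygen_compression_recovered(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        # the refined Fe-O bond is compressed to ~2.5 A (vs 2.78 in the
        # crystal); the fit must find it from a perturbed start
        res = fit_shells(chi_ligand_free, perturbed_start(ligand_free_model), funcs)
        assert round(res.model["II Fe-O"].r, 1) == 2.5

    def test_perfect_start_leaves_parameters_unchanged(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        res = fit_shells(
            chi_ligand_free, ligand_free_model, funcs, noise=1e-3, multistart=1
        )
        assert res.chi2_reduced == pytest.approx(0.0, abs=1e-12)
        assert np.max(np.abs(res.residual)) < 1e-10
        for shell in ligand_free_model.shells:
            assert res.model[shell.label].r == pytest.approx(shell.r, abs=1e-8)

    def test_amplitude_factor_recovered_free(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        m = only_free(ligand_free_model, {s.label: (False, True, False)
                                          for s in ligand_free_model.shells})
        m = replace(m, s02=1.0, s02_free=True)
        for s in ligand_free_model.shells:
            m = m.replace_shell(s.label, r=s.r + 0.02)
        res = fit_shells(chi_ligand_free, m, funcs)
        assert round(res.model.s02, 2) == 0.85

    def test_energy_shift_recovered_free(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        m = only_free(ligand_free_model, {s.label: (False, True, False)
                                          for s in ligand_free_model.shells})
        m = replace(m, delta_e=0.0, delta_e_free=True)
        for s in ligand_free_model.shells:
            m = m.replace_shell(s.label, r=s.r + 0.02)
        res = fit_shells(chi_ligand_free, m, funcs)
        assert round(res.model.delta_e, 2) == 1.35

    def test_too_many_free_parameters(self, ligand_free_model, funcs):
        k = np.linspace(3.0, 3.3, 5)
        chi = simulate_chi(ligand_free_model, funcs, k)
        with pytest.raises(ValueError, match="free parameters"):
            EXAFSModel(chi, perturbed_start(ligand_free_model), funcs,
                       k_range=(3.0, 3.3))


class TestBruteForceOracle:
    def test_optimum_matches_dense_grid_search(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        """On <= 2 free parameters the minimizer lands within one step of
        a dense brute-force grid (independent oracle)."""
        chi = noisy_copy(chi_ligand_free, 1e-3, seed=17)
        m = only_free(ligand_free_model, {"I Fe-N": (False, True, True)})
        exm = EXAFSModel(chi, m, funcs, noise=1e-3)
        res = exm.fit()
        step = 1e-3
        r_grid = np.arange(2.03, 2.11 + step / 2, step)
        s_grid = np.arange(1e-3, 8e-3 + step / 2, step)
        best, argbest = np.inf, None
        for r in r_grid:
            for s2 in s_grid:
                a = exm.objective([r, s2])
                if a < best:
                    best, argbest = a, (r, s2)
        names = res.param_names
        assert res.theta[names.index("I Fe-N.r")] == pytest.approx(
            argbest[0], abs=step
        )
        assert res.theta[names.index("I Fe-N.sigma2")] == pytest.approx(
            argbest[1], abs=step
        )
        assert res.objective_min <= best + 1e-15


class TestGoodnessMetrics:
    def test_chi2_calibration_on_correct_model(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        """chi2_nu ~ 1 over 20 seeded replicates of correctly specified
        noisy data (and the fitted first-shell distance is unbiased)."""
        chi2s, r_vals = [], []
        for rep in range(20):
            chi = noisy_copy(chi_ligand_free, 1e-3, seed=100 + rep)
            res = fit_shells(chi, ligand_free_model, funcs, noise=1e-3,
                             multistart=1)
            chi2s.append(res.chi2_reduced)
            r_vals.append(res.model["I Fe-N"].r)
        assert 0.5 < np.mean(chi2s) < 2.0
        assert np.all((np.array(chi2s) > 0.4) & (np.array(chi2s) < 2.5))
        assert np.mean(r_vals) == pytest.approx(2.07, abs=0.01)

    def test_sigma_coverage_between_half_and_ninety_percent(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        hits = 0
        for rep in range(20):
            chi = noisy_copy(chi_ligand_free, 1e-3, seed=300 + rep)
            res = fit_shells(chi, ligand_free_model, funcs, noise=1e-3,
                             multistart=1)
            sig = res.uncertainties["I Fe-N.r"][0]
            hits += abs(res.model["I Fe-N"].r - 2.07) <= sig
        assert 0.5 <= hits / 20 <= 0.9

    def test_r_squared_scale_invariant(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        # an intentionally imperfect model (disorder fixed 1.5x too large,
        # only distances free) leaves a finite residual whose R^2 must not
        # change when data and model amplitude are scaled together
        m = only_free(ligand_free_model, {s.label: (False, True, False)
                                          for s in ligand_free_model.shells})
        for s in ligand_free_model.shells:
            m = m.replace_shell(s.label, sigma2=s.sigma2 * 1.5)
        res = fit_shells(chi_ligand_free, m, funcs)
        assert res.r_squared > 1e-6
        scaled = ChiSpectrum(chi_ligand_free.k, 1.2 * chi_ligand_free.chi)
        res2 = fit_shells(scaled, replace(m, s02=0.85 * 1.2), funcs)
        assert res2.r_squared == pytest.approx(res.r_squared, rel=1e-6)

    def test_misspecified_model_never_beats_generator(
        self, drug_bound_model, chi_drug_bound, ligand_free_model, funcs
    ):
        four = fit_shells(chi_drug_bound, perturbed_start(ligand_free_model, 0.02, 1.5), funcs)
        five = fit_shells(chi_drug_bound, perturbed_start(drug_bound_model, 0.02, 1.5), funcs)
        assert four.r_squared >= five.r_squared


class TestProfileUncertainty:
    def test_single_linear_parameter_matches_analytic(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        """chi is linear in a shell multiplicity: the profile interval
        must equal the closed-form least-squares sigma."""
        chi = noisy_copy(chi_ligand_free, 1e-3, seed=9)
        m = only_free(ligand_free_model, {"I Fe-N": (True, False, False)})
        res = fit_shells(chi, m, funcs, noise=1e-3)
        _, parts = simulate_chi(ligand_free_model, funcs, chi.k,
                                return_partials=True)
        g = parts["I Fe-N"].chi / ligand_free_model["I Fe-N"].N
        kw = chi.k**1
        sigma_w2 = 1e-6 * np.mean(kw**2)
        analytic = np.sqrt(sigma_w2 / np.sum((kw * g) ** 2))
        prof = res.conf_interval("I Fe-N.N")
        assert prof["low"] == pytest.approx(analytic, rel=0.01)
        assert prof["high"] == pytest.approx(analytic, rel=0.01)

    def test_profile_matches_covariance_when_mildly_nonlinear(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        chi = noisy_copy(chi_ligand_free, 1e-3, seed=10)
        m = only_free(ligand_free_model, {"I Fe-N": (False, True, True)})
        res = fit_shells(chi, m, funcs, noise=1e-3)
        for name in res.param_names:
            prof = res.conf_interval(name)
            cov = res.uncertainties[name][0]
            assert prof["low"] == pytest.approx(cov, rel=0.05)
            assert prof["high"] == pytest.approx(cov, rel=0.05)

    def test_correlation_widens_profile_beyond_conditional(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        """N and sigma2 of one shell are strongly correlated; the profile
        interval (which re-minimizes the partner) must exceed the
        conditional interval that pretends the partner is known."""
        chi = noisy_copy(chi_ligand_free, 1e-3, seed=11)
        m = only_free(ligand_free_model, {"I Fe-N": (True, False, True)})
        exm = EXAFSModel(chi, m, funcs, noise=1e-3)
        res = exm.fit()
        assert abs(res.correlations[0, 1]) > 0.5
        fisher = np.linalg.inv(res.covariance)
        for j, name in enumerate(res.param_names):
            conditional = 1.0 / np.sqrt(fisher[j, j])
            prof = res.conf_interval(name)
            assert prof["low"] >= conditional * 1.05
            assert prof["high"] >= conditional * 1.05

    def test_bound_hit_is_flagged(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        m = only_free(ligand_free_model, {"I Fe-N": (False, True, True)})
        m = m.replace_shell("I Fe-N", bounds={"sigma2": (4.05e-3, 4.2e-3)})
        res = fit_shells(chi_ligand_free, m, funcs, noise=1e-3)
        prof = res.conf_interval("I Fe-N.sigma2")
        assert prof["at_bound_low"] or prof["at_bound_high"]


class TestBoundPinning:
    def test_underfitting_drug_data_collapses_first_shell_disorder(
        self, ligand_free_model, chi_drug_bound, funcs
    ):
        """Fitting the five-coordinate model to six-coordinate data drives
        the first-shell MSRD far below its ligand-free value (the fit
        fakes the extra neighbor's amplitude by sharpening shell I)."""
        m = ligand_free_model.replace_shell(
            "I Fe-N", bounds={"sigma2": (1e-3, 0.1)}
        )
        res = fit_shells(chi_drug_bound, m, funcs, noise=1e-3)
        assert res.model["I Fe-N"].sigma2 < 0.6 * 4.1e-3

    def test_pinned_parameter_equals_bound_exactly(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        m = only_free(ligand_free_model, {"I Fe-N": (False, True, True)})
        m = m.replace_shell("I Fe-N", bounds={"sigma2": (5e-3, 0.1)},
                            sigma2=5.5e-3)
        res = fit_shells(chi_ligand_free, m, funcs)
        assert "I Fe-N.sigma2" in res.at_bound
        assert res.model["I Fe-N"].sigma2 == 5e-3


class TestModelComparison:
    @pytest.fixture()
    def five_plus_one(self, ligand_free_model):
        return ligand_free_model.add_shell(
            Shell("Nb Fe-N", "N", 1, 2.10, 4.1e-3,
                  free_flags=(True, True, False), sigma2_tied_to="I Fe-N")
        )

    def test_identical_fits_no_preference(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        a = fit_shells(chi_ligand_free, ligand_free_model, funcs, multistart=1)
        b = fit_shells(chi_ligand_free, ligand_free_model, funcs, multistart=1)
        cmp_ = compare_models(a, b)
        assert cmp_.preferred == "none"
        assert cmp_.delta_n_free == 0

    def test_six_coordinate_model_wins_on_drug_data(
        self, ligand_free_model, five_plus_one, chi_drug_bound, funcs
    ):
        a = fit_shells(chi_drug_bound, ligand_free_model, funcs)
        b = fit_shells(chi_drug_bound, five_plus_one, funcs)
        cmp_ = compare_models(a, b)
        assert cmp_.preferred == "b"
        assert b.model["Nb Fe-N"].r == pytest.approx(2.15, abs=0.02)

    def test_parsimony_on_five_coordinate_truth(
        self, ligand_free_model, five_plus_one, chi_ligand_free, funcs
    ):
        """The richer model must NOT be preferred when the data contain no
        sixth neighbor: its extra multiplicity collapses to ~0 or the
        residual gain stays below threshold."""
        a = fit_shells(chi_ligand_free, ligand_free_model, funcs)
        b = fit_shells(chi_ligand_free, five_plus_one, funcs)
        cmp_ = compare_models(a, b)
        assert cmp_.preferred != "b"

    def test_different_data_rejected(
        self, ligand_free_model, chi_ligand_free, chi_drug_bound, funcs
    ):
        a = fit_shells(chi_ligand_free, ligand_free_model, funcs)
        b = fit_shells(chi_drug_bound, ligand_free_model, funcs)
        with pytest.raises(ValueError, match="same data"):
            compare_models(a, b)


class TestSummary:
    def test_summary_reports_key_quantities(
        self, ligand_free_model, chi_ligand_free, funcs
    ):
        res = fit_shells(chi_ligand_free, perturbed_start(ligand_free_model),
                         funcs, noise=1e-3)
        text = res.summary()
        assert "chi2_reduced" in text and "S0^2 0.850" in text
        assert "I Fe-N" in text
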