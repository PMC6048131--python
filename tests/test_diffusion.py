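"""Diffusion engine: drift/selection terms, expected spectra, demography."""

import numpy as np
import pytest

from domfit.diffusion import (DemographicModel, ancestral_ne,
                              drift_selection_terms, expected_sfs,
                              fit_demography, selfing_effective_params)
from domfit.sfs import fold, poisson_resample
from domfit.wright_fisher import wf_exact_expected_sfs


class TestDriftSelectionTerms:
    def test_additive_outcrossing_reduction(self):
        p = np.linspace(0.05, 0.95, 9)
        M, V = drift_selection_terms(p, s=-0.01, h=0.5, F=0.0, N=500)
        np.testing.assert_allclose(M, -0.01 * p * (1 - p) / 2)
        np.testing.assert_allclose(V, p * (1 - p) / 1000)

    @pytest.mark.parametrize("h", [0.0, 0.3, 1.0])
    def test_full_selfing_is_h_independent(self, h):
        p = np.linspace(0.05, 0.95, 9)
        M, V = drift_selection_terms(p, s=-0.01, h=h, F=1.0, N=500)
        np.testing.assert_allclose(M, -0.01 * p * (1 - p))
        np.testing.assert_allclose(V, p * (1 - p) / 500)

    def test_selfing_mean_term_is_twice_additive(self):
        p = np.linspace(0.01, 0.99, 25)
        M1, _ = drift_selection_terms(p, s=-0.004, h=0.7, F=1.0, N=100)
        M0, _ = drift_selection_terms(p, s=-0.004, h=0.5, F=0.0, N=100)
        np.testing.assert_allclose(M1, 2.0 * M0, rtol=1e-14)

    def test_no_selection_no_directional_change(self):
        M, _ = drift_selection_terms(np.linspace(0.1, 0.9, 5), 0.0, 0.3,
                                     0.2, 100)
        assert np.all(M == 0)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            drift_selection_terms(0.0, -0.01, 0.5, 0.0, 100)


class TestExpectedSFS:
    def test_neutral_closed_form(self):
        e = expected_sfs(DemographicModel(), 0.0, 0.5, 0.0, 11, 1.0)
        expected = 1.0 / np.arange(1, 11)
        np.testing.assert_allclose(e.counts, expected, rtol=0.01)

    def test_linear_in_theta(self):
        a = expected_sfs(DemographicModel(), -2.0, 0.5, 0.0, 10, 1.0)
        b = expected_sfs(DemographicModel(), -2.0, 0.5, 0.0, 10, 3.5)
        np.testing.assert_allclose(b.counts, 3.5 * a.counts, rtol=1e-12)

    def test_matches_wright_fisher_oracle(self):
        wf = wf_exact_expected_sfs(200, -0.01, 0.5, 0.0, 20, 1.0)
        di = expected_sfs(DemographicModel(), -2.0, 0.5, 0.0, 20, 1.0)
        np.testing.assert_allclose(di.counts, wf.counts, rtol=0.02)

    def test_dominance_matters_at_f_zero(self):
        rec = expected_sfs(DemographicModel(), -8.0, 0.05, 0.0, 12, 1.0)
        add = expected_sfs(DemographicModel(), -8.0, 0.5, 0.0, 12, 1.0)
        assert np.max(np.abs(rec.counts / add.counts - 1)) > 0.05

    def test_monotone_suppression_in_gamma(self):
        gammas = [-0.01, -1.0, -5.0, -25.0, -125.0]
        for h in (0.1, 0.5, 0.9):
            prev = None
            for g in gammas:
                e = expected_sfs(DemographicModel(), g, h, 0.0, 10, 1.0,
                                 extrap=False).counts
                if prev is not None:
                    assert np.all(e <= prev + 1e-12)
                prev = e

    def test_continuity_in_h(self):
        # |delta SFS| -> 0 linearly as delta h -> 0, at weak through strong
        # selection
        for g in (-0.5, -5.0, -50.0):
            base = expected_sfs(DemographicModel(), g, 0.3, 0.0, 10, 1.0,
                                extrap=False).counts
            errs = []
            for dh in (0.04, 0.01, 0.0025):
                near = expected_sfs(DemographicModel(), g, 0.3 + dh, 0.0, 10,
                                    1.0, extrap=False).counts
                errs.append(np.max(np.abs(near - base) / base))
            assert errs[2] < errs[1] < errs[0]
            # roughly first-order: quartering dh cuts the change ~4x
            assert errs[1] < 0.5 * errs[0]
            assert errs[2] < 0.5 * errs[1]

    def test_f1_spectra_h_invariant(self):
        a = expected_sfs(DemographicModel(), -4.0, 0.0, 1.0, 12, 1.0)
        b = expected_sfs(DemographicModel(), -4.0, 1.0, 1.0, 12, 1.0)
        np.testing.assert_allclose(a.counts, b.counts, rtol=1e-12)

    def test_positive_gamma_rejected(self):
        with pytest.raises(ValueError):
            expected_sfs(DemographicModel(), 1.0, 0.5, 0.0, 10, 1.0)


class TestSelfingReduction:
    def test_effective_params(self):
        assert selfing_effective_params(-0.001) == (-0.002, 0.5)
        assert selfing_effective_params(0.0) == (0.0, 0.5)

    def test_full_spectrum_equivalence_wf_oracle(self):
        # selfing chain at N=100 individuals vs additive chain at the
        # drift-matched size with s_e = 2s
        selfing = wf_exact_expected_sfs(100, -0.01, 0.1, 1.0, 8, 1.0)
        additive = wf_exact_expected_sfs(50, -0.02, 0.5, 0.0, 8, 1.0)
        np.testing.assert_allclose(selfing.counts, additive.counts,
                                   rtol=1e-3)


class TestAncestralNe:
    def test_identity_scaling(self):
        assert ancestral_ne(4.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_methods_magnitude(self):
        # theta_syn of the selfing species at mu = 7e-9 over 10 Mb
        assert ancestral_ne(41_800.0, 7e-9, 1e7) == pytest.approx(
            149_285.714285, rel=1e-9)

    def test_inverse_proportional_to_length(self):
        assert ancestral_ne(10.0, 1e-8, 2e6) == pytest.approx(
            ancestral_ne(10.0, 1e-8, 1e6) / 2.0)

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            ancestral_ne(10.0, 0.0, 1e6)


class TestFitDemography:
    def test_theta_profile_is_exact_scaling(self):
        unit = fold(expected_sfs(DemographicModel(), 0.0, 0.5, 0.0, 12, 1.0,
                                 pts=200, extrap=False))
        obs = unit.copy()
        obs.counts = 5.0 * obs.counts
        _, theta_hat, _ = fit_demography(obs, family="constant")
        assert theta_hat == pytest.approx(5.0, rel=1e-12)

    def test_no_spurious_size_changes_on_constant_data(self):
        truth = fold(expected_sfs(DemographicModel(), 0.0, 0.5, 0.0, 12,
                                  4000.0))
        obs = poisson_resample(truth, seed=21)
        _, _, ll_const = fit_demography(obs, family="constant")
        _, _, ll_three = fit_demography(obs, family="three_epoch",
                                        n_starts=6, seed=3)
        assert ll_three >= ll_const - 1e-6
        assert ll_three - ll_const < 2.0

    @pytest.mark.parametrize("family,true_epochs", [
        ("two_epoch", ((0.2, 0.3),)),
        ("three_epoch", ((0.2, 0.2), (1.5, 0.05))),
    ])
    def test_bottleneck_predictive_recovery(self, family, true_epochs):
        """Size-change likelihoods of folded spectra carry a theta-vs-size
        ridge, so recovery is judged on the identifiable functional: the
        expected spectrum the fit implies, and a likelihood at least as good
        as the generating parameters'."""
        true_model = DemographicModel(true_epochs)
        truth = fold(expected_sfs(true_model, 0.0, 0.5, 0.0, 22, 4000.0))
        obs = poisson_resample(truth, seed=4)
        model, theta_hat, ll = fit_demography(obs, family=family,
                                              n_starts=8, seed=5)
        implied = fold(expected_sfs(model, 0.0, 0.5, 0.0, 22, theta_hat))
        rel = np.abs(implied.counts / truth.counts - 1.0)
        assert np.max(rel) < 0.08
        from domfit.diffusion import _demog_ll

        p_truth = np.log(np.array(true_epochs).ravel())
        ll_truth = _demog_ll(p_truth, obs, 22, 200, 2e-3)[0]
        assert ll >= ll_truth - 1e-6  # the optimum is at least as good
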