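"""DFE and h-s relationship models and the grid integration."""

import numpy as np
import pytest

from domfit.dfe import (GammaDFE, HSRelationship, discretize_gamma_dfe,
                        expected_nonsyn_sfs, theta_nonsyn_from_syn)
from domfit.diffusion import DemographicModel, expected_sfs
from domfit.errors import InvalidStateError
from domfit.grid import build_coarse, refine


class TestHOfS:
    def test_intercept_is_h_at_zero(self):
        rel = HSRelationship("inverse", theta_intercept=0.37, theta_rate=1e4)
        assert rel.h_of_s(0.0) == pytest.approx(0.37)

    def test_zero_rate_is_constant_model_limit(self):
        rel = HSRelationship("inverse", theta_intercept=0.42, theta_rate=0.0)
        s = -np.logspace(-6, -1, 20)
        np.testing.assert_allclose(rel.h_of_s(s), 0.42)

    def test_hand_evaluation(self):
        rel = HSRelationship("inverse", theta_intercept=0.5, theta_rate=1e4)
        assert rel.h_of_s(-0.001) == pytest.approx(1.0 / 12.0)

    def test_logistic_intercept_and_decay(self):
        rel = HSRelationship("logistic", theta_intercept=0.8,
                             theta_rate=2e3, theta_offset=1.0)
        assert rel.h_of_s(0.0) == pytest.approx(0.8)
        s = -np.logspace(-5, -1, 30)  # |s| increases along the array
        h = rel.h_of_s(s)
        assert np.all(np.diff(h) <= 1e-12)  # h falls as |s| grows

    @pytest.mark.parametrize("form,kw", [
        ("inverse", {}),
        ("logistic", {"theta_offset": 0.5}),
        ("logistic", {"theta_offset": -1.0}),
    ])
    def test_monotone_nonincreasing_in_magnitude(self, form, kw):
        for ti in (0.2, 0.5, 0.99):
            for tr in (0.0, 1e2, 1e4, 1e6):
                rel = HSRelationship(form, theta_intercept=ti,
                                     theta_rate=tr, **kw)
                s = -np.logspace(-7, 0, 50)  # |s| increasing
                h = rel.h_of_s(s)
                assert np.all(np.diff(h) <= 1e-12)
                assert np.all((0 <= h) & (h <= 1))

    def test_negative_rate_rejected_unless_extended(self):
        with pytest.raises(ValueError):
            HSRelationship("inverse", theta_intercept=0.5, theta_rate=-1.0)
        rel = HSRelationship("inverse", theta_intercept=0.5,
                             theta_rate=-100.0, extend=True)
        assert 0.0 <= rel.h_of_s(-0.01) <= 1.0

    def test_positive_s_rejected(self):
        with pytest.raises(ValueError):
            HSRelationship("additive").h_of_s(0.1)

    def test_free_parameter_counts(self):
        assert HSRelationship("additive").n_free_params == 0
        assert HSRelationship("constant", h_const=0.3).n_free_params == 1
        assert HSRelationship("inverse", theta_intercept=0.5).n_free_params == 2
        assert HSRelationship("logistic", theta_intercept=0.5).n_free_params == 3


class TestThetaScaling:
    def test_methods_values(self):
        assert theta_nonsyn_from_syn(131_600.0) == pytest.approx(303_996.0)
        assert theta_nonsyn_from_syn(41_800.0) == pytest.approx(96_558.0)

    def test_unit_multiplier_is_identity(self):
        assert theta_nonsyn_from_syn(123.0, multiplier=1.0) == 123.0


class TestDiscretisation:
    def test_masses_sum_to_deleterious_fraction(self):
        dfe = GammaDFE(0.3, 0.01, p_neutral=0.2)
        g, w = discretize_gamma_dfe(dfe, 1e4, 40)
        assert w.sum() == pytest.approx(0.8, rel=1e-9)
        assert np.all(g < 0)

    def test_bin_means_reproduce_global_mean(self):
        dfe = GammaDFE(0.5, 0.004)
        g, w = discretize_gamma_dfe(dfe, 1e4, 200)
        est = -(g * w).sum() / w.sum() / 1e4
        assert est == pytest.approx(dfe.mean_s, rel=1e-3)


@pytest.fixture(scope="module")
def small_grid():
    """A small refined grid for integration tests (constant demography)."""
    g = build_coarse(DemographicModel(), n=10, N_e=2000.0, F=0.0,
                     gamma_points=30, h_points=12, pts=300, extrap=False)
    return refine(g, 300, 100)


class TestExpectedNonsynSFS:
    def test_pure_neutral_mixture(self, small_grid):
        dfe = GammaDFE(0.3, 0.01, p_neutral=1.0)
        rel = HSRelationship("additive")
        e = expected_nonsyn_sfs(small_grid, dfe, rel, 2000.0, 7.0)
        np.testing.assert_allclose(e.counts, 7.0 * small_grid.neutral,
                                   rtol=1e-12)

    def test_linear_in_theta(self, small_grid):
        dfe = GammaDFE(0.3, 0.002)
        rel = HSRelationship("inverse", theta_intercept=0.5, theta_rate=1e3)
        a = expected_nonsyn_sfs(small_grid, dfe, rel, 2000.0, 1.0)
        b = expected_nonsyn_sfs(small_grid, dfe, rel, 2000.0, 9.0)
        np.testing.assert_allclose(b.counts, 9.0 * a.counts, rtol=1e-12)

    def test_against_refined_quadrature_oracle(self, small_grid):
        """Trapezoid on the grid nodes vs a brute-force Riemann sum over a
        10x denser gamma lattice with directly solved spectra."""
        dfe = GammaDFE(0.4, 0.001)
        rel = HSRelationship("inverse", theta_intercept=0.5, theta_rate=1e4)
        N_e = 2000.0
        e = expected_nonsyn_sfs(small_grid, dfe, rel, N_e, 1.0)

        lg = np.linspace(np.log(N_e), np.log(1e-4), 10 * len(small_grid.gamma_axis))
        gam = -np.exp(lg)
        order = np.argsort(gam)
        gam = gam[order]
        from scipy.stats import gamma as gamma_dist
        pdf = gamma_dist.pdf(-gam / N_e, dfe.shape, scale=dfe.scale) / N_e
        dg = np.diff(gam)
        w = np.zeros(len(gam))
        w[:-1] += 0.5 * dg
        w[1:] += 0.5 * dg
        w *= pdf
        brute = np.zeros(9)
        for g, wi in zip(gam, w):
            if wi == 0:
                continue
            h = rel.h_of_s(g / N_e)
            brute += wi * expected_sfs(DemographicModel(), g, float(h), 0.0,
                                       10, 1.0, pts=300, extrap=False).counts
        brute += gamma_dist.sf(1.0, dfe.shape, scale=dfe.scale) * \
            expected_sfs(DemographicModel(), -N_e, 0.0, 0.0, 10, 1.0,
                         pts=300, extrap=False).counts
        brute += gamma_dist.cdf(1e-4 / N_e, dfe.shape, scale=dfe.scale) * \
            small_grid.neutral
        np.testing.assert_allclose(e.counts, brute, rtol=0.01)

    def test_continuity_in_dfe_parameters(self, small_grid):
        rel = HSRelationship("constant", h_const=0.3)
        base = expected_nonsyn_sfs(small_grid, GammaDFE(0.3, 0.002), rel,
                                   2000.0, 1.0).counts
        near = expected_nonsyn_sfs(small_grid, GammaDFE(0.301, 0.002), rel,
                                   2000.0, 1.0).counts
        far = expected_nonsyn_sfs(small_grid, GammaDFE(0.35, 0.002), rel,
                                  2000.0, 1.0).counts
        assert np.max(np.abs(near - base)) < np.max(np.abs(far - base))
        assert np.max(np.abs(near / base - 1)) < 0.02

    def test_provenance_mismatch_rejected(self, small_grid):
        with pytest.raises(InvalidStateError):
            expected_nonsyn_sfs(small_grid, GammaDFE(0.3, 0.01),
                                HSRelationship("additive"), 2000.0, 1.0,
                                provenance={"n": 22})

    def test_f1_grid_is_relationship_independent(self):
        g = build_coarse(DemographicModel(), n=8, N_e=500.0, F=1.0,
                         gamma_points=20, h_points=8, pts=200, extrap=False)
        g = refine(g, 100, 40)
        dfe = GammaDFE(0.3, 0.003)
        rels = [HSRelationship("additive"),
                HSRelationship("constant", h_const=0.05),
                HSRelationship("inverse", theta_intercept=0.9,
                               theta_rate=1e5),
                HSRelationship("logistic", theta_intercept=0.3,
                               theta_rate=1e3, theta_offset=1.0)]
        base = expected_nonsyn_sfs(g, dfe, rels[0], 500.0, 1.0).counts
        for rel in rels[1:]:
            np.testing.assert_allclose(
                expected_nonsyn_sfs(g, dfe, rel, 500.0, 1.0).counts, base,
                rtol=1e-10)

    def test_additive_equals_constant_half(self, small_grid):
        dfe = GammaDFE(0.25, 0.004)
        a = expected_nonsyn_sfs(small_grid, dfe,
                                HSRelationship("additive"), 2000.0, 1.0)
        c = expected_nonsyn_sfs(small_grid, dfe,
                                HSRelationship("constant", h_const=0.5),
                                2000.0, 1.0)
        np.testing.assert_allclose(a.counts, c.counts, rtol=1e-12)
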