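"""Likelihoods, model fitting, LRT, bootstrap, category comparison."""

import numpy as np
import pytest

from domfit.inference import (LL_SENTINEL, ModelSpec,
                              bootstrap, composite_ll, fit, fit_model_menu,
                              lrt, poisson_ll, z_compare, FitResult)
from domfit.sfs import SpectrumCounts


class TestPoissonLL:
    def test_hand_value(self):
        obs = SpectrumCounts([1.0], 2)
        exp = SpectrumCounts([1.0], 2)
        assert poisson_ll(obs, exp) == pytest.approx(-1.0)

    def test_empty_data(self):
        obs = SpectrumCounts([0.0, 0.0, 0.0], 4)
        exp = SpectrumCounts([2.0, 1.0, 0.5], 4)
        assert poisson_ll(obs, exp) == pytest.approx(-3.5)

    def test_maximised_at_observed(self):
        obs = SpectrumCounts([7.0, 3.0, 1.0], 4)
        lls = []
        scales = np.linspace(0.3, 2.5, 45)
        for c in scales:
            exp = SpectrumCounts(c * obs.counts, 4)
            lls.append(poisson_ll(obs, exp))
        assert scales[int(np.argmax(lls))] == pytest.approx(1.0, abs=0.03)

    def test_zero_expectation_sentinel(self):
        obs = SpectrumCounts([1.0, 0.0, 0.0], 4)
        exp = SpectrumCounts([0.0, 1.0, 1.0], 4)
        assert poisson_ll(obs, exp) == LL_SENTINEL

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            poisson_ll(SpectrumCounts([1.0], 2),
                       SpectrumCounts([1.0, 1.0, 1.0], 4))


class TestLRT:
    def _fr(self, form, ll, k):
        return FitResult(params={}, ll=ll, form=form, n_free_params=k)

    def test_equal_likelihoods(self):
        t = lrt(self._fr("additive", -10.0, 2), self._fr("constant", -10.0, 3))
        assert t.lambda_ == 0.0 and t.p_value == 1.0 and t.df == 1

    def test_hand_chi_square_tail(self):
        t = lrt(self._fr("additive", -12.0, 2), self._fr("constant", -10.0, 3))
        assert t.lambda_ == pytest.approx(4.0)
        assert t.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_df_by_pair(self):
        assert lrt(self._fr("additive", -1.0, 2),
                   self._fr("inverse", -1.0, 4)).df == 2
        assert lrt(self._fr("constant", -1.0, 3),
                   self._fr("inverse", -1.0, 4)).df == 1

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fr("inverse", -1.0, 4), self._fr("constant", -1.0, 3))

    def test_null_distribution_calibrated(self, null_calibration):
        """Additive-truth replicates: df=2 type-I error near nominal and no
        extreme null statistics."""
        res = null_calibration
        assert 0.01 <= res["type1_df2_at_05"] <= 0.12
        assert float(np.max(res["lambda_hs"])) <= 30.0


class TestZCompare:
    def test_identical_estimates(self):
        z, p, pb = z_compare(1.0, 0.5, 1.0, 0.5)
        assert z == 0.0 and p == 1.0 and pb == 1.0

    def test_hand_value(self):
        z, p, _ = z_compare(3.0, 1.0, 1.0, 1.0)
        assert z == pytest.approx(np.sqrt(2.0))
        assert p == pytest.approx(0.1573, abs=2e-4)

    def test_bonferroni(self):
        _, p, pb = z_compare(2.0, 1.0, 0.0, 1.0, n_tests=10)
        assert pb == pytest.approx(min(1.0, 10 * p))
        # capped at 1 once n_tests * p exceeds it
        assert z_compare(1.0, 1.0, 0.0, 1.0, n_tests=100)[2] == 1.0

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            z_compare(1.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def toy_blocks():
    """Small single- and two-population datasets simulated from the model
    family itself (fast, exact-family fitting tests)."""
    from domfit.calibration import make_blocks
    from domfit.wright_fisher import SimulationConfig, forward_simulate

    cfg0 = SimulationConfig().theta_scaled(10.0)
    cfg = cfg0.__class__(**{**vars(cfg0), "seed": 101, "replicates": 1,
                            "engine": "field"})
    from domfit.wright_fisher import expected_spectra_for_config

    expected = expected_spectra_for_config(cfg)
    rep = forward_simulate(cfg)[0]
    return make_blocks(cfg, rep, theta_from="expected", expected=expected), cfg


class TestFit:
    def test_refit_with_same_seed_identical(self, toy_blocks):
        blocks, _ = toy_blocks
        spec = ModelSpec("additive", blocks)
        a = fit(spec, n_starts=3, seed=9)
        b = fit(spec, n_starts=3, seed=9)
        assert a.ll == b.ll and a.params == b.params

    def test_composite_ll_additivity_and_symmetry(self, toy_blocks):
        blocks, _ = toy_blocks
        params = {"shape": 0.3, "mean_s": 5e-3, "theta_intercept": 0.5,
                  "theta_rate": 4.8e4}
        both = composite_ll(ModelSpec("inverse", blocks), params)
        parts = [composite_ll(ModelSpec("inverse", [b]), params)
                 for b in blocks]
        assert both == pytest.approx(sum(parts), abs=1e-9)
        swapped = composite_ll(ModelSpec("inverse", blocks[::-1]), params)
        assert swapped == pytest.approx(both, abs=1e-9)

    def test_ll_nesting_order(self, toy_blocks):
        blocks, _ = toy_blocks
        fits = fit_model_menu(blocks, n_starts=3, seed=4)
        assert fits["inverse"].ll >= fits["constant"].ll - 1e-3
        assert fits["constant"].ll >= fits["additive"].ll - 1e-3

    def test_single_population_mode(self, toy_blocks):
        """Outcrossing-only inference runs end-to-end and orders LLs."""
        blocks, _ = toy_blocks
        fits = fit_model_menu([blocks[0]], n_starts=3, seed=5)
        assert fits["inverse"].ll >= fits["constant"].ll - 1e-3
        assert fits["constant"].ll >= fits["additive"].ll - 1e-3

    def test_per_species_dfe_variant(self, toy_blocks):
        """The robustness variant with an unshared DFE under additivity has
        two more free parameters and can only improve the likelihood."""
        blocks, _ = toy_blocks
        shared = fit(ModelSpec("additive", blocks), n_starts=3, seed=6)
        unshared = fit(ModelSpec("additive", blocks, shared_dfe=False),
                       n_starts=3, seed=6,
                       warm_starts=[{"shape_0": shared.params["shape"],
                                     "mean_s_0": shared.params["mean_s"],
                                     "shape_1": shared.params["shape"],
                                     "mean_s_1": shared.params["mean_s"]}])
        assert unshared.n_free_params == shared.n_free_params + 2
        assert unshared.ll >= shared.ll - 1e-3

    def test_neutral_mixture_dfe_variant(self, toy_blocks):
        """A DFE with a free neutral point mass adds one parameter and can
        only improve the likelihood."""
        blocks, _ = toy_blocks
        plain = fit(ModelSpec("additive", blocks), n_starts=3, seed=14)
        warm = dict(plain.params, p_neutral=0.05)
        mix = fit(ModelSpec("additive", blocks, p_neutral_free=True),
                  n_starts=3, seed=14, warm_starts=[warm])
        assert 0.0 <= mix.params["p_neutral"] <= 1.0
        assert mix.n_free_params == plain.n_free_params + 1
        assert mix.ll >= plain.ll - 1e-3

    def test_constrained_intercept_variant(self, toy_blocks):
        blocks, _ = toy_blocks
        spec = ModelSpec("inverse", blocks, constrain_intercept=0.5)
        r = fit(spec, n_starts=3, seed=8)
        assert r.params["theta_intercept"] == 0.5
        assert spec.n_free_params == 3

    def test_power_recovery_of_dominance_curve(self, power_analysis):
        """Fitted h-s curves recover strong recessivity of s = -0.001
        mutations in most replicates (truth h ~ 0.02)."""
        res = power_analysis
        assert res["n_h_below_0.1"] >= 16


class TestBootstrap:
    def test_identical_seeds_identical_cis(self, toy_blocks):
        blocks, _ = toy_blocks
        spec = ModelSpec("constant", blocks)
        mle = fit(spec, n_starts=3, seed=2)
        a = bootstrap(spec, B=2, seed=3, n_starts=2, mle=mle)
        b = bootstrap(spec, B=2, seed=3, n_starts=2, mle=mle)
        assert a["params"]["h_const"]["ci95"] == b["params"]["h_const"]["ci95"]

    def test_positive_ses_and_coverage_direction(self, toy_blocks):
        blocks, cfg = toy_blocks
        spec = ModelSpec("inverse", blocks)
        mle = fit(spec, n_starts=4, seed=12)
        bs = bootstrap(spec, B=6, seed=13, n_starts=2, mle=mle)
        for nm, st in bs["params"].items():
            assert st["se"] > 0, nm
        lo, hi = bs["params"]["theta_rate"]["ci95"]
        assert lo < mle.params["theta_rate"] < hi or bs["n_failures"] == 0
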