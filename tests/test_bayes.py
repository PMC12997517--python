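"""Bayesian segmented model: identities, ROPE, priors, quadrature oracle, LOO."""

import numpy as np
import pytest

import mfdbp
from mfdbp.bayes import (
    BayesPriors,
    derive_rope_halfwidth,
    fit_bayes_segmented,
    loo_compare,
    posterior_quadrature,
    rope_analysis,
    rope_sensitivity,
)


class TestDrawIdentities:
    def test_post_slope_equals_pre_plus_delta_drawwise(self, bayes_fit):
        assert np.array_equal(
            bayes_fit.post_slope_draws(),
            bayes_fit.pre_slope_draws() + bayes_fit.flat("beta_delta"),
        )

    def test_psi_is_centred_plus_mu_x_drawwise(self, bayes_fit):
        assert np.allclose(
            bayes_fit.psi_draws(), bayes_fit.flat("psi_star") + bayes_fit.mu_x
        )

    def test_mu_x_is_subset_mean_age(self, bayes_fit, analysis_subset):
        assert bayes_fit.mu_x == pytest.approx(analysis_subset.ages.mean())

    def test_shapes_and_convergence(self, bayes_fit):
        assert bayes_fit.draws["psi_star"].shape == (4, 2500)
        assert bayes_fit.converged, f"Rhat: {bayes_fit.rhat}"


class TestAgainstQuadratureOracle:
    """The sampler must agree with the exact grid posterior within MC error."""

    def test_posterior_means(self, bayes_fit, quad_posterior):
        assert bayes_fit.psi_draws().mean() == pytest.approx(
            quad_posterior.psi_mean(), abs=0.05
        )
        assert bayes_fit.pre_slope_draws().mean() == pytest.approx(
            quad_posterior.slope_mean("pre"), abs=1.0
        )
        assert bayes_fit.post_slope_draws().mean() == pytest.approx(
            quad_posterior.slope_mean("post"), abs=1.0
        )

    def test_rope_fractions(self, bayes_fit, quad_posterior):
        res = rope_analysis(bayes_fit, 62.0)
        assert res.fraction_inside_post == pytest.approx(
            quad_posterior.rope_fraction("post", 62.0), abs=0.01
        )
        assert res.fraction_inside_pre == pytest.approx(
            quad_posterior.rope_fraction("pre", 62.0), abs=0.001
        )


class TestPriorRecovery:
    def test_data_free_limit_returns_priors(self, analysis_subset):
        # sigma clamped huge: the likelihood is flat and the posterior must
        # reproduce the prior means/sds within MC error
        fit = fit_bayes_segmented(
            analysis_subset.ages,
            analysis_subset.mfd,
            sigma_fixed=1e8,
            seed=11,
            warmup=4000,
        )
        priors = BayesPriors()
        for name, (m, s) in [
            ("alpha", priors.alpha),
            ("beta1", priors.beta1),
            ("beta_delta", priors.beta_delta),
            ("psi_star", priors.psi_star),
        ]:
            d = fit.flat(name)
            assert d.mean() == pytest.approx(m, abs=0.1 * s)
            assert d.std() == pytest.approx(s, rel=0.1)

    def test_large_n_posterior_approaches_frequentist(self):
        # flat-ish priors + n=500: posterior means within 2% of the
        # segmented least-squares estimates
        cfg = mfdbp.SyntheticConfig(n=500, seed=4, sigma=150.0)
        cohort = mfdbp.generate_cohort(cfg)
        x, y = cohort.ages, cohort.mfd
        freq = mfdbp.fit_segmented(x, y, psi0=6.0)
        # an order of magnitude wider than the likelihood's posterior scale
        # at n=500, but proper enough for the ensemble to mix
        wide = BayesPriors(
            alpha=(1000.0, 1000.0),
            beta1=(-100.0, 150.0),
            beta_delta=(100.0, 150.0),
            psi_star=(0.0, 4.0),
            sigma_scale=1000.0,
        )
        fit = fit_bayes_segmented(x, y, priors=wide, seed=12, warmup=5000)
        assert fit.converged, fit.rhat
        assert fit.psi_draws().mean() == pytest.approx(freq.psi, rel=0.02)
        assert fit.pre_slope_draws().mean() == pytest.approx(freq.beta1, rel=0.02)
        post = fit.post_slope_draws().mean()
        assert post == pytest.approx(freq.beta2, abs=0.02 * abs(freq.beta1))


class TestRope:
    def test_halfwidth_from_paired_diffs(self):
        assert derive_rope_halfwidth([100.0, 200.0], [150.0, 126.0]) == 62.0
        assert derive_rope_halfwidth([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 0.0
        with pytest.raises(ValueError):
            derive_rope_halfwidth([1.0, 2.0], [1.0])

    def test_infinite_halfwidth_captures_everything(self, bayes_fit):
        res = rope_analysis(bayes_fit, np.inf)
        assert res.fraction_inside_pre == 1.0
        assert res.fraction_inside_post == 1.0

    def test_zero_halfwidth_captures_nothing(self, bayes_fit):
        res = rope_analysis(bayes_fit, 0.0)
        assert res.fraction_inside_pre == 0.0
        assert res.fraction_inside_post == 0.0

    def test_fractions_monotone_in_halfwidth(self, bayes_fit):
        widths = [0.0, 10.0, 62.0, 100.0, 300.0, 1000.0]
        pre = [rope_analysis(bayes_fit, w).fraction_inside_pre for w in widths]
        post = [rope_analysis(bayes_fit, w).fraction_inside_post for w in widths]
        assert pre == sorted(pre)
        assert post == sorted(post)

    def test_sensitivity_zero_multiplier_reproduces_base(self, bayes_fit):
        base = rope_analysis(bayes_fit, 62.0)
        table = rope_sensitivity(bayes_fit, 62.0, paired_diff_sd=55.0, multipliers=[0.0])
        assert table.loc[0.0, "fraction_inside_post"] == base.fraction_inside_post

    def test_sensitivity_monotone_across_multipliers(self, bayes_fit):
        table = rope_sensitivity(bayes_fit, 62.0, paired_diff_sd=55.0)
        assert table["fraction_inside_post"].is_monotonic_increasing
        assert table["fraction_inside_pre"].is_monotonic_increasing


class TestLoo:
    def test_model_vs_itself_is_zero(self, bayes_fit):
        diff, se = loo_compare(bayes_fit, bayes_fit)
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_segmented_beats_linear_on_reference_cohort(self, bayes_fit, bayes_linear_fit):
        diff, se = loo_compare(bayes_fit, bayes_linear_fit)
        assert diff > 3.0
        assert se > 0.0

    def test_psis_agrees_with_exact_refit(self, analysis_subset):
        # brute-force exact LOO (35 reduced refits) vs importance sampling
        from mfdbp.bayes import _exact_elpd_point, _loo_pointwise

        fit = fit_bayes_segmented(
            analysis_subset.ages, analysis_subset.mfd, chains=4, draws=1000,
            seed=21, warmup=2000, thin=10,
        )
        psis = _loo_pointwise(fit)
        # exact refits are expensive: check the 5 most influential points
        worst = np.argsort(psis)[:5]
        exact = np.array([_exact_elpd_point(fit, int(i)) for i in worst])
        assert np.abs(psis[worst] - exact).max() < 0.5
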