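import numpy as np
import pytest

from occaban import (
    ParameterVector,
    PriorConfig,
    build_sigma,
    linear_predictor,
    log_likelihood,
    log_prior,
    predict_mu_beta1,
)
from occaban.model_core import (
    OccurrenceModel,
    bernoulli_logit_loglik,
    half_cauchy_logpdf,
    normal_logpdf,
)


def random_params(rng, n_s, design, **extra):
    return ParameterVector(
        beta0=rng.normal(size=n_s),
        slopes=rng.normal(size=(n_s, 5)),
        mu=rng.normal(size=5),
        sigma_beta=np.abs(rng.normal(size=5)) + 0.5,
        rho=0.3,
        eps_reg=rng.normal(size=design.n_regions),
        eps_set=rng.normal(size=design.n_settlements),
        eps_lu=rng.normal(size=design.n_lu_groups),
        sigma_groups=np.abs(rng.normal(size=3)) + 0.5,
        **extra,
    )


def zero_params(n_s, design):
    return ParameterVector(
        beta0=np.zeros(n_s),
        slopes=np.zeros((n_s, 5)),
        mu=np.zeros(5),
        sigma_beta=np.ones(5),
        rho=0.0,
        eps_reg=np.zeros(design.n_regions),
        eps_set=np.zeros(design.n_settlements),
        eps_lu=np.zeros(design.n_lu_groups),
        sigma_groups=np.ones(3),
    )


class TestLinearPredictor:
    def test_all_zero_params_give_half_probability(self, tiny_table, tiny_design):
        params = zero_params(tiny_table.n_species, tiny_design)
        eta = linear_predictor(params, tiny_design)
        np.testing.assert_array_equal(eta, 0.0)

    def test_unit_abandonment_slope(self, tiny_table, tiny_design):
        params = zero_params(tiny_table.n_species, tiny_design)
        params.slopes[:, 0] = 1.0
        eta = linear_predictor(params, tiny_design)
        np.testing.assert_allclose(
            eta, np.tile(tiny_design.aban, (eta.shape[0], 1))
        )

    def test_matches_term_by_term_hand_sum(self, tiny_table, tiny_design):
        rng = np.random.default_rng(31)
        params = random_params(rng, 3, tiny_design)
        params.beta0 = params.beta0[:3]
        eta = linear_predictor(params, tiny_design)
        d = tiny_design
        for i in range(3):
            for j in range(4):  # a handful of plots suffices
                hand = (
                    params.beta0[i]
                    + params.slopes[i, 0] * d.aban[j]
                    + params.slopes[i, 1] * d.temp[j]
                    + params.slopes[i, 2] * d.month[j]
                    + params.slopes[i, 3] * d.lu_dry[j]
                    + params.slopes[i, 4] * d.lu_built[j]
                    + params.eps_reg[d.region_idx[j]]
                    + params.eps_set[d.settlement_idx[j]]
                    + params.eps_lu[d.lu_group_idx[j]]
                )
                assert abs(eta[i, j] - hand) < 1e-12

    def test_shape_mismatch_raises(self, tiny_design):
        params = zero_params(3, tiny_design)
        params.slopes = np.zeros((3, 4))
        with pytest.raises(ValueError, match="slopes"):
            linear_predictor(params, tiny_design)


class TestLogLikelihood:
    def test_single_observation_at_zero_predictor(self):
        assert bernoulli_logit_loglik(
            np.array([[1.0]]), np.array([[0.0]])
        ) == pytest.approx(np.log(0.5), abs=1e-15)

    def test_five_observation_toy_matches_per_term_sum(self):
        rng = np.random.default_rng(5)
        y = np.array([[1, 0, 1, 1, 0]], dtype=float)
        eta = rng.normal(size=(1, 5))
        p = 1 / (1 + np.exp(-eta))
        direct = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bernoulli_logit_loglik(y, eta) == pytest.approx(
            direct, abs=1e-12
        )

    def test_extreme_predictor_stable(self):
        # eta=+20 with y=1: contribution is -log1p(exp(-20)), ~0 but finite
        val = bernoulli_logit_loglik(np.array([[1.0]]), np.array([[20.0]]))
        assert np.isfinite(val)
        assert val == pytest.approx(-np.log1p(np.exp(-20.0)), abs=1e-15)
        assert abs(val) < 1e-8

    def test_likelihood_invariant_to_plot_permutation(
        self, tiny_table, tiny_design
    ):
        from occaban import SurveyTable, build_design

        rng = np.random.default_rng(17)
        params = random_params(rng, tiny_table.n_species, tiny_design)
        base = log_likelihood(params, tiny_table, tiny_design)
        perm = rng.permutation(tiny_table.n_plots)
        shuffled = SurveyTable(
            plots=tiny_table.plots.iloc[perm].reset_index(drop=True),
            occupancy=tiny_table.occupancy.iloc[:, perm],
        )
        design_p = build_design(shuffled)
        assert log_likelihood(params, shuffled, design_p) == pytest.approx(
            base, rel=1e-12
        )


class TestBuildSigma:
    def test_zero_rho_diagonal(self):
        np.testing.assert_array_equal(
            build_sigma(2.0, 3.0, 0.0), np.diag([4.0, 9.0])
        )

    def test_determinant_identity(self):
        # det = s1^2 s2^2 (1 - rho^2) = 4 * 9 * 0.75 = 27
        sigma = build_sigma(2.0, 3.0, 0.5)
        assert np.linalg.det(sigma) == pytest.approx(27.0)
        assert sigma[0, 1] == sigma[1, 0] == pytest.approx(3.0)

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_degenerate_rho_rejected(self, rho):
        with pytest.raises(ValueError):
            build_sigma(1.0, 1.0, rho)


class TestLogPrior:
    def test_rho_outside_support_is_minus_inf(self, tiny_table, tiny_design):
        params = zero_params(tiny_table.n_species, tiny_design)
        params.rho = 1.5
        assert log_prior(params, PriorConfig()) == -np.inf

    def test_negative_scale_is_minus_inf(self, tiny_table, tiny_design):
        params = zero_params(tiny_table.n_species, tiny_design)
        params.sigma_beta = params.sigma_beta.copy()
        params.sigma_beta[0] = -1.0
        assert log_prior(params, PriorConfig()) == -np.inf

    def test_half_cauchy_density_at_zero(self):
        # closed form 2/(pi*gamma*(1+(x/gamma)^2)) at x=0, gamma=5
        assert half_cauchy_logpdf(0.0, 5.0) == pytest.approx(
            np.log(2.0 / (5.0 * np.pi)), abs=1e-14
        )

    def test_normal_100_density_at_zero(self):
        assert normal_logpdf(0.0, 100.0) == pytest.approx(
            -0.5 * np.log(200 * np.pi), abs=1e-14
        )

    def test_finite_on_support(self, tiny_table, tiny_design):
        rng = np.random.default_rng(23)
        params = random_params(rng, tiny_table.n_species, tiny_design)
        lp = log_prior(params, PriorConfig())
        assert np.isfinite(lp)

    def test_m2_collapses_to_m1_when_habitat_terms_vanish(
        self, tiny_table, tiny_design, uniform_habitat
    ):
        """With alpha1 = alphaT1 = 0, the M2 prior equals the M1 prior up to
        the different variance of the slope-mean priors."""
        rng = np.random.default_rng(29)
        prior = PriorConfig()
        a0, at0 = 0.7, -0.4
        params = random_params(rng, tiny_table.n_species, tiny_design)
        params.mu = params.mu.copy()
        params.mu[0], params.mu[1] = a0, at0
        lp_m1 = log_prior(params, prior, model="M1")
        params.alpha = np.array([a0, 0.0, at0, 0.0])
        lp_m2 = log_prior(
            params, prior, model="M2", habitat=uniform_habitat,
            habitat_type="grassland",
        )
        correction = (
            2 * normal_logpdf(0.0, prior.normal_var_alpha)
            + normal_logpdf(a0, prior.normal_var_alpha)
            + normal_logpdf(at0, prior.normal_var_alpha)
            - normal_logpdf(a0, prior.normal_var_fixed)
            - normal_logpdf(at0, prior.normal_var_fixed)
        )
        assert lp_m2 - lp_m1 == pytest.approx(correction, abs=1e-10)

    def test_m3_shrinkage_concentrates_alphas_at_zero(
        self, tiny_table, tiny_design, uniform_habitat
    ):
        rng = np.random.default_rng(37)
        params = random_params(rng, tiny_table.n_species, tiny_design)
        params.alpha0, params.alphaT0 = 0.0, 0.0
        params.tau = params.tauT = 1e-3
        params.alphaT_vec = np.zeros(11)
        params.alpha_vec = np.zeros(11)
        lp_zero = log_prior(
            params, PriorConfig(), model="M3", habitat=uniform_habitat
        )
        params.alpha_vec = np.full(11, 0.5)
        lp_away = log_prior(
            params, PriorConfig(), model="M3", habitat=uniform_habitat
        )
        assert lp_zero - lp_away > 1e4  # tiny tau forces alphas to zero


class TestPredictMuBeta1:
    def test_zero_habitat_vector_returns_intercept_draws(self):
        draws = {
            "alpha0": np.array([0.1, -0.2, 0.3]),
            "alpha_vec": np.arange(33, dtype=float).reshape(3, 11),
        }
        np.testing.assert_array_equal(
            predict_mu_beta1(np.zeros(11), draws), draws["alpha0"]
        )

    def test_one_hot_grassland(self):
        rng = np.random.default_rng(3)
        draws = {
            "alpha0": rng.normal(size=4),
            "alpha_vec": rng.normal(size=(4, 11)),
        }
        h = np.zeros(11)
        h[3] = 1  # grassland position in the canonical order
        np.testing.assert_allclose(
            predict_mu_beta1(h, draws),
            draws["alpha0"] + draws["alpha_vec"][:, 3],
        )

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(41)
        draws = {
            "alpha0": rng.normal(size=50),
            "alpha_vec": rng.normal(size=(50, 11)),
        }
        h = rng.integers(0, 2, size=11).astype(float)
        expected = np.array(
            [draws["alpha0"][d] + np.dot(draws["alpha_vec"][d], h)
             for d in range(50)]
        )
        np.testing.assert_allclose(
            predict_mu_beta1(h, draws), expected, atol=1e-12
        )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="11"):
            predict_mu_beta1(np.zeros(10), {"alpha0": np.zeros(1),
                                            "alpha_vec": np.zeros((1, 11))})


class TestUnconstrainedModel:
    @pytest.mark.parametrize("variant", ["M1", "M2", "M3"])
    def test_gradient_matches_finite_differences(
        self, variant, tiny_table, tiny_design, uniform_habitat
    ):
        kw = {}
        if variant == "M2":
            kw = dict(habitat=uniform_habitat, habitat_type="grassland")
        elif variant == "M3":
            kw = dict(habitat=uniform_habitat)
        model = OccurrenceModel(
            variant, tiny_table.occupancy_matrix(), tiny_design,
            temper=0.8, **kw,
        )
        rng = np.random.default_rng(11)
        z = 0.4 * rng.standard_normal(model.dim)
        _, grad = model.logp_and_grad(z)
        eps = 1e-6
        for i in rng.choice(model.dim, size=25, replace=False):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (model.logp_and_grad(zp)[0] - model.logp_and_grad(zm)[0]) / (
                2 * eps
            )
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_unpacked_params_reproduce_constrained_likelihood(
        self, tiny_table, tiny_design
    ):
        """The sampler's parameterization and the constrained-scale surface
        compute the same likelihood."""
        model = OccurrenceModel(
            "M1", tiny_table.occupancy_matrix(), tiny_design
        )
        rng = np.random.default_rng(13)
        z = 0.5 * rng.standard_normal(model.dim)
        p = model.unpack(z)
        params = ParameterVector(
            beta0=p["beta0"], slopes=p["slopes"], mu=p["mu"],
            sigma_beta=p["sigma_beta"], rho=p["rho"], eps_reg=p["eps_reg"],
            eps_set=p["eps_set"], eps_lu=p["eps_lu"],
            sigma_groups=p["sigma_groups"],
        )
        assert model.loglik(z) == pytest.approx(
            log_likelihood(params, tiny_table, tiny_design), rel=1e-12
        )
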