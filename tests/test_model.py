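"""Joint posterior: likelihood terms, gradients, parameterizations,
imputation, and design builders."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import expit, logit

from wildmeat.model import (
    JointPosterior,
    ModelData,
    Priors,
    bernoulli_loglik,
    beta_frequency_loglik,
    gamma_quantity_loglik,
    sim_design,
    survey_design,
)
from wildmeat.survey import ingest_tables


class TestLikelihoodTerms:
    def test_null_predictor_single_recall(self):
        assert bernoulli_loglik([1], [0.0]) == pytest.approx(np.log(0.5))
        assert bernoulli_loglik([0], [0.0]) == pytest.approx(np.log(0.5))

    def test_duration_term_raises_probability(self):
        # a positive per-day increment makes longer recalls more likely to
        # record an event
        days = np.array([1.0, 7.0, 30.0, 365.0])
        pi = expit(-2.0 + 0.05 * days)
        assert np.all(np.diff(pi) > 0)

    def test_full_monitoring_removes_latent_noise(self):
        # at mdays = 365 the latent sd is 0 and the observation density is
        # the Beta at expit(phibar), whatever tau is
        f = np.array([0.21])
        phibar = np.array([-1.1])
        mdays = np.array([365.0])
        base = float(
            stats.beta.logpdf(f, expit(phibar) * 12, (1 - expit(phibar)) * 12)[0]
        )
        for tau in (-3.0, 0.0, 5.0):
            ll = beta_frequency_loglik(
                f, phibar, mdays, np.array([tau]), sigma=0.01, kappa=12.0
            )
            assert ll - float(stats.norm.logpdf(tau)) == pytest.approx(base)

    def test_single_day_monitoring_has_maximal_noise(self):
        # Sigma = sigma * (365 - 1): shifting tau by t moves the latent
        # logit frequency by 364 * sigma * t
        sigma, tau = 0.003, 1.0
        f = np.array([0.3])
        phibar = np.array([-0.8])
        ll_ref = beta_frequency_loglik(
            f, phibar + 364 * sigma * tau, np.array([365.0]), np.array([0.0]),
            sigma, 15.0,
        )
        ll = beta_frequency_loglik(
            f, phibar, np.array([1.0]), np.array([tau]), sigma, 15.0
        )
        # same Beta density; only the standard-normal tau term differs
        assert ll - stats.norm.logpdf(tau) == pytest.approx(
            ll_ref - stats.norm.logpdf(0.0)
        )

    def test_monitoring_beyond_a_year_rejected(self):
        with pytest.raises(ValueError):
            beta_frequency_loglik(
                np.array([0.1]), np.array([0.0]), np.array([400.0]),
                np.array([0.0]), 0.01, 10.0,
            )

    def test_beta_mean_is_phi_by_quadrature(self):
        phi, kappa = 0.3, 10.0
        mean, _ = quad(
            lambda x: x * stats.beta.pdf(x, phi * kappa, (1 - phi) * kappa), 0, 1
        )
        assert mean == pytest.approx(phi, abs=1e-8)

    def test_gamma_mean_is_mu_by_quadrature(self):
        mu, theta = 0.4, 5.0
        mean, _ = quad(
            lambda x: x * stats.gamma.pdf(x, a=mu * theta, scale=1 / theta),
            0, np.inf,
        )
        assert mean == pytest.approx(mu, abs=1e-8)

    def test_gamma_variance_vanishes_at_large_rate(self):
        mu, theta = 0.4, 1e6
        assert stats.gamma.var(a=mu * theta, scale=1 / theta) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_quantity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_quantity_loglik(
                np.array([0.0]), np.array([2.0]), np.array([0.0]), 2.0
            )


class TestParameterizations:
    def test_centred_noncentred_density_identity(self):
        # same joint distribution: densities differ exactly by the
        # change-of-variables Jacobian sum(log Sigma)
        rng = np.random.default_rng(5)
        n = 15
        f = rng.uniform(0.05, 0.9, n)
        phibar = rng.normal(-1, 0.5, n)
        mdays = rng.integers(2, 360, n).astype(float)
        sigma, kappa = 0.004, 20.0
        Sigma = sigma * (365 - mdays)
        for _ in range(5):
            tau = rng.normal(size=n)
            u = phibar + Sigma * tau
            nc = beta_frequency_loglik(f, phibar, mdays, tau, sigma, kappa)
            c = beta_frequency_loglik(
                f, phibar, mdays, u, sigma, kappa, parameterization="centred"
            )
            assert c == pytest.approx(nc - np.sum(np.log(Sigma)), rel=1e-12)

    def test_centred_rejects_degenerate_sd(self):
        with pytest.raises(ValueError):
            beta_frequency_loglik(
                np.array([0.1]), np.array([0.0]), np.array([365.0]),
                np.array([0.0]), 0.01, 10.0, parameterization="centred",
            )


class TestJointPosterior:
    def test_gradient_matches_finite_differences(self, tiny_model_data):
        model = JointPosterior(tiny_model_data)
        rng = np.random.default_rng(17)
        theta = model.initial_position(rng, jitter=0.1)
        logp, grad = model.logp_and_grad(theta)
        assert np.isfinite(logp)
        h = 1e-6
        for i in rng.choice(model.n_params, size=40, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (model.log_posterior(tp) - model.log_posterior(tm)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_finite_at_initial_position(self, tiny_model_data):
        model = JointPosterior(tiny_model_data)
        assert np.isfinite(model.log_posterior(model.initial_position()))

    def test_removing_a_data_block_removes_its_term(self, tiny_model_data):
        d = tiny_model_data
        full = JointPosterior(d)
        no_freq = ModelData(
            y_c=d.y_c, X_c=d.X_c, names_c=d.names_c, loc_c=d.loc_c,
            q=d.q, X_q=d.X_q, names_q=d.names_q, ame=d.ame,
            imp_idx=d.imp_idx, n_imp=d.n_imp, ame_name=d.ame_name,
            D=d.D, ame_prior_mean=d.ame_prior_mean,
        )
        reduced = JointPosterior(no_freq)
        terms_full = full.term_logps(full.initial_position())
        terms_reduced = reduced.term_logps(reduced.initial_position())
        assert set(terms_full) == {"consumption", "frequency", "quantity"}
        assert set(terms_reduced) == {"consumption", "quantity"}
        assert terms_reduced["consumption"] == pytest.approx(
            terms_full["consumption"]
        )

    def test_imputed_ame_collapses_to_nu_as_psi_vanishes(self, tiny_model_data):
        model = JointPosterior(tiny_model_data)
        theta = model.initial_position()
        nu = 5.0
        theta[model.slices["nu"]] = nu
        theta[model.slices["log_psi"]] = np.log(1e-5)
        # the prior dominates: the gradient pushes every imputed AME hard
        # towards nu, and is ~0 exactly at nu
        theta[model.slices["u_imp"]] = np.log(nu)
        g_at_nu = model.logp_and_grad(theta)[1][model.slices["u_imp"]]
        theta2 = theta.copy()
        theta2[model.slices["u_imp"]] = np.log(nu * 1.2)
        g_above = model.logp_and_grad(theta2)[1][model.slices["u_imp"]]
        assert np.all(np.abs(g_at_nu) < 1e-3 * np.abs(g_above))
        assert np.all(g_above < 0)

    def test_missing_covariate_raises(self, tiny_model_data):
        d = tiny_model_data
        bad = ModelData(
            y_c=d.y_c, X_c=d.X_c, names_c=d.names_c, loc_c=d.loc_c,
            q=d.q, X_q=d.X_q, names_q=d.names_q,
            ame=np.where(np.arange(len(d.ame)) == 0, np.nan, d.ame),
            imp_idx=np.full(len(d.ame), -1), n_imp=0,
            D=d.D,
        )
        with pytest.raises(ValueError, match="missing AME"):
            JointPosterior(bad)


class TestSurveyDesign:
    def test_builds_and_evaluates(self, survey_schema_tables):
        t = survey_schema_tables
        tables = ingest_tables(
            t["studies"], t["locations"], t["households"], t["recalls"]
        )
        data = survey_design(tables)
        names = set(data.names_c)
        assert {"alpha0", "alpha_days", "alpha_hpd[village]", "alpha_hdi",
                "alpha_ed[secondary_or_higher]", "alpha_period2"} <= names
        assert [b.name for b in data.re_c] == ["study", "household"]
        assert data.loc_c is not None and data.loc_f is not None
        model = JointPosterior(data)
        rng = np.random.default_rng(3)
        theta = model.initial_position(rng, 0.05)
        logp, grad = model.logp_and_grad(theta)
        assert np.isfinite(logp)
        h = 1e-6
        for i in rng.choice(model.n_params, size=25, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (model.log_posterior(tp) - model.log_posterior(tm)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_scalers_recorded_for_prediction(self, survey_schema_tables):
        t = survey_schema_tables
        tables = ingest_tables(
            t["studies"], t["locations"], t["households"], t["recalls"]
        )
        data = survey_design(tables)
        assert set(data.meta["scalers"]) == {"hpd", "rem", "hdi", "fci"}

    def test_boundary_frequencies_clamped_and_counted(self, survey_schema_tables):
        t = survey_schema_tables
        households = t["households"].copy()
        households.loc[households.index[0], "frequency"] = 0.0
        households.loc[households.index[1], "frequency"] = 1.0
        tables = ingest_tables(
            t["studies"], t["locations"], households, t["recalls"]
        )
        data = survey_design(tables)
        assert data.n_clamped == 2
        assert data.f.min() >= 1e-4 and data.f.max() <= 1 - 1e-4
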