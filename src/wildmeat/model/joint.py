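"""Joint log-posterior of the three-part consumption model, with gradients.

The three likelihood terms:

* consumption: ``consumed_r ~ Bernoulli(pi_r)`` with
  ``logit(pi_r) = X_c alpha + (random intercepts) + eps[location] ``,
  where the recall-duration column of ``X_c`` captures the increased chance
  of recording at least one event over a longer recall window;
* frequency: ``frequency_h ~ Beta(phi_h kappa, (1 - phi_h) kappa)`` with
  ``logit(phi_h) = phibar_h + Sigma_h tau_h`` (non-centred), where
  ``phibar_h = X_f beta + eps[location]`` and the observation sd
  ``Sigma_h = sigma (365 - mdays_h)`` vanishes for a household monitored
  every day of the year;
* quantity: ``q_r / AME_r ~ Gamma(mu_r theta, theta)`` (shape-rate) with
  ``log(mu_r) = X_q gamma + gamma_ame AME_r + (random intercepts)``, AME
  imputed where missing via ``AME_m ~ Normal(nu, psi)`` constrained
  positive.

The latent spatial effect ``eps = LX eta`` is non-centred over the
Cholesky factor of the exponentiated-quadratic kernel (see
:mod:`wildmeat.model.gp`).  All gradients are analytic; the Cholesky
factor is differentiated exactly for the kernel hyperparameters.

Positive parameters (sigma, kappa, theta, zeta, rho, psi, random-effect
sds, imputed AMEs) are sampled on the log scale with the Jacobian included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln

from .design import ModelData
from .gp import DEFAULT_JITTER

__all__ = [
    "Priors",
    "JointPosterior",
    "bernoulli_loglik",
    "beta_frequency_loglik",
    "gamma_quantity_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults; every entry is overridable.

    ``coef_sd``: Normal(0, coef_sd) on logit/log-scale coefficients.
    ``sd_scale``: half-Normal(0, sd_scale) on sds (GP zeta, sigma, psi,
    random-intercept sds).  ``rate_shape``/``rate_rate``: Gamma prior on the
    Beta sample size kappa and the Gamma rate theta.  ``nu_sd``: sd of the
    Normal prior on the mean imputed AME (centred at the observed mean).
    ``rho_scale``: half-Normal scale for the GP inverse length scale; the
    default lets the kernel decay anywhere from flat to fully within the
    shortest inter-site distances (5 / median off-diagonal distance).
    """

    coef_sd: float = 2.5
    sd_scale: float = 2.0
    rate_shape: float = 2.0
    rate_rate: float = 0.1
    nu_sd: float = 2.0
    rho_scale: float | None = None


# ---------------------------------------------------------------------------
# Stand-alone likelihood terms (used directly and as the spec surface)
# ---------------------------------------------------------------------------


def bernoulli_loglik(consumed: np.ndarray, logit_pi: np.ndarray) -> float:
    """Sum of Bernoulli log-masses at the given logit-scale predictor."""
    consumed = np.asarray(consumed, dtype=float)
    z = np.asarray(logit_pi, dtype=float)
    return float(np.sum(consumed * z) - np.sum(np.logaddexp(0.0, z)))


def beta_frequency_loglik(
    frequency: np.ndarray,
    phibar: np.ndarray,
    mdays: np.ndarray,
    tau: np.ndarray,
    sigma: float,
    kappa: float,
    parameterization: str = "noncentred",
) -> float:
    """Frequency term: Beta observation density plus the latent-noise density.

    In the non-centred form ``tau`` holds standard-normal variates and the
    latent logit frequency is ``phibar + sigma (365 - mdays) tau``; the
    returned value includes the standard-normal log-density of ``tau``.  In
    the centred form ``tau`` holds the latent logit frequency itself and the
    Normal(phibar, Sigma) log-density is included.  The two forms describe
    the same joint distribution up to the change-of-variables Jacobian
    ``sum(log Sigma)``.
    """
    mdays = np.asarray(mdays, dtype=float)
    if np.any(mdays > 365):
        raise ValueError("monitored days cannot exceed 365")
    f = np.asarray(frequency, dtype=float)
    tau = np.asarray(tau, dtype=float)
    Sigma = sigma * (365.0 - mdays)
    if parameterization == "noncentred":
        u = phibar + Sigma * tau
        latent = -0.5 * np.sum(tau**2) - 0.5 * len(tau) * _LOG_2PI
    elif parameterization == "centred":
        if np.any(Sigma <= 0):
            raise ValueError("centred form undefined at Sigma = 0")
        u = tau
        latent = float(
            -0.5 * np.sum(((u - phibar) / Sigma) ** 2)
            - np.sum(np.log(Sigma))
            - 0.5 * len(tau) * _LOG_2PI
        )
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    phi = expit(u)
    a, b = phi * kappa, (1.0 - phi) * kappa
    obs = np.sum(
        gammaln(kappa)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(f)
        + (b - 1.0) * np.log1p(-f)
    )
    return float(obs + latent)


def gamma_quantity_loglik(
    quantity_kg: np.ndarray,
    ame: np.ndarray,
    log_mu: np.ndarray,
    theta: float,
) -> float:
    """Quantity term: Gamma(mu theta, theta) density of per-AME daily kg."""
    q = np.asarray(quantity_kg, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantity term requires strictly positive quantities")
    x = q / np.asarray(ame, dtype=float)
    mu = np.exp(np.asarray(log_mu, dtype=float))
    a = mu * theta
    return float(
        np.sum(a * np.log(theta) - gammaln(a) + (a - 1.0) * np.log(x) - theta * x)
    )


# ---------------------------------------------------------------------------
# Joint posterior
# ---------------------------------------------------------------------------


class JointPosterior:
    """Differentiable unnormalized log-posterior over a packed parameter
    vector, assembled from :class:`~wildmeat.model.design.ModelData`."""

    def __init__(self, data: ModelData, priors: Priors = Priors()):
        self.data = data
        self.priors = priors
        self.gp_c = data.loc_c is not None
        self.gp_f = data.has_frequency and data.loc_f is not None
        if (self.gp_c or self.gp_f) and data.D is None:
            raise ValueError("a GP term requires the distance matrix D")
        self.n_loc = len(data.D) if data.D is not None else 0
        if data.D is not None:
            self._D2 = data.D**2
            off = data.D[np.triu_indices_from(data.D, k=1)]
            med = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
            self._median_distance = med
            n = len(data.D)
            self._diag_idx = np.diag_indices(n)
            self._tril_half = np.tril(np.ones((n, n)))
            self._tril_half[self._diag_idx] = 0.5
            from scipy.linalg import get_lapack_funcs

            self._trtrs = get_lapack_funcs("trtrs", (data.D,))
        self.rho_scale = (
            priors.rho_scale
            if priors.rho_scale is not None
            else (5.0 / self._median_distance if data.D is not None else 1.0)
        )

        if data.has_frequency:
            self._umdays = 365.0 - np.asarray(data.mdays, dtype=float)
            self._logf = np.log(data.f)
            self._log1mf = np.log1p(-data.f)
        if data.has_quantity:
            self._miss_rows = np.flatnonzero(data.imp_idx >= 0)
            self._imp_map = data.imp_idx[self._miss_rows]
            self._imp_row_counts = np.bincount(
                self._imp_map, minlength=data.n_imp
            ).astype(float)
            if np.any(np.isnan(data.ame) & (data.imp_idx < 0)):
                raise ValueError("missing AME without an imputation index")

        blocks: list[tuple[str, int]] = [("alpha", data.X_c.shape[1])]
        for blk in data.re_c:
            blocks += [(f"re_c:{blk.name}", blk.n_levels), (f"re_c:{blk.name}:log_sd", 1)]
        if self.gp_c:
            blocks += [("eta_c", self.n_loc), ("log_zeta_c", 1), ("log_rho_c", 1)]
        if data.has_frequency:
            blocks += [("beta", data.X_f.shape[1])]
            if self.gp_f:
                blocks += [("eta_f", self.n_loc), ("log_zeta_f", 1), ("log_rho_f", 1)]
            blocks += [("tau", len(data.f)), ("log_sigma", 1), ("log_kappa", 1)]
        if data.has_quantity:
            blocks += [("gamma", data.X_q.shape[1]), ("gamma_ame", 1)]
            for blk in data.re_q:
                blocks += [
                    (f"re_q:{blk.name}", blk.n_levels),
                    (f"re_q:{blk.name}:log_sd", 1),
                ]
            blocks += [("log_theta", 1)]
            if data.n_imp:
                blocks += [("u_imp", data.n_imp), ("nu", 1), ("log_psi", 1)]

        self.slices: dict[str, slice] = {}
        offset = 0
        for name, size in blocks:
            self.slices[name] = slice(offset, offset + size)
            offset += size
        self.n_params = offset

    # -- naming -------------------------------------------------------------

    def parameter_names(self) -> list:
        """One name per scalar in the packed vector."""
        names = []
        for block, sl in self.slices.items():
            size = sl.stop - sl.start
            if block == "alpha":
                names += list(self.data.names_c)
            elif block == "beta":
                names += list(self.data.names_f)
            elif block == "gamma":
                names += list(self.data.names_q)
            elif block == "gamma_ame":
                names.append(self.data.ame_name)
            elif size == 1:
                names.append(block)
            else:
                names += [f"{block}[{i}]" for i in range(size)]
        return names

    # -- initial position ----------------------------------------------------

    def initial_position(self, rng=None, jitter: float = 0.05) -> np.ndarray:
        theta = np.zeros(self.n_params)
        start = {
            "log_sigma": np.log(0.01),
            "log_kappa": np.log(10.0),
            "log_theta": np.log(5.0),
            "nu": self.data.ame_prior_mean,
            "log_psi": np.log(1.0),
        }
        if self.gp_c:
            start["log_zeta_c"] = np.log(0.5)
            start["log_rho_c"] = np.log(1.0 / self._median_distance)
        if self.gp_f:
            start["log_zeta_f"] = np.log(0.5)
            start["log_rho_f"] = np.log(1.0 / self._median_distance)
        for name, value in start.items():
            if name in self.slices:
                theta[self.slices[name]] = value
        if "u_imp" in self.slices:
            theta[self.slices["u_imp"]] = np.log(self.data.ame_prior_mean)
        if rng is not None and jitter > 0:
            theta = theta + jitter * rng.standard_normal(self.n_params)
        return theta

    def initial_inv_mass(self) -> np.ndarray:
        """Diagonal inverse-mass starting guess from rough Fisher curvature.

        Latent standard-normal blocks are unit scale; fixed-effect
        coefficients get the inverse of a generalized-linear curvature bound
        (prior precision plus a design-weighted information term), which
        mainly matters for columns far from unit scale such as the raw
        recall-duration covariate.  The warmup windows refine this estimate.
        """
        inv_mass = np.ones(self.n_params)
        d, pr = self.data, self.priors

        def glm_scale(X, weight):
            info = weight * (X**2).sum(axis=0) + 1.0 / pr.coef_sd**2
            return 1.0 / info

        inv_mass[self.slices["alpha"]] = glm_scale(d.X_c, 0.25)
        if d.has_frequency:
            inv_mass[self.slices["beta"]] = glm_scale(d.X_f, 1.0)
        if d.has_quantity:
            inv_mass[self.slices["gamma"]] = glm_scale(d.X_q, 1.0)
            ame_obs = np.nan_to_num(d.ame, nan=d.ame_prior_mean)
            inv_mass[self.slices["gamma_ame"]] = 1.0 / (
                (ame_obs**2).sum() + 1.0 / pr.coef_sd**2
            )
        for name in ("log_sigma", "log_kappa", "log_theta", "log_psi",
                     "log_zeta_c", "log_rho_c", "log_zeta_f", "log_rho_f"):
            if name in self.slices:
                inv_mass[self.slices[name]] = 0.1
        if "u_imp" in self.slices:
            inv_mass[self.slices["u_imp"]] = 0.1
        return inv_mass

    # -- evaluation ----------------------------------------------------------

    def _gp_eval(self, theta, prefix):
        """Kernel pieces for one GP block: (eta, zeta, rho, K, L, eps)."""
        eta = theta[self.slices[f"eta_{prefix}"]]
        zeta = float(np.exp(theta[self.slices[f"log_zeta_{prefix}"]][0]))
        rho = float(np.exp(theta[self.slices[f"log_rho_{prefix}"]][0]))
        K = np.exp(-(rho**2) * self._D2)
        X = zeta**2 * K
        X[self._diag_idx] += DEFAULT_JITTER
        L = np.linalg.cholesky(X)
        return eta, zeta, rho, K, L, L @ eta

    def _gp_grads(self, g, geps, eta, zeta, rho, K, L, prefix):
        # For eps = L @ eta, d(logp)/d(kernel hyperparameter) contracts the
        # Cholesky differential dL = L Phi(L^-1 dX L^-T) against geps and
        # eta; written as sum(S * dX) with S = L^-T W L^-1 and
        # W = tril(a eta^T, halved diagonal), a = L^T geps, the two
        # triangular solves are shared between zeta and rho.
        a = L.T @ geps
        g[self.slices[f"eta_{prefix}"]] += a
        W = np.outer(a, eta)
        W *= self._tril_half
        T1, _ = self._trtrs(L, W, lower=1, trans=1)
        S, _ = self._trtrs(L, np.ascontiguousarray(T1.T), lower=1, trans=1)
        S = S.T
        SK = S * K
        g[self.slices[f"log_zeta_{prefix}"]] += 2.0 * zeta**2 * float(SK.sum())
        g[self.slices[f"log_rho_{prefix}"]] += (
            -2.0 * rho**2 * zeta**2 * float((SK * self._D2).sum())
        )
        # standard-normal prior on eta; half-normal on zeta, rho
        g[self.slices[f"eta_{prefix}"]] -= eta
        g[self.slices[f"log_zeta_{prefix}"]] += (
            -(zeta**2) / self.priors.sd_scale**2 + 1.0
        )
        g[self.slices[f"log_rho_{prefix}"]] += -(rho**2) / self.rho_scale**2 + 1.0

    def _gp_priors_logp(self, eta, zeta, rho):
        return (
            -0.5 * float(eta @ eta)
            - zeta**2 / (2.0 * self.priors.sd_scale**2)
            + np.log(zeta)
            - rho**2 / (2.0 * self.rho_scale**2)
            + np.log(rho)
        )

    def log_posterior(self, theta: np.ndarray) -> float:
        return self.logp_and_grad(theta)[0]

    def term_logps(self, theta: np.ndarray) -> dict:
        """Likelihood terms evaluated separately (additivity checks)."""
        d = self.data
        terms = {}
        z = self._consumption_predictor(theta)
        terms["consumption"] = bernoulli_loglik(d.y_c, z)
        if d.has_frequency:
            phibar = d.X_f @ theta[self.slices["beta"]]
            if self.gp_f:
                phibar = phibar + self._gp_eval(theta, "f")[5][d.loc_f]
            terms["frequency"] = beta_frequency_loglik(
                d.f,
                phibar,
                d.mdays,
                theta[self.slices["tau"]],
                float(np.exp(theta[self.slices["log_sigma"]][0])),
                float(np.exp(theta[self.slices["log_kappa"]][0])),
            )
        if d.has_quantity:
            ame, lmu = self._quantity_predictor(theta)
            terms["quantity"] = gamma_quantity_loglik(
                d.q, ame, lmu, float(np.exp(theta[self.slices["log_theta"]][0]))
            )
        return terms

    def _consumption_predictor(self, theta):
        d = self.data
        z = d.X_c @ theta[self.slices["alpha"]]
        for blk in d.re_c:
            raw = theta[self.slices[f"re_c:{blk.name}"]]
            sd = np.exp(theta[self.slices[f"re_c:{blk.name}:log_sd"]][0])
            z = z + sd * raw[blk.idx]
        if self.gp_c:
            z = z + self._gp_eval(theta, "c")[5][d.loc_c]
        return z

    def _quantity_predictor(self, theta):
        d = self.data
        ame = d.ame.copy()
        if d.n_imp:
            ame[self._miss_rows] = np.exp(theta[self.slices["u_imp"]])[self._imp_map]
        lmu = d.X_q @ theta[self.slices["gamma"]] + theta[self.slices["gamma_ame"]][0] * ame
        for blk in d.re_q:
            raw = theta[self.slices[f"re_q:{blk.name}"]]
            sd = np.exp(theta[self.slices[f"re_q:{blk.name}:log_sd"]][0])
            lmu = lmu + sd * raw[blk.idx]
        return ame, lmu

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        # Overflow at extreme positions yields a -inf posterior (rejected by
        # the sampler); the intermediate warnings carry no information.
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                return self._logp_and_grad(theta)
            except np.linalg.LinAlgError:
                # kernel numerically singular at extreme (zeta, rho):
                # reject the position
                return -np.inf, np.zeros_like(theta)

    def _logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d, pr = self.data, self.priors
        sl = self.slices
        g = np.zeros_like(theta)
        logp = 0.0

        # ----- consumption ---------------------------------------------------
        alpha = theta[sl["alpha"]]
        z = d.X_c @ alpha
        re_info = []
        for blk in d.re_c:
            raw = theta[sl[f"re_c:{blk.name}"]]
            sd = float(np.exp(theta[sl[f"re_c:{blk.name}:log_sd"]][0]))
            z = z + sd * raw[blk.idx]
            re_info.append((f"re_c:{blk.name}", blk, raw, sd))
        if self.gp_c:
            eta_c, zeta_c, rho_c, K_c, L_c, eps_c = self._gp_eval(theta, "c")
            z = z + eps_c[d.loc_c]

        logp += np.sum(d.y_c * z) - np.sum(np.logaddexp(0.0, z))
        dz = d.y_c - expit(z)
        g[sl["alpha"]] += d.X_c.T @ dz
        for name, blk, raw, sd in re_info:
            gsum = np.bincount(blk.idx, weights=dz, minlength=blk.n_levels)
            g[sl[name]] += sd * gsum
            g[sl[name + ":log_sd"]] += sd * float(gsum @ raw)
        if self.gp_c:
            geps = np.bincount(d.loc_c, weights=dz, minlength=self.n_loc)
            self._gp_grads(g, geps, eta_c, zeta_c, rho_c, K_c, L_c, "c")
            logp += self._gp_priors_logp(eta_c, zeta_c, rho_c)

        # ----- frequency -----------------------------------------------------
        if d.has_frequency:
            beta = theta[sl["beta"]]
            tau = theta[sl["tau"]]
            sigma = float(np.exp(theta[sl["log_sigma"]][0]))
            kappa = float(np.exp(theta[sl["log_kappa"]][0]))
            phibar = d.X_f @ beta
            if self.gp_f:
                eta_f, zeta_f, rho_f, K_f, L_f, eps_f = self._gp_eval(theta, "f")
                phibar = phibar + eps_f[d.loc_f]
            Sig = sigma * self._umdays
            u = phibar + Sig * tau
            phi = np.clip(expit(u), 1e-12, 1.0 - 1e-12)
            a, b = phi * kappa, (1.0 - phi) * kappa
            logp += np.sum(
                gammaln(kappa)
                - gammaln(a)
                - gammaln(b)
                + (a - 1.0) * self._logf
                + (b - 1.0) * self._log1mf
            )
            dldphi = kappa * (digamma(b) - digamma(a) + self._logf - self._log1mf)
            dldu = dldphi * phi * (1.0 - phi)
            g[sl["beta"]] += d.X_f.T @ dldu
            g[sl["tau"]] += dldu * Sig - tau  # includes the N(0,1) prior
            logp += -0.5 * float(tau @ tau)
            g[sl["log_sigma"]] += sigma * float((dldu * tau) @ self._umdays)
            dldkappa = np.sum(
                digamma(kappa)
                - phi * digamma(a)
                - (1.0 - phi) * digamma(b)
                + phi * self._logf
                + (1.0 - phi) * self._log1mf
            )
            g[sl["log_kappa"]] += kappa * dldkappa
            if self.gp_f:
                geps_f = np.bincount(d.loc_f, weights=dldu, minlength=self.n_loc)
                self._gp_grads(g, geps_f, eta_f, zeta_f, rho_f, K_f, L_f, "f")
                logp += self._gp_priors_logp(eta_f, zeta_f, rho_f)
            # half-normal prior on sigma, Gamma prior on kappa (log scale)
            logp += -(sigma**2) / (2.0 * pr.sd_scale**2) + np.log(sigma)
            g[sl["log_sigma"]] += -(sigma**2) / pr.sd_scale**2 + 1.0
            t_kap = theta[sl["log_kappa"]][0]
            logp += pr.rate_shape * t_kap - pr.rate_rate * kappa
            g[sl["log_kappa"]] += pr.rate_shape - pr.rate_rate * kappa

        # ----- quantity ------------------------------------------------------
        if d.has_quantity:
            gam = theta[sl["gamma"]]
            gam_ame = float(theta[sl["gamma_ame"]][0])
            th = float(np.exp(theta[sl["log_theta"]][0]))
            ame = d.ame.copy()
            if d.n_imp:
                u_imp = theta[sl["u_imp"]]
                A = np.exp(u_imp)
                ame[self._miss_rows] = A[self._imp_map]
            lmu = d.X_q @ gam + gam_ame * ame
            re_q_info = []
            for blk in d.re_q:
                raw = theta[sl[f"re_q:{blk.name}"]]
                sd = float(np.exp(theta[sl[f"re_q:{blk.name}:log_sd"]][0]))
                lmu = lmu + sd * raw[blk.idx]
                re_q_info.append((f"re_q:{blk.name}", blk, raw, sd))
            mu = np.exp(lmu)
            x = d.q / ame
            logx = np.log(x)
            aq = mu * th
            lth = theta[sl["log_theta"]][0]
            logp += np.sum(
                aq * lth - gammaln(aq) + (aq - 1.0) * logx - th * x
            )
            dldaq = lth - digamma(aq) + logx
            dldlmu = dldaq * th * mu
            g[sl["gamma"]] += d.X_q.T @ dldlmu
            g[sl["gamma_ame"]] += float(dldlmu @ ame)
            for name, blk, raw, sd in re_q_info:
                gsum = np.bincount(blk.idx, weights=dldlmu, minlength=blk.n_levels)
                g[sl[name]] += sd * gsum - raw
                logp += -0.5 * float(raw @ raw)
                g[sl[name + ":log_sd"]] += (
                    sd * float(gsum @ raw) - sd**2 / pr.sd_scale**2 + 1.0
                )
                logp += -(sd**2) / (2.0 * pr.sd_scale**2) + np.log(sd)
            g[sl["log_theta"]] += th * float(np.sum(mu * dldaq + mu - x))
            logp += pr.rate_shape * lth - pr.rate_rate * th
            g[sl["log_theta"]] += pr.rate_shape - pr.rate_rate * th

            if d.n_imp:
                nu = float(theta[sl["nu"]][0])
                psi = float(np.exp(theta[sl["log_psi"]][0]))
                dldx = (aq - 1.0) / x - th
                dame = dldx * (-d.q / ame**2) + dldlmu * gam_ame
                gu = np.bincount(
                    self._imp_map,
                    weights=dame[self._miss_rows] * A[self._imp_map],
                    minlength=d.n_imp,
                )
                # observed datum is q, not q/AME: the change of variables
                # contributes -log(AME) per imputed row (without it the
                # density would improve without bound as AME grows)
                logp += -float(np.sum(np.log(ame[self._miss_rows])))
                gu -= self._imp_row_counts
                resid = (A - nu) / psi
                logp += (
                    -0.5 * float(resid @ resid)
                    - d.n_imp * np.log(psi)
                    + float(np.sum(u_imp))
                )
                gu += (-(A - nu) / psi**2) * A + 1.0
                g[sl["u_imp"]] += gu
                g[sl["nu"]] += float(np.sum(A - nu)) / psi**2
                g[sl["log_psi"]] += float(resid @ resid) - d.n_imp
                # hyperpriors: nu ~ Normal(observed mean, nu_sd), psi half-normal
                logp += -((nu - d.ame_prior_mean) ** 2) / (2.0 * pr.nu_sd**2)
                g[sl["nu"]] += -(nu - d.ame_prior_mean) / pr.nu_sd**2
                logp += -(psi**2) / (2.0 * pr.sd_scale**2) + np.log(psi)
                g[sl["log_psi"]] += -(psi**2) / pr.sd_scale**2 + 1.0

        # ----- coefficient and random-effect priors --------------------------
        for name in ("alpha", "beta", "gamma", "gamma_ame"):
            if name in sl and (name != "beta" or d.has_frequency):
                v = theta[sl[name]]
                logp += -0.5 * float(v @ v) / pr.coef_sd**2
                g[sl[name]] += -v / pr.coef_sd**2
        for name, blk, raw, sd in re_info:
            logp += -0.5 * float(raw @ raw)
            g[sl[name]] += -raw
            logp += -(sd**2) / (2.0 * pr.sd_scale**2) + np.log(sd)
            g[sl[name + ":log_sd"]] += -(sd**2) / pr.sd_scale**2 + 1.0

        if not np.isfinite(logp):
            return -np.inf, g
        return float(logp), g
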