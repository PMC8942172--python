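"""Likelihood, priors and parameterization for the occurrence model variants.

Three variants of a multi-species random-slope logistic GLMM are supported:

M1
    Species-level model: logit(p_ij) = beta0_i + beta1_i*ABAN_j +
    beta2_i*TEMP_j + beta3_i*MONTH_j + beta4_i*I(dry) + beta5_i*I(built)
    + eps_reg(j) + eps_set(j) + eps_lu(j).  The abandonment and temperature
    slopes (beta1_i, beta2_i) share a bivariate-normal prior with means
    (mu_b1, mu_b2), SDs (sigma_b1, sigma_b2) and correlation rho; the
    confounder slopes beta3..5 have independent normal priors.
M2
    Habitat hierarchy for one habitat type k: the slope means become
    mu_b1i = alpha0 + alpha1*H_ik and mu_b2i = alphaT0 + alphaT1*H_ik,
    with vague N(0, 1000) priors on the alphas.  Fit separately per
    habitat type.
M3
    Ridge multivariate habitat model: mu_b1i = alpha0 + sum_k alpha_k*H_ik
    over all 11 habitat types, with Gaussian shrinkage alpha_k ~ N(0, tau^2)
    and a half-Cauchy(5) hyperprior on the shared scale tau; the same
    structure is applied to the temperature slope means (configurable).

Hyperpriors: beta0_i and the free slope means ~ N(0, 100); all SDs
~ half-Cauchy(5); rho ~ Uniform(-1, 1).

The sampler operates on an unconstrained vector with a non-centered
parameterization of every random effect; this module supplies the joint
log-density and its analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data_model import DesignInputs, HabitatMatrix, SurveyTable

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Configuration and parameter containers
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Prior hyperparameters; defaults are the model's stated vague priors."""

    normal_var_fixed: float = 100.0   # beta0_i and free slope means
    normal_var_alpha: float = 1000.0  # habitat-model alphas
    half_cauchy_scale: float = 5.0    # all standard deviations
    ridge_temperature: bool = True    # M3: shrink the temperature block too

    def __post_init__(self) -> None:
        if self.normal_var_fixed <= 0 or self.normal_var_alpha <= 0:
            raise ValueError("prior variances must be positive")
        if self.half_cauchy_scale <= 0:
            raise ValueError("half-Cauchy scale must be positive")


@dataclass
class ParameterVector:
    """Constrained-scale parameters of the occurrence model.

    Shapes: ``beta0`` (n_species,), ``slopes`` (n_species, 5) in
    (aban, temp, month, dry, built) column order, ``mu`` (5,),
    ``sigma_beta`` (5,), ``sigma_groups`` (3,) = (sigma_r, sigma_s, sigma_l).
    Habitat-model coefficients are optional and variant-specific.
    """

    beta0: np.ndarray
    slopes: np.ndarray
    mu: np.ndarray
    sigma_beta: np.ndarray
    rho: float
    eps_reg: np.ndarray
    eps_set: np.ndarray
    eps_lu: np.ndarray
    sigma_groups: np.ndarray
    alpha: np.ndarray | None = None       # M2: (a0, a1, aT0, aT1)
    alpha0: float | None = None           # M3 intercepts
    alpha_vec: np.ndarray | None = None   # M3: 11 abandonment coefficients
    alphaT0: float | None = None
    alphaT_vec: np.ndarray | None = None
    tau: float | None = None              # M3 shrinkage scales
    tauT: float | None = None

    def __post_init__(self) -> None:
        # out-of-support values (|rho| >= 1, non-positive scales) are allowed
        # to exist so log_prior can evaluate them to -inf
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.sigma_beta = np.asarray(self.sigma_beta, dtype=float)
        self.sigma_groups = np.asarray(self.sigma_groups, dtype=float)


# ---------------------------------------------------------------------------
# Elementary densities
# ---------------------------------------------------------------------------

def normal_logpdf(x, var: float):
    return -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * np.asarray(x) ** 2 / var


def half_cauchy_logpdf(x, scale: float):
    """log density 2 / (pi * scale * (1 + (x/scale)^2)) on x >= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0,
        -np.inf,
        np.log(2.0) - np.log(np.pi * scale) - np.log1p((x / scale) ** 2),
    )
    return out


def build_sigma(sigma1: float, sigma2: float, rho: float) -> np.ndarray:
    """2x2 slope covariance from SDs and the correlation coefficient."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("standard deviations must be positive")
    c = rho * sigma1 * sigma2
    return np.array([[sigma1**2, c], [c, sigma2**2]])


# ---------------------------------------------------------------------------
# Likelihood on the constrained scale
# ---------------------------------------------------------------------------

def linear_predictor(params: ParameterVector, design: DesignInputs) -> np.ndarray:
    """logit(p_ij) as a species x plot matrix."""
    x = design.x
    n_s = params.beta0.shape[0]
    if params.slopes.shape != (n_s, 5):
        raise ValueError(
            f"slopes must be (n_species, 5), got {params.slopes.shape}"
        )
    eps = (
        params.eps_reg[design.region_idx]
        + params.eps_set[design.settlement_idx]
        + params.eps_lu[design.lu_group_idx]
    )
    return params.beta0[:, None] + params.slopes @ x.T + eps[None, :]


def bernoulli_logit_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """sum_ij log Bernoulli(y_ij | logit^-1(eta_ij)), numerically stable.

    Uses y*eta - softplus(eta) with the log1p-exp form of softplus, so
    predictors of magnitude ~tens stay finite and exact.
    """
    sp = np.logaddexp(0.0, eta)  # softplus
    return float(np.sum(y * eta - sp))


def log_likelihood(
    params: ParameterVector, data: SurveyTable, design: DesignInputs
) -> float:
    eta = linear_predictor(params, design)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return bernoulli_logit_loglik(data.occupancy_matrix(), eta)


def log_prior(
    params: ParameterVector,
    prior: PriorConfig,
    model: str = "M1",
    habitat: HabitatMatrix | None = None,
    habitat_type: str | None = None,
) -> float:
    """Joint log prior density on the constrained scale (no Jacobians).

    Returns -inf outside the support (|rho| >= 1 or non-positive scale).
    """
    if not -1.0 < params.rho < 1.0:
        return -np.inf
    if (params.sigma_beta <= 0).any() or (params.sigma_groups <= 0).any():
        return -np.inf
    lp = 0.0
    vf = prior.normal_var_fixed
    lp += normal_logpdf(params.beta0, vf).sum()
    lp += half_cauchy_logpdf(params.sigma_beta, prior.half_cauchy_scale).sum()
    lp += half_cauchy_logpdf(params.sigma_groups, prior.half_cauchy_scale).sum()
    lp += -np.log(2.0)  # rho ~ Uniform(-1, 1)
    # group effects
    for eps, sd in zip(
        (params.eps_reg, params.eps_set, params.eps_lu), params.sigma_groups
    ):
        lp += normal_logpdf(eps, sd**2).sum()
    # slope-mean structure per variant
    n_s = params.beta0.shape[0]
    if model == "M1":
        lp += normal_logpdf(params.mu[:2], vf).sum()
        m1 = np.full(n_s, params.mu[0])
        m2 = np.full(n_s, params.mu[1])
    elif model == "M2":
        if params.alpha is None or habitat is None or habitat_type is None:
            raise ValueError("M2 requires alpha, habitat and habitat_type")
        lp += normal_logpdf(params.alpha, prior.normal_var_alpha).sum()
        h = habitat.H[habitat_type].to_numpy(dtype=float)
        a0, a1, at0, at1 = params.alpha
        m1 = a0 + a1 * h
        m2 = at0 + at1 * h
    elif model == "M3":
        if params.alpha_vec is None or habitat is None:
            raise ValueError("M3 requires alpha_vec and habitat")
        H = habitat.matrix()
        lp += normal_logpdf(params.alpha0, prior.normal_var_alpha)
        lp += normal_logpdf(params.alpha_vec, params.tau**2).sum()
        lp += half_cauchy_logpdf(params.tau, prior.half_cauchy_scale)
        m1 = params.alpha0 + H @ params.alpha_vec
        if prior.ridge_temperature:
            lp += normal_logpdf(params.alphaT0, prior.normal_var_alpha)
            lp += normal_logpdf(params.alphaT_vec, params.tauT**2).sum()
            lp += half_cauchy_logpdf(params.tauT, prior.half_cauchy_scale)
            m2 = params.alphaT0 + H @ params.alphaT_vec
        else:
            lp += normal_logpdf(params.mu[1], vf)
            m2 = np.full(n_s, params.mu[1])
    else:
        raise ValueError(f"unknown model variant {model!r}")
    lp += normal_logpdf(params.mu[2:], vf).sum()
    # bivariate normal on (beta1, beta2)
    s1, s2 = params.sigma_beta[0], params.sigma_beta[1]
    r = params.rho
    d1 = (params.slopes[:, 0] - m1) / s1
    d2 = (params.slopes[:, 1] - m2) / s2
    quad = (d1**2 - 2 * r * d1 * d2 + d2**2) / (1 - r**2)
    lp += float(
        np.sum(
            -np.log(2 * np.pi)
            - np.log(s1 * s2)
            - 0.5 * np.log(1 - r**2)
            - 0.5 * quad
        )
    )
    # independent normals on beta3..5
    for k in range(2, 5):
        lp += normal_logpdf(
            params.slopes[:, k] - params.mu[k], params.sigma_beta[k] ** 2
        ).sum()
    return float(lp)


def predict_mu_beta1(habitat_row: np.ndarray, alpha_draws: dict) -> np.ndarray:
    """Per-draw predicted abandonment-slope mean for a species from its
    habitat-preference vector, under the ridge (M3) model.

    ``alpha_draws`` must contain flattened draws ``"alpha0"`` (n_draws,) and
    ``"alpha_vec"`` (n_draws, 11).
    """
    h = np.asarray(habitat_row, dtype=float)
    if h.shape != (11,):
        raise ValueError(f"habitat vector must have length 11, got {h.shape}")
    return alpha_draws["alpha0"] + alpha_draws["alpha_vec"] @ h


# ---------------------------------------------------------------------------
# Unconstrained posterior with analytic gradient (sampler backend)
# ---------------------------------------------------------------------------

class OccurrenceModel:
    """Joint log-density of one model variant on an unconstrained vector.

    All random effects and species slopes are non-centered; scales are
    log-transformed and rho is tanh-transformed, with the Jacobians included
    so the density is the correct posterior in the unconstrained space.
    ``temper`` scales the likelihood only (used for WBIC sampling).
    """

    def __init__(
        self,
        variant: str,
        y: np.ndarray,
        design: DesignInputs,
        prior: PriorConfig | None = None,
        habitat: HabitatMatrix | None = None,
        habitat_type: str | None = None,
        temper: float = 1.0,
    ):
        if variant not in ("M1", "M2", "M3"):
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        self.y = np.asarray(y, dtype=float)
        self.design = design
        self.prior = prior or PriorConfig()
        self.temper = float(temper)
        self.n_s, self.n_p = self.y.shape
        if design.n_plots != self.n_p:
            raise ValueError("design/occupancy plot dimension mismatch")
        self.x = design.x
        if variant == "M2":
            if habitat is None or habitat_type is None:
                raise ValueError("M2 requires habitat matrix and habitat_type")
            self.h = habitat.H[habitat_type].to_numpy(dtype=float)
        elif variant == "M3":
            if habitat is None:
                raise ValueError("M3 requires habitat matrix")
            self.H = habitat.matrix()
        self._build_layout()

    # -- layout ------------------------------------------------------------
    def _build_layout(self) -> None:
        n_s, d = self.n_s, self.design
        blocks: list[tuple[str, int]] = [
            ("z_b0", n_s),
            ("z_sl", n_s * 5),
            ("z_lsb", 5),
            ("z_rho", 1),
            ("z_reg", d.n_regions),
            ("z_set", d.n_settlements),
            ("z_lu", d.n_lu_groups),
            ("z_lsg", 3),
            ("z_mu345", 3),
        ]
        if self.variant == "M1":
            blocks.append(("z_mu12", 2))
        elif self.variant == "M2":
            blocks.append(("z_alpha", 4))
        else:
            blocks.append(("z_alpha0", 1))
            blocks.append(("z_avec", 11))
            blocks.append(("z_ltau", 1))
            if self.prior.ridge_temperature:
                blocks.append(("z_alphaT0", 1))
                blocks.append(("z_avecT", 11))
                blocks.append(("z_ltauT", 1))
            else:
                blocks.append(("z_mu2", 1))
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in blocks:
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off

    def _get(self, z: np.ndarray, name: str) -> np.ndarray:
        return z[self.slices[name]]

    # -- constrained reconstruction ---------------------------------------
    def unpack(self, z: np.ndarray) -> dict:
        """Constrained parameters from an unconstrained vector."""
        pr = self.prior
        s0 = np.sqrt(pr.normal_var_fixed)
        sa = np.sqrt(pr.normal_var_alpha)
        beta0 = s0 * self._get(z, "z_b0")
        sigma_beta = np.exp(self._get(z, "z_lsb"))
        # clamp away from +/-1 so sqrt(1-rho^2) and the Jacobian stay finite
        rho = float(np.clip(np.tanh(self._get(z, "z_rho")[0]), -1 + 1e-12, 1 - 1e-12))
        sigma_groups = np.exp(self._get(z, "z_lsg"))
        mu = np.zeros(5)
        mu[2:] = s0 * self._get(z, "z_mu345")
        out: dict = {}
        if self.variant == "M1":
            mu[:2] = s0 * self._get(z, "z_mu12")
            m1 = np.full(self.n_s, mu[0])
            m2 = np.full(self.n_s, mu[1])
        elif self.variant == "M2":
            alpha = sa * self._get(z, "z_alpha")
            out["alpha"] = alpha
            m1 = alpha[0] + alpha[1] * self.h
            m2 = alpha[2] + alpha[3] * self.h
        else:
            alpha0 = sa * self._get(z, "z_alpha0")[0]
            tau = np.exp(self._get(z, "z_ltau")[0])
            alpha_vec = tau * self._get(z, "z_avec")
            out.update(alpha0=alpha0, tau=tau, alpha_vec=alpha_vec)
            m1 = alpha0 + self.H @ alpha_vec
            if pr.ridge_temperature:
                alphaT0 = sa * self._get(z, "z_alphaT0")[0]
                tauT = np.exp(self._get(z, "z_ltauT")[0])
                alphaT_vec = tauT * self._get(z, "z_avecT")
                out.update(alphaT0=alphaT0, tauT=tauT, alphaT_vec=alphaT_vec)
                m2 = alphaT0 + self.H @ alphaT_vec
            else:
                mu[1] = s0 * self._get(z, "z_mu2")[0]
                m2 = np.full(self.n_s, mu[1])
        z_sl = self._get(z, "z_sl").reshape(self.n_s, 5)
        s1, s2 = sigma_beta[0], sigma_beta[1]
        rt = np.sqrt(1.0 - rho**2)
        slopes = np.empty((self.n_s, 5))
        slopes[:, 0] = m1 + s1 * z_sl[:, 0]
        slopes[:, 1] = m2 + s2 * (rho * z_sl[:, 0] + rt * z_sl[:, 1])
        for k in range(2, 5):
            slopes[:, k] = mu[k] + sigma_beta[k] * z_sl[:, k]
        eps_reg = sigma_groups[0] * self._get(z, "z_reg")
        eps_set = sigma_groups[1] * self._get(z, "z_set")
        eps_lu = sigma_groups[2] * self._get(z, "z_lu")
        out.update(
            beta0=beta0,
            slopes=slopes,
            mu=mu,
            sigma_beta=sigma_beta,
            rho=rho,
            sigma_groups=sigma_groups,
            eps_reg=eps_reg,
            eps_set=eps_set,
            eps_lu=eps_lu,
            slope_means=(m1, m2),
        )
        return out

    def eta(self, params: dict) -> np.ndarray:
        d = self.design
        eps = (
            params["eps_reg"][d.region_idx]
            + params["eps_set"][d.settlement_idx]
            + params["eps_lu"][d.lu_group_idx]
        )
        return params["beta0"][:, None] + params["slopes"] @ self.x.T + eps

    def loglik(self, z: np.ndarray) -> float:
        """Untempered Bernoulli log-likelihood at an unconstrained point."""
        return bernoulli_logit_loglik(self.y, self.eta(self.unpack(z)))

    # -- joint density and gradient ---------------------------------------
    def logp_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.prior
        hc = pr.half_cauchy_scale
        s0 = np.sqrt(pr.normal_var_fixed)
        sa = np.sqrt(pr.normal_var_alpha)
        p = self.unpack(z)
        grad = np.zeros_like(z)
        d = self.design

        eta = self.eta(p)
        # likelihood and residual (tempered)
        sp = np.logaddexp(0.0, eta)
        ll = np.sum(self.y * eta - sp)
        r = (self.y - expit(eta)) * self.temper  # n_s x n_p

        logp = self.temper * ll

        # ---- standard-normal prior on every non-centered block ----------
        transformed = {"z_lsb", "z_lsg", "z_ltau", "z_ltauT", "z_rho"}
        for name in self.slices:
            if name in transformed:
                continue  # transformed scales and rho handled separately
            zi = self._get(z, name)
            logp += -0.5 * float(zi @ zi) - 0.5 * len(zi) * _LOG_2PI
            grad[self.slices[name]] -= zi

        # ---- likelihood chain rules --------------------------------------
        sigma_beta = p["sigma_beta"]
        rho = p["rho"]
        rt = np.sqrt(1.0 - rho**2)
        s1, s2 = sigma_beta[0], sigma_beta[1]
        z_sl = self._get(z, "z_sl").reshape(self.n_s, 5)

        g_beta0 = r.sum(axis=1)                      # d ll / d beta0_i
        grad[self.slices["z_b0"]] += s0 * g_beta0
        G = r @ self.x                               # n_s x 5, d ll / d slopes
        g_zsl = np.empty_like(z_sl)
        g_zsl[:, 0] = G[:, 0] * s1 + G[:, 1] * s2 * rho
        g_zsl[:, 1] = G[:, 1] * s2 * rt
        for k in range(2, 5):
            g_zsl[:, k] = G[:, k] * sigma_beta[k]
        grad[self.slices["z_sl"]] += g_zsl.ravel()

        # slope means
        g_m1 = G[:, 0]
        g_m2 = G[:, 1]
        if self.variant == "M1":
            grad[self.slices["z_mu12"]] += s0 * np.array(
                [g_m1.sum(), g_m2.sum()]
            )
        elif self.variant == "M2":
            grad[self.slices["z_alpha"]] += sa * np.array(
                [
                    g_m1.sum(),
                    float(g_m1 @ self.h),
                    g_m2.sum(),
                    float(g_m2 @ self.h),
                ]
            )
        else:
            tau = p["tau"]
            grad[self.slices["z_alpha0"]] += sa * g_m1.sum()
            g_avec = self.H.T @ g_m1                 # d ll / d alpha_k
            grad[self.slices["z_avec"]] += tau * g_avec
            # tau chain: alpha_k = tau * z_k; plus half-Cauchy and Jacobian
            z_avec = self._get(z, "z_avec")
            g_tau = float(g_avec @ z_avec)
            logp += (
                np.log(2.0) - np.log(np.pi * hc) - np.log1p((tau / hc) ** 2)
            ) + np.log(tau)
            grad[self.slices["z_ltau"]] += (
                tau * g_tau - 2.0 * tau**2 / (hc**2 + tau**2) + 1.0
            )
            if pr.ridge_temperature:
                tauT = p["tauT"]
                grad[self.slices["z_alphaT0"]] += sa * g_m2.sum()
                g_avecT = self.H.T @ g_m2
                grad[self.slices["z_avecT"]] += tauT * g_avecT
                z_avecT = self._get(z, "z_avecT")
                g_tauT = float(g_avecT @ z_avecT)
                logp += (
                    np.log(2.0)
                    - np.log(np.pi * hc)
                    - np.log1p((tauT / hc) ** 2)
                ) + np.log(tauT)
                grad[self.slices["z_ltauT"]] += (
                    tauT * g_tauT - 2.0 * tauT**2 / (hc**2 + tauT**2) + 1.0
                )
            else:
                grad[self.slices["z_mu2"]] += s0 * g_m2.sum()
        grad[self.slices["z_mu345"]] += s0 * G[:, 2:].sum(axis=0)

        # sigma_beta chains: likelihood part
        g_sb = np.empty(5)
        g_sb[0] = float(G[:, 0] @ z_sl[:, 0])
        w = rho * z_sl[:, 0] + rt * z_sl[:, 1]
        g_sb[1] = float(G[:, 1] @ w)
        for k in range(2, 5):
            g_sb[k] = float(G[:, k] @ z_sl[:, k])
        # rho chain (likelihood through slopes[:,1])
        g_rho = s2 * float(G[:, 1] @ (z_sl[:, 0] - (rho / rt) * z_sl[:, 1]))

        # group effects
        s_col = r.sum(axis=0)                        # per-plot residual sum
        sg = p["sigma_groups"]
        g_sg = np.empty(3)
        for i, (name, idx, n_g) in enumerate(
            (
                ("z_reg", d.region_idx, d.n_regions),
                ("z_set", d.settlement_idx, d.n_settlements),
                ("z_lu", d.lu_group_idx, d.n_lu_groups),
            )
        ):
            per_group = np.bincount(idx, weights=s_col, minlength=n_g)
            grad[self.slices[name]] += sg[i] * per_group
            g_sg[i] = float(per_group @ self._get(z, name))

        # ---- transformed scales: half-Cauchy prior + log Jacobian --------
        for sl_name, sig, g_lik in (
            ("z_lsb", sigma_beta, g_sb),
            ("z_lsg", sg, g_sg),
        ):
            logp += float(
                np.sum(
                    np.log(2.0)
                    - np.log(np.pi * hc)
                    - np.log1p((sig / hc) ** 2)
                    + np.log(sig)
                )
            )
            grad[self.slices[sl_name]] += (
                sig * g_lik - 2.0 * sig**2 / (hc**2 + sig**2) + 1.0
            )

        # ---- rho: Uniform(-1,1) prior + tanh Jacobian --------------------
        logp += -np.log(2.0) + np.log1p(-rho**2)
        grad[self.slices["z_rho"]] += g_rho * (1.0 - rho**2) - 2.0 * rho

        return float(logp), grad

    def init_z(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        return jitter * rng.standard_normal(self.dim)
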