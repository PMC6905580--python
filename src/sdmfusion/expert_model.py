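"""Confidence-weighted Beta regression with a Gaussian random intercept per
expert (the E model).

Each elicited habitat-suitability probability y_ij (expert j, site i) is
modelled as

    y_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi),
    logit(mu_ij) = x_i' beta + u_j,      u_j ~ Normal(0, sigma^2),

in the mean-precision parameterization (phi > 0 is the Beta precision).  The
expert's stated confidence enters as a prior case weight w_ij multiplying the
record's log-density.  The random intercepts are integrated out (marginal
maximum likelihood) with adaptive Gauss-Hermite quadrature: per expert the
integrand is re-centred at the conditional mode and rescaled by its
curvature, so a modest node count is accurate even for skewed panels.
Standard errors come from the inverse observed information of the marginal
log-likelihood; fusion consumes only the fixed effects beta_e and s_e.

All per-expert computations are batched over the panel (segment sums via
``bincount``), so fits on thousands of records take well under a second.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, logsumexp, polygamma, psi

from .survey_model import TERMS, FittedModel, design_matrix, _check_rank

__all__ = [
    "squeeze_probabilities",
    "fit_weighted_beta",
    "residual_df_expert",
]

_MU_EPS = 1e-10
_P_FIXED = len(TERMS)


def squeeze_probabilities(p: np.ndarray | float, n: int) -> np.ndarray | float:
    """Compress probabilities off the boundary: y' = (p (n-1) + 0.5) / n.

    Experts may state 0 or 1, where the Beta log-density is infinite; the
    transform pulls every value strictly inside (0, 1) toward 0.5 by an
    amount vanishing in the sample size n.  p = 0.5 is a fixed point.
    """
    if np.isscalar(p):
        return (p * (n - 1) + 0.5) / n
    return (np.asarray(p, dtype=float) * (n - 1) + 0.5) / n


class _Panel:
    """Stacked elicitation records with batched per-expert marginals."""

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, g_idx: np.ndarray, n_groups: int):
        self.X = X
        self.y = y
        self.w = w
        self.g = g_idx
        self.G = n_groups
        self.ystar = np.log(y) - np.log1p(-y)
        self.log_y = np.log(y)
        self.log_1my = np.log1p(-y)
        self.u_hat = np.zeros(n_groups)  # warm start across optimizer steps

    def _group_loglik(self, eta_u: np.ndarray, phi: float) -> np.ndarray:
        """Weighted Beta loglik summed per expert; eta_u has one linear
        predictor per record (random intercept already added)."""
        mu = np.clip(expit(eta_u), _MU_EPS, 1.0 - _MU_EPS)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = self.w * ((a - 1.0) * self.log_y + (b - 1.0) * self.log_1my - betaln(a, b))
        return np.bincount(self.g, ll, minlength=self.G)

    def _group_derivs(self, eta_u: np.ndarray, phi: float) -> tuple[np.ndarray, np.ndarray]:
        """d/du and d2/du2 of the weighted loglik, summed per expert."""
        mu = np.clip(expit(eta_u), _MU_EPS, 1.0 - _MU_EPS)
        mustar = psi(mu * phi) - psi((1.0 - mu) * phi)
        dmu = mu * (1.0 - mu)
        resid = self.ystar - mustar
        d1 = np.bincount(self.g, self.w * phi * resid * dmu, minlength=self.G)
        trig = polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)
        d2 = np.bincount(
            self.g,
            self.w * phi * dmu * (-phi * trig * dmu + resid * (1.0 - 2.0 * mu)),
            minlength=self.G,
        )
        return d1, d2

    def _score_parts(self, eta_u: np.ndarray, phi: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-record score contributions: d(log pdf)/d(eta) and d/d(phi)."""
        mu = np.clip(expit(eta_u), _MU_EPS, 1.0 - _MU_EPS)
        mustar = psi(mu * phi) - psi((1.0 - mu) * phi)
        d_eta = self.w * phi * (self.ystar - mustar) * mu * (1.0 - mu)
        d_phi = self.w * (
            mu * self.log_y
            + (1.0 - mu) * self.log_1my
            - mu * psi(mu * phi)
            - (1.0 - mu) * psi((1.0 - mu) * phi)
            + psi(phi)
        )
        return d_eta, d_phi

    def marginal_loglik(
        self, beta: np.ndarray, phi: float, sigma: float,
        nodes: np.ndarray, log_gh_w: np.ndarray,
        want_grad: bool = False,
    ):
        """Sum over experts of log ∫ exp(weighted loglik(u)) N(u;0,sigma^2) du.

        With ``want_grad`` also returns the gradient w.r.t. (beta, log phi,
        log sigma) by Fisher's identity: the posterior expectation of the
        joint score, evaluated with the posterior weights the adapted
        quadrature itself provides.
        """
        eta = self.X @ beta
        if sigma < 1e-8:
            ll = float(self._group_loglik(eta, phi).sum())
            if not want_grad:
                return ll
            d_eta, d_phi = self._score_parts(eta, phi)
            grad = np.concatenate([self.X.T @ d_eta, [phi * d_phi.sum()]])
            return ll, grad
        inv_s2 = 1.0 / (sigma * sigma)

        # damped Newton for the per-expert conditional modes, batched
        u = self.u_hat.copy()
        g_val = self._group_loglik(eta + u[self.g], phi) - 0.5 * u * u * inv_s2
        for _ in range(50):
            d1, d2 = self._group_derivs(eta + u[self.g], phi)
            gp = d1 - u * inv_s2
            if np.all(np.abs(gp) < 1e-9):
                break
            gpp = np.minimum(d2 - inv_s2, -inv_s2 * 1e-8 - 1e-12)
            step = -gp / gpp
            for _ in range(30):  # backtrack groups whose objective decreased
                u_new = u + step
                g_new = self._group_loglik(eta + u_new[self.g], phi) - 0.5 * u_new * u_new * inv_s2
                bad = g_new < g_val - 1e-12
                if not bad.any():
                    break
                step[bad] *= 0.5
            if np.max(np.abs(u_new - u)) < 1e-12:
                u, g_val = u_new, g_new
                break
            u, g_val = u_new, g_new
        self.u_hat = u

        _, d2 = self._group_derivs(eta + u[self.g], phi)
        h = -(d2 - inv_s2)
        h = np.where(h > 0, h, inv_s2)
        scale = np.sqrt(2.0 / h)  # (G,)
        # nodes re-centred per expert: (G, K) -> per-record (K stacked) eval
        u_k = u[:, None] + scale[:, None] * nodes[None, :]
        K = len(nodes)
        ll_gk = np.empty((self.G, K))
        for k in range(K):
            ll_gk[:, k] = self._group_loglik(eta + u_k[self.g, k], phi)
        log_prior = -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * u_k * u_k * inv_s2
        body = ll_gk + log_prior + nodes[None, :] ** 2 + log_gh_w[None, :]
        lse = logsumexp(body, axis=1)
        ll_total = float(np.sum(lse + np.log(scale)))
        if not want_grad:
            return ll_total

        # posterior node weights per expert; joint score averaged under them
        p_gk = np.exp(body - lse[:, None])  # (G, K)
        g_beta = np.zeros(len(beta))
        g_logphi = 0.0
        g_logsigma = 0.0
        for k in range(K):
            d_eta, d_phi = self._score_parts(eta + u_k[self.g, k], phi)
            pk_rec = p_gk[self.g, k]
            g_beta += self.X.T @ (pk_rec * d_eta)
            g_logphi += float(np.dot(p_gk[:, k], np.bincount(self.g, d_phi, minlength=self.G)))
        g_logsigma = float(np.sum(p_gk * (u_k * u_k * inv_s2 - 1.0)))
        grad = np.concatenate([g_beta, [phi * g_logphi], [g_logsigma]])
        return ll_total, grad


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4, grad=None) -> np.ndarray:
    """Central-difference Hessian of a scalar function (from its gradient
    when one is supplied, which needs only 2n evaluations)."""
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    if grad is not None:
        for i in range(n):
            ei = np.zeros(n); ei[i] = h[i]
            H[i, :] = (grad(x + ei) - grad(x - ei)) / (2.0 * h[i])
        return 0.5 * (H + H.T)
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_weighted_beta(
    z: pd.DataFrame,
    y: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    terms: Sequence[str] = TERMS,
    n_nodes: int = 15,
    squeeze: bool = True,
    sigma: float | None = None,
    df_method: str = "edf",
) -> FittedModel:
    """Fit the weighted Beta mixed model by marginal maximum likelihood.

    Parameters
    ----------
    z : standardized covariate table, one row per elicitation record
    y : elicited probabilities in [0, 1] (squeezed to (0, 1) unless
        ``squeeze=False``, in which case they must already be interior)
    weights : confidence weights, conventionally in {0.5, 0.75, 1.0}
    groups : expert identifier per record (the random-intercept grouping)
    n_nodes : Gauss-Hermite nodes for the adaptive random-effect integral
    sigma : fix the random-intercept SD instead of estimating it
        (``sigma=0`` gives a plain weighted Beta regression)
    df_method : "edf" subtracts the effective df absorbed by the random
        intercepts from n - p; "nominal" uses n - p directly

    Returns a :class:`FittedModel` with family ``"beta"``; ``aux`` carries
    ``phi``, ``sigma_expert`` and ``edf_random``.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    grp_labels = np.asarray(groups)
    X = design_matrix(z, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more records ({n}) than fixed-effect parameters ({p})")
    _check_rank(X, terms)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if squeeze:
        y = np.asarray(squeeze_probabilities(y, n))
    elif np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses touch {0, 1}; squeeze them first")

    labels = pd.unique(grp_labels)
    if sigma is None and len(labels) < 2:
        warnings.warn(
            "fewer than 2 experts: random intercept unidentifiable, "
            "falling back to a fixed-intercept-only fit",
            stacklevel=2,
        )
        sigma = 0.0
    lab_index = {lab: i for i, lab in enumerate(labels)}
    g_idx = np.array([lab_index[lab] for lab in grp_labels])
    panel = _Panel(X, y, w, g_idx, len(labels))

    estimate_sigma = sigma is None
    sigma_fixed = None if estimate_sigma else float(sigma)
    nodes, gh_w = np.polynomial.hermite.hermgauss(n_nodes)
    log_gh_w = np.log(gh_w)

    def nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        phi = np.exp(theta[p])
        sig = sigma_fixed if sigma_fixed is not None else np.exp(theta[p + 1])
        return -panel.marginal_loglik(beta, phi, sig, nodes, log_gh_w)

    def nll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta = theta[:p]
        phi = np.exp(theta[p])
        sig = sigma_fixed if sigma_fixed is not None else np.exp(theta[p + 1])
        ll, grad = panel.marginal_loglik(beta, phi, sig, nodes, log_gh_w, want_grad=True)
        return -ll, -grad[: len(theta)]

    # start fixed effects from weighted least squares on logit(y)
    ystar = np.log(y) - np.log1p(-y)
    Xw = X * w[:, None]
    beta0, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ ystar, rcond=None)
    x0 = np.concatenate([beta0, [np.log(10.0)]])
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p + [
        (np.log(1e-2), np.log(1e5))
    ]
    if estimate_sigma:
        x0 = np.concatenate([x0, [np.log(0.3)]])
        bounds.append((np.log(1e-4), np.log(10.0)))

    res = minimize(
        nll_grad, x0, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": 500},
    )
    theta = res.x
    beta_hat = theta[:p]
    phi_hat = float(np.exp(theta[p]))
    sigma_hat = float(np.exp(theta[p + 1])) if estimate_sigma else float(sigma_fixed)
    converged = bool(res.success)

    at_bound = theta[p] <= bounds[p][0] + 1e-6 or theta[p] >= bounds[p][1] - 1e-6
    if estimate_sigma and theta[p + 1] >= bounds[p + 1][1] - 1e-6:
        at_bound = True
    if at_bound:
        warnings.warn(
            f"parameter at boundary (phi={phi_hat:.3g}, sigma={sigma_hat:.3g}); "
            "estimates flagged as non-converged",
            stacklevel=2,
        )
        converged = False

    H = _numeric_hessian(nll, theta, grad=lambda t: nll_grad(t)[1])
    try:
        vcov_all = np.linalg.inv(H)
        se_all = np.sqrt(np.diag(vcov_all))
        ok = bool(np.all(np.isfinite(se_all[:p])) and np.all(se_all[:p] > 0))
    except (np.linalg.LinAlgError, FloatingPointError):
        ok = False
    if not ok:
        warnings.warn("observed information not positive definite; fit flagged", stacklevel=2)
        converged = False
        vcov_all = np.full((len(theta), len(theta)), np.nan)
        se_all = np.full(len(theta), np.nan)

    # effective df absorbed by the shrunken intercepts: per expert the ridge
    # trace I_j / (I_j + 1/sigma^2), capped at n_experts - 1
    if sigma_hat < 1e-8:
        edf = 0.0
    else:
        panel.marginal_loglik(beta_hat, phi_hat, sigma_hat, nodes, log_gh_w)
        _, d2 = panel._group_derivs(X @ beta_hat + panel.u_hat[g_idx], phi_hat)
        I_j = np.maximum(-d2, 0.0)
        inv_s2 = 1.0 / (sigma_hat * sigma_hat)
        edf = float(min(np.sum(I_j / (I_j + inv_s2)), len(labels) - 1.0))

    if df_method == "edf":
        residual_df = float(n - p - edf)
    elif df_method == "nominal":
        residual_df = float(n - p)
    else:
        raise ValueError(f"unknown df_method {df_method!r}; use 'edf' or 'nominal'")

    # containment df: the intercept is confounded with the expert intercepts,
    # so its Wald interval is replicated at the expert level only
    df_by_term = np.full(p, residual_df)
    if sigma_hat > 1e-8 and len(labels) > 1:
        df_by_term[list(terms).index("intercept")] = len(labels) - 1.0

    return FittedModel(
        family="beta",
        terms=tuple(terms),
        coef=beta_hat,
        se=se_all[:p],
        vcov=vcov_all[:p, :p],
        residual_df=residual_df,
        n_obs=n,
        converged=converged,
        aux={
            "phi": phi_hat,
            "sigma_expert": sigma_hat,
            "edf_random": edf,
            "n_experts": len(labels),
            "loglik": -float(res.fun),
            "df_by_term": df_by_term,
        },
    )


def residual_df_expert(model: FittedModel, method: str = "edf") -> float:
    """Residual degrees of freedom v_e of a fitted expert model.

    ``"edf"``: n - p_fixed - edf_random, where edf_random is the effective
    number of parameters absorbed by the shrunken expert intercepts (bounded
    by n_experts - 1).  ``"nominal"``: simply n - p_fixed.
    """
    p = len(model.coef)
    if method == "nominal":
        return float(model.n_obs - p)
    if method == "edf":
        return float(model.n_obs - p - model.aux.get("edf_random", 0.0))
    raise ValueError(f"unknown method {method!r}; use 'edf' or 'nominal'")
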