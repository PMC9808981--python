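"""Vectorized negative-binomial GLM fitting for count matrices.

All exons are fit simultaneously: one IRLS step solves a small weighted
least-squares problem per exon via batched normal equations.  The log link
is used with offsets log(lib_size * norm_factor).  With dispersion 0 the
model reduces exactly to a Poisson GLM.

The NB parameterization is mean/dispersion: Var(y) = mu + phi * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

_ETA_MIN, _ETA_MAX = -30.0, 30.0
_PHI_EPS = 1e-10


@dataclass
class GlmFit:
    """Per-exon GLM fit: coefficients, fitted means, deviance, df."""

    coef: np.ndarray        # (G, P)
    mu: np.ndarray          # (G, S) fitted means
    deviance: np.ndarray    # (G,)
    df_residual: int
    converged: np.ndarray   # (G,) bool
    offsets: np.ndarray     # (S,)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Residual deviance of the NB model, rowwise.

    2 * sum[ y*log(y/mu) - (y + 1/phi)*log((1 + phi*y)/(1 + phi*mu)) ];
    the Poisson limit 2*sum[y*log(y/mu) - (y - mu)] is used when phi ~ 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    pois = 2.0 * np.sum(ylogy - (y - mu), axis=1)
    phi_safe = np.maximum(phi, _PHI_EPS)
    nb = 2.0 * np.sum(
        ylogy - (y + 1.0 / phi_safe) * np.log1p(phi_safe * (y - mu) / (1.0 + phi_safe * mu)),
        axis=1,
    )
    small = phi.ravel() < _PHI_EPS
    return np.where(small, pois, nb)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rowwise NB log-likelihood (Poisson when phi ~ 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    pois = np.sum(y * np.log(mu) - mu - gammaln(y + 1.0), axis=1)
    r = 1.0 / np.maximum(phi, _PHI_EPS)
    nb = np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu) + 1e-300)
        - r * np.log1p(phi * mu),
        axis=1,
    )
    small = phi.ravel() < _PHI_EPS
    return np.where(small, pois, nb)


def fit_nb_glm(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    dispersions: np.ndarray | float,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GlmFit:
    """Fit a log-link NB GLM per exon (rows) with shared design and offsets.

    dispersions may be a scalar or per-exon vector; 0 gives a Poisson fit.
    All-zero rows get near-zero fitted means, zero deviance, and are marked
    converged without iteration.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    G, S = y.shape
    P = X.shape[1]
    if X.shape[0] != S:
        raise ValueError("design rows must match samples")
    if np.linalg.matrix_rank(X) < P:
        raise ValueError("design matrix is not full column rank")
    offsets = np.asarray(offsets, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersions, dtype=float).reshape(-1), (G,)).copy() \
        if np.ndim(dispersions) else np.full(G, float(dispersions))
    phi = np.maximum(phi, 0.0)

    allzero = y.sum(axis=1) == 0
    active = ~allzero

    beta = np.zeros((G, P))
    # initialize from a log-scale least-squares projection
    mu0 = np.maximum((y + y.mean(axis=1, keepdims=True)) / 2.0, 1e-4)
    eta0 = np.log(mu0) - offsets
    pinv = np.linalg.pinv(X)
    beta = eta0 @ pinv.T

    converged = np.zeros(G, dtype=bool)
    converged[allzero] = True
    phi_col = phi.reshape(-1, 1)
    idx = np.where(active)[0]
    for _ in range(max_iter):
        if idx.size == 0:
            break
        eta = np.clip(beta[idx] @ X.T + offsets, _ETA_MIN, _ETA_MAX)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_col[idx] * mu)  # mu^2 / (mu + phi mu^2)
        z = (eta - offsets) + (y[idx] - mu) / mu
        xtwx = np.einsum("sp,gs,sq->gpq", X, w, X)
        xtwz = np.einsum("sp,gs,gs->gp", X, w, z)
        # ridge-stabilize near-singular systems (e.g. a group with all zeros)
        xtwx += 1e-10 * np.eye(P)
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta[idx]), axis=1)
        beta[idx] = new_beta
        done = delta < tol
        converged[idx[done]] = True
        idx = idx[~done]

    eta = np.clip(beta @ X.T + offsets, _ETA_MIN, _ETA_MAX)
    mu = np.exp(eta)
    mu[allzero] = 1e-12
    beta[allzero] = _ETA_MIN
    dev = nb_deviance(y, mu, phi)
    dev[allzero] = 0.0
    return GlmFit(
        coef=beta,
        mu=mu,
        deviance=dev,
        df_residual=S - P,
        converged=converged,
        offsets=offsets,
    )


def adjusted_profile_loglik(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray | float,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per exon at dispersion(s) phi.

    APL_g(phi) = loglik(y_g; mu_hat(phi), phi) - 0.5*log det(X' W X), the
    standard adjustment removing first-order bias from estimating the
    coefficients.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    G = y.shape[0]
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1), (G,)).copy() \
        if np.ndim(phi) else np.full(G, float(phi))
    fit = fit_nb_glm(y, X, offsets, phi_vec)
    ll = nb_loglik(y, fit.mu, phi_vec)
    w = fit.mu / (1.0 + phi_vec.reshape(-1, 1) * fit.mu)
    xtwx = np.einsum("sp,gs,sq->gpq", X, w, X) + 1e-12 * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(xtwx)
    return ll - 0.5 * logdet
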