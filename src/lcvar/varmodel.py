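"""Cluster-level VAR(p) model with covariate-moderated means.

The observation model for a person in cluster k is

    y_t = mu + beta x_t + w_t
    w_t = sum_a Phi_a w_{t-a} + u_t,    u_t ~ N(0, Sigma)

so the one-step conditional mean of y_t given its history is

    mu + beta x_t + sum_a Phi_a (y_{t-a} - mu - beta x_{t-a}).

This module evaluates those conditional Gaussian densities, accumulates
per-person log-likelihoods over predictable rows, and performs the
weighted M-step used by the EM engine: two exact conditional blocks
(lagged effects and innovation covariance given the mean structure, then
a generalized-least-squares update of the mean structure given the lagged
effects), which makes the surrounding EM a generalized EM with a
monotone log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import LongPanel, PredictabilityMask, predictability_mask

__all__ = [
    "ClusterParams",
    "RegressionData",
    "ClusterCollapseError",
    "build_regression_data",
    "conditional_mean",
    "conditional_log_density",
    "person_cluster_loglik",
    "cluster_logliks",
    "weighted_m_step",
    "companion_spectral_radius",
]

_LOG2PI = np.log(2.0 * np.pi)
#: jitter added to Sigma when it is close to singular
_SIGMA_FLOOR = 1e-8
_COND_LIMIT = 1e12


class ClusterCollapseError(RuntimeError):
    """A cluster has too little effective weight to estimate its VAR."""


@dataclass(frozen=True)
class ClusterParams:
    """One cluster's VAR parameters.

    mu : (m,) means (value of the mean structure at x = 0)
    beta : (m, q) immediate covariate effects on the means
    phi : tuple of p (m, m) lagged-effects matrices (lag 1..p)
    sigma : (m, m) innovation covariance, symmetric positive definite
    tau : prior cluster proportion in (0, 1]
    """

    mu: np.ndarray
    beta: np.ndarray
    phi: tuple[np.ndarray, ...]
    sigma: np.ndarray
    tau: float = 1.0

    def __post_init__(self):
        m = len(self.mu)
        object.__setattr__(self, "mu", np.asarray(self.mu, float))
        object.__setattr__(self, "beta", np.asarray(self.beta, float).reshape(m, -1))
        object.__setattr__(
            self, "phi", tuple(np.asarray(P, float) for P in self.phi)
        )
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if not self.phi:
            raise ValueError("at least one lag matrix is required")
        for P in self.phi:
            if P.shape != (m, m):
                raise ValueError(f"phi matrices must be {m}x{m}, got {P.shape}")
        if self.sigma.shape != (m, m):
            raise ValueError("sigma has wrong shape")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")

    @property
    def m(self) -> int:
        return len(self.mu)

    @property
    def p(self) -> int:
        return len(self.phi)

    @property
    def q(self) -> int:
        return self.beta.shape[1]

    def to_records(self, cluster: int = 0) -> list[dict]:
        """Flat long-format records for CSV serialization."""
        rec = []
        for j, v in enumerate(self.mu):
            rec.append(dict(cluster=cluster, parameter_type="mu", row=j, col=0, value=v))
        for j in range(self.m):
            for l in range(self.q):
                rec.append(
                    dict(cluster=cluster, parameter_type="beta", row=j, col=l,
                         value=self.beta[j, l])
                )
        for a, P in enumerate(self.phi, start=1):
            for j in range(self.m):
                for l in range(self.m):
                    rec.append(
                        dict(cluster=cluster, parameter_type=f"phi_lag_{a}",
                             row=j, col=l, value=P[j, l])
                    )
        for j in range(self.m):
            for l in range(self.m):
                rec.append(
                    dict(cluster=cluster, parameter_type="sigma", row=j, col=l,
                         value=self.sigma[j, l])
                )
        rec.append(dict(cluster=cluster, parameter_type="tau", row=0, col=0,
                        value=self.tau))
        return rec


def companion_spectral_radius(phi) -> float:
    """Largest eigenvalue modulus of the VAR companion matrix.

    A value < 1 means the VAR is stable (weakly stationary).
    """
    phi = [np.atleast_2d(np.asarray(P, float)) for P in phi]
    m = phi[0].shape[0]
    for P in phi:
        if P.shape != (m, m):
            raise ValueError("all lag matrices must be square with equal size")
    p = len(phi)
    C = np.zeros((p * m, p * m))
    C[:m, :] = np.hstack(phi)
    if p > 1:
        C[m:, :-m] = np.eye((p - 1) * m)
    return float(np.abs(np.linalg.eigvals(C)).max())


# ---------------------------------------------------------------------------
# regression layout for the predictable rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionData:
    """Predictable rows of a panel arranged for lag-``p`` regression.

    Y : (n, m) targets;  L : (n, p, m) lagged outcomes (a-th slice is
    y_{t-a});  X : (n, q) covariates at t;  XL : (n, p, q) lagged
    covariates;  person : (n,) integer person codes;  T : (N,) effective
    counts per person;  row_index : positions in the panel.
    """

    lag: int
    Y: np.ndarray
    L: np.ndarray
    X: np.ndarray
    XL: np.ndarray
    person: np.ndarray
    T: np.ndarray
    n_persons: int
    row_index: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    @property
    def q(self) -> int:
        return self.X.shape[1]


def build_regression_data(
    panel: LongPanel,
    lag: int,
    mask: PredictabilityMask | None = None,
    use_day_breaks: bool = True,
) -> RegressionData:
    """Extract targets, lagged predictors and covariates for all
    predictable rows of the panel under the given lag order."""
    if mask is None:
        mask = predictability_mask(panel, lag, use_day_breaks=use_day_breaks)
    df = panel.data
    Yfull = panel.outcome_matrix()
    Xfull, _ = panel.covariate_matrix()
    codes = panel.person_codes()

    # map (person, day, beep) -> row position for lag lookups
    import pandas as pd

    from .panel import BEEP, DAY, ID

    pos = pd.Series(
        np.arange(len(df)),
        index=pd.MultiIndex.from_arrays([df[ID], df[DAY], df[BEEP]]),
    )
    idx = np.flatnonzero(mask.predictable)
    n, m, q = len(idx), Yfull.shape[1], Xfull.shape[1]
    L = np.empty((n, lag, m))
    XL = np.empty((n, lag, q))
    sub = df.iloc[idx]
    for a in range(1, lag + 1):
        prev_keys = pd.MultiIndex.from_arrays([sub[ID], sub[DAY], sub[BEEP] - a])
        prev_pos = pos.reindex(prev_keys).to_numpy()
        # predictable rows are guaranteed to have all predecessors present
        prev_pos = prev_pos.astype(int)
        L[:, a - 1, :] = Yfull[prev_pos]
        XL[:, a - 1, :] = Xfull[prev_pos]
    counts = np.bincount(codes[idx], minlength=panel.n_persons)
    return RegressionData(
        lag=lag,
        Y=Yfull[idx],
        L=L,
        X=Xfull[idx],
        XL=XL,
        person=codes[idx],
        T=counts,
        n_persons=panel.n_persons,
        row_index=idx,
    )


# ---------------------------------------------------------------------------
# conditional densities
# ---------------------------------------------------------------------------

def conditional_mean(params: ClusterParams, history, x_t=None, x_history=None):
    """One-step conditional mean of y_t.

    history : (p, m) array, row a-1 holding y_{t-a}.
    x_t : (q,) covariates at t; x_history : (p, q) lagged covariates.
    """
    history = np.atleast_2d(np.asarray(history, float))
    if history.shape[0] < params.p:
        raise ValueError(
            f"history supplies {history.shape[0]} lags, model needs {params.p}"
        )
    q = params.q
    x_t = np.zeros(q) if x_t is None else np.asarray(x_t, float)
    x_history = (
        np.zeros((params.p, q)) if x_history is None else np.atleast_2d(x_history)
    )
    mean = params.mu + params.beta @ x_t
    for a in range(params.p):
        centered = history[a] - params.mu - params.beta @ x_history[a]
        mean = mean + params.phi[a] @ centered
    return mean


def conditional_log_density(params: ClusterParams, y_t, history, x_t=None,
                            x_history=None) -> float:
    """Log density of y_t under the cluster's conditional Gaussian."""
    resid = np.asarray(y_t, float) - conditional_mean(params, history, x_t, x_history)
    chol = _safe_cholesky(params.sigma)
    from scipy.linalg import solve_triangular

    u = solve_triangular(chol, resid, lower=True)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(-0.5 * (params.m * _LOG2PI + logdet + u @ u))


def _safe_cholesky(sigma: np.ndarray) -> np.ndarray:
    try:
        if np.linalg.cond(sigma) > _COND_LIMIT:
            raise np.linalg.LinAlgError("ill-conditioned")
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("innovation covariance near-singular; adding jitter",
                      stacklevel=2)
        try:
            return np.linalg.cholesky(
                sigma + _SIGMA_FLOOR * np.eye(len(sigma))
            )
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "innovation covariance singular even after jitter"
            ) from exc


def _row_logdensities(data: RegressionData, params: ClusterParams) -> np.ndarray:
    """Vectorized conditional log density for every predictable row."""
    mean = np.broadcast_to(params.mu, data.Y.shape).copy()
    if params.q:
        mean = mean + data.X @ params.beta.T
    for a in range(params.p):
        centered = data.L[:, a, :] - params.mu
        if params.q:
            centered = centered - data.XL[:, a, :] @ params.beta.T
        mean = mean + centered @ params.phi[a].T
    resid = data.Y - mean
    chol = _safe_cholesky(params.sigma)
    from scipy.linalg import solve_triangular

    u = solve_triangular(chol, resid.T, lower=True).T
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (data.m * _LOG2PI + logdet + np.einsum("ij,ij->i", u, u))


def cluster_logliks(data: RegressionData, params: ClusterParams) -> np.ndarray:
    """Per-person log-likelihood l_{ik} under one cluster's parameters."""
    ld = _row_logdensities(data, params)
    return np.bincount(data.person, weights=ld, minlength=data.n_persons)


def person_cluster_loglik(
    panel: LongPanel,
    person,
    params: ClusterParams,
    mask: PredictabilityMask | None = None,
) -> float:
    """Sum of conditional log densities over one person's predictable rows."""
    data = build_regression_data(panel, params.p, mask)
    persons = panel.persons
    code = int(np.flatnonzero(persons == person)[0])
    if data.T[code] == 0:
        warnings.warn(
            f"person {person!r} has no predictable rows at lag {params.p}; "
            "log-likelihood contribution is 0",
            stacklevel=2,
        )
        return 0.0
    return float(cluster_logliks(data, params)[code])


# ---------------------------------------------------------------------------
# weighted M-step
# ---------------------------------------------------------------------------

def weighted_m_step(
    data: RegressionData,
    weights: np.ndarray,
    prev: ClusterParams | None = None,
    ridge: float = 0.0,
) -> ClusterParams:
    """Weighted conditional maximizer of the cluster's Gaussian likelihood.

    ``weights`` is a per-row weight in [0, 1] (each row carries its
    person's posterior membership probability).

    Without covariates the conditional mean mu + sum_a Phi_a (y_{t-a} - mu)
    is a pure reparameterization of an intercept form c + sum_a Phi_a
    y_{t-a}, so the exact joint maximizer is weighted least squares with
    an intercept, followed by mu = (I - sum_a Phi_a)^{-1} c.

    With covariates the joint problem is nonlinear in (mu, beta, Phi) and
    one pass of two exact conditional blocks is used instead:

    * Block A — given the mean structure (mu, beta) from ``prev`` (or a
      weighted-mean initialization), form w_t = y_t - mu - beta x_t and
      solve the weighted multivariate least-squares regression of w_t on
      its p lags for Phi; Sigma is the weighted residual covariance.
    * Block B — given Phi and Sigma, update (mu, beta) by generalized
      least squares on z_t = y_t - sum_a Phi_a y_{t-a}, whose mean is
      (I - sum_a Phi_a) mu + beta x_t - sum_a Phi_a beta x_{t-a}.

    Each block maximizes its conditional objective, so the surrounding EM
    is a generalized EM with monotone log-likelihood.
    """
    w = np.asarray(weights, float)
    m, p, q = data.m, data.lag, data.q
    sw = w.sum()
    if sw <= m * (p + 1) + q:
        raise ClusterCollapseError(
            f"effective weight {sw:.2f} too small for m={m}, p={p}, q={q}"
        )
    if q == 0:
        return _m_step_no_covariates(data, w, sw)
    if prev is None:
        mu = (w @ data.Y) / sw
        beta = np.zeros((m, q))
    else:
        mu, beta = prev.mu, prev.beta

    # ---- Block A: Phi and Sigma given (mu, beta) ----------------------
    Wy = data.Y - mu
    Wl = data.L - mu
    if q:
        Wy = Wy - data.X @ beta.T
        Wl = Wl - np.einsum("naq,mq->nam", data.XL, beta)
    D = Wl.reshape(data.n, p * m)  # stacked lagged predictors
    Dw = D * w[:, None]
    G = D.T @ Dw
    if ridge:
        G = G + ridge * np.eye(p * m)
    try:
        B = np.linalg.solve(G, D.T @ (Wy * w[:, None]))
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient lag design; applying ridge regularization",
                      stacklevel=2)
        B = np.linalg.solve(G + 1e-8 * np.trace(G) / (p * m) * np.eye(p * m),
                            D.T @ (Wy * w[:, None]))
    phi = tuple(B[a * m : (a + 1) * m, :].T for a in range(p))

    resid = Wy - D @ B
    sigma = (resid.T * w) @ resid / sw
    sigma = 0.5 * (sigma + sigma.T)
    if np.linalg.cond(sigma) > _COND_LIMIT:
        sigma = sigma + _SIGMA_FLOOR * np.eye(m)

    # ---- Block B: (mu, beta) given Phi and Sigma -----------------------
    A = np.eye(m) - sum(phi)
    Z = data.Y - sum(data.L[:, a, :] @ phi[a].T for a in range(p))
    siginv = np.linalg.inv(sigma)
    if q == 0:
        zbar = (w @ Z) / sw
        try:
            mu_new = np.linalg.solve(A, zbar)
        except np.linalg.LinAlgError:
            mu_new = np.linalg.lstsq(A, zbar, rcond=None)[0]
        beta_new = beta
    else:
        mu_new, beta_new = _gls_mean_structure(data, phi, A, siginv, w, Z)
    return ClusterParams(mu=mu_new, beta=beta_new, phi=phi, sigma=sigma, tau=1.0)


def _m_step_no_covariates(data: RegressionData, w: np.ndarray,
                          sw: float) -> ClusterParams:
    """Exact weighted maximizer for q = 0 via the intercept form."""
    m, p = data.m, data.lag
    D = np.column_stack([np.ones(data.n), data.L.reshape(data.n, p * m)])
    Dw = D * w[:, None]
    G = D.T @ Dw
    try:
        B = np.linalg.solve(G, D.T @ (data.Y * w[:, None]))
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient lag design; applying ridge regularization",
                      stacklevel=2)
        k = G.shape[0]
        B = np.linalg.solve(G + 1e-8 * np.trace(G) / k * np.eye(k),
                            D.T @ (data.Y * w[:, None]))
    c = B[0]
    phi = tuple(B[1 + a * m : 1 + (a + 1) * m, :].T for a in range(p))
    resid = data.Y - D @ B
    sigma = (resid.T * w) @ resid / sw
    sigma = 0.5 * (sigma + sigma.T)
    if np.linalg.cond(sigma) > _COND_LIMIT:
        sigma = sigma + _SIGMA_FLOOR * np.eye(m)
    A = np.eye(m) - sum(phi)
    try:
        mu = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        mu = np.linalg.lstsq(A, c, rcond=None)[0]
    return ClusterParams(mu=mu, beta=np.zeros((m, 0)), phi=phi, sigma=sigma,
                         tau=1.0)


def _gls_mean_structure(data, phi, A, siginv, w, Z):
    """GLS solve for (mu, beta) given the lagged effects.

    The per-row design for the stacked unknown [mu, beta[:,1], ...,
    beta[:,q]] is a sum of fixed m x m matrices with scalar row
    coefficients, so the normal equations assemble from small matrix
    products and weighted cross-moments of the coefficients.
    """
    m, p, q = data.m, data.lag, data.q
    # basis per unknown block: list of (coefficient column (n,), matrix)
    ones = np.ones(data.n)
    blocks: list[list[tuple[np.ndarray, np.ndarray]]] = [[(ones, A)]]
    for j in range(q):
        terms = [(data.X[:, j], np.eye(m))]
        for a in range(p):
            terms.append((-data.XL[:, a, j], phi[a]))
        blocks.append(terms)

    nb = 1 + q
    M = np.zeros((nb * m, nb * m))
    rhs = np.zeros(nb * m)
    for r in range(nb):
        for (c1, G1) in blocks[r]:
            rhs[r * m : (r + 1) * m] += G1.T @ siginv @ ((w * c1) @ Z)
            for s in range(nb):
                for (c2, G2) in blocks[s]:
                    scal = float(np.dot(w * c1, c2))
                    M[r * m : (r + 1) * m, s * m : (s + 1) * m] += (
                        scal * (G1.T @ siginv @ G2)
                    )
    try:
        theta = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("mean-structure design rank-deficient; least-squares fallback",
                      stacklevel=2)
        theta = np.linalg.lstsq(M, rhs, rcond=None)[0]
    mu = theta[:m]
    beta = theta[m:].reshape(q, m).T
    return mu, beta
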