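"""EM estimation of latent class VAR models.

Each person belongs to exactly one of K clusters; cluster k has its own
VAR(p_k) parameters Theta_k and prior proportion tau_k.  The E-step
computes posterior membership probabilities by Bayes' rule,

    pi_{ik} = tau_k L_{ik} / sum_k' tau_k' L_{ik'},

where L_{ik} is person i's likelihood over their predictable rows under
cluster k (evaluated in log space with a log-sum-exp shift so that long
series never underflow).  The M-step re-estimates each cluster's
parameters from all persons' predictable rows weighted by the posterior,
and tau_k as the posterior column mean.  Starts are a mix of random
partitions, a "rational" k-means-on-person-features partition, and
optionally the modal partition of a previous fit; the winner is the
start with the highest final log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .panel import LongPanel, predictability_mask
from .varmodel import (
    ClusterCollapseError,
    ClusterParams,
    RegressionData,
    build_regression_data,
    cluster_logliks,
    weighted_m_step,
)

__all__ = [
    "ModelSpec",
    "StartConfig",
    "LCVARFit",
    "StartFailedError",
    "initialize_partition",
    "e_step",
    "run_em",
    "multi_start_fit",
]


class StartFailedError(RuntimeError):
    """An EM start aborted (cluster collapse or degenerate likelihood)."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: K clusters with per-cluster lag orders.

    ``lags`` may be a single int (shared by all clusters) or a sequence of
    length K; it is stored sorted, as cluster order is arbitrary.
    """

    K: int
    lags: tuple[int, ...]
    centered: bool = False

    def __post_init__(self):
        lags = self.lags
        if isinstance(lags, int):
            lags = (lags,) * self.K
        lags = tuple(sorted(int(l) for l in lags))
        if len(lags) != self.K:
            raise ValueError(f"need {self.K} lag orders, got {len(lags)}")
        if any(l < 1 for l in lags):
            raise ValueError("lag orders must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        object.__setattr__(self, "lags", lags)

    @property
    def common_lag(self) -> int | None:
        return self.lags[0] if len(set(self.lags)) == 1 else None


@dataclass(frozen=True)
class StartConfig:
    """Initialization and convergence control for multi-start EM."""

    n_random: int = 50
    use_rational: bool = True
    previous: "LCVARFit | None" = None
    max_iter: int = 100
    conv_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.n_random < 0 or self.max_iter < 1 or self.conv_tol <= 0:
            raise ValueError("invalid start configuration")


@dataclass
class LCVARFit:
    """A fitted latent class VAR model."""

    spec: ModelSpec
    clusters: list[ClusterParams]
    posterior: np.ndarray
    loglik_trace: list[float]
    converged: bool
    n_iterations: int
    effective_T: np.ndarray  # (N, K) T_{ik}
    persons: np.ndarray
    criteria: dict = field(default_factory=dict)
    n_starts_converged: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def K(self) -> int:
        return self.spec.K

    @property
    def tau(self) -> np.ndarray:
        return np.array([c.tau for c in self.clusters])

    @property
    def modal_assignment(self) -> np.ndarray:
        """Highest-posterior cluster per person; ties -> lowest index."""
        return self.posterior.argmax(axis=1)

    def proportions(self) -> np.ndarray:
        """Share of persons modally assigned to each cluster."""
        return np.bincount(self.modal_assignment, minlength=self.K) / len(
            self.posterior
        )

    def relabel(self, perm: np.ndarray) -> "LCVARFit":
        """Return a copy with clusters reordered by ``perm``."""
        perm = np.asarray(perm)
        return LCVARFit(
            spec=ModelSpec(self.spec.K,
                           tuple(self.spec.lags[j] for j in perm),
                           self.spec.centered),
            clusters=[self.clusters[j] for j in perm],
            posterior=self.posterior[:, perm],
            loglik_trace=list(self.loglik_trace),
            converged=self.converged,
            n_iterations=self.n_iterations,
            effective_T=self.effective_T[:, perm],
            persons=self.persons,
            criteria=dict(self.criteria),
            n_starts_converged=self.n_starts_converged,
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize_partition(
    panel: LongPanel,
    spec: ModelSpec,
    strategy: str = "random",
    seed: int = 0,
    previous: LCVARFit | None = None,
) -> np.ndarray:
    """Hard person-to-cluster assignment used to start EM.

    random   : uniform assignment, redrawn until every cluster holds at
               least ceil(N / 4K) persons.
    rational : k-means on standardized per-person features (outcome means
               plus lag-1 OLS VAR coefficients).
    previous : modal assignment of a supplied fit.
    """
    N, K = panel.n_persons, spec.K
    if K > N:
        raise ValueError(f"K={K} exceeds number of persons N={N}")
    if K == 1:
        return np.zeros(N, dtype=int)

    if strategy == "random":
        rng = np.random.default_rng(seed)
        min_size = int(np.ceil(N / (4 * K)))
        for _ in range(1000):
            labels = rng.integers(0, K, size=N)
            if np.bincount(labels, minlength=K).min() >= min_size:
                return labels
        raise StartFailedError("could not draw a partition meeting the size rule")
    if strategy == "rational":
        feats = _person_features(panel)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, random_state=seed, n_init=10)
        return km.fit_predict(feats)
    if strategy == "previous":
        if previous is None:
            raise ValueError("strategy 'previous' requires a prior fit")
        if previous.K != K:
            raise ValueError("previous fit has a different number of clusters")
        return previous.modal_assignment.copy()
    raise ValueError(f"unknown start strategy {strategy!r}")


def _person_features(panel: LongPanel) -> np.ndarray:
    """Per-person outcome means and lag-1 OLS VAR coefficients."""
    data = build_regression_data(panel, lag=1)
    m = data.m
    N = panel.n_persons
    feats = np.zeros((N, m + m * m))
    Y = panel.outcome_matrix()
    codes = panel.person_codes()
    for i in range(N):
        rows = Y[codes == i]
        rows = rows[~np.isnan(rows).any(axis=1)]
        if len(rows):
            feats[i, :m] = rows.mean(axis=0)
        sel = data.person == i
        if sel.sum() >= m + 2:
            X = data.L[sel, 0, :] - feats[i, :m]
            Z = data.Y[sel] - feats[i, :m]
            B, *_ = np.linalg.lstsq(X, Z, rcond=None)
            feats[i, m:] = B.T.ravel()
    return feats


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def e_step(loglik_matrix: np.ndarray, tau: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior memberships and the mixture log-likelihood.

    ``loglik_matrix`` is the (N, K) array of per-person log-likelihoods
    l_{ik}; ``tau`` the prior proportions.  Returns (posterior, loglik).
    """
    tau = np.asarray(tau, float)
    if np.any(tau <= 0) or abs(tau.sum() - 1.0) > 1e-8:
        raise ValueError("tau must be positive and sum to 1")
    if not np.all(np.isfinite(loglik_matrix.max(axis=1))):
        bad = np.flatnonzero(~np.isfinite(loglik_matrix.max(axis=1)))
        raise StartFailedError(
            f"no cluster can explain person index(es) {bad.tolist()}"
        )
    a = loglik_matrix + np.log(tau)
    norm = logsumexp(a, axis=1)
    post = np.exp(a - norm[:, None])
    return post, float(norm.sum())


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _posterior_from_labels(labels: np.ndarray, K: int) -> np.ndarray:
    post = np.zeros((len(labels), K))
    post[np.arange(len(labels)), labels] = 1.0
    return post


def run_em(
    panel: LongPanel,
    spec: ModelSpec,
    start: np.ndarray,
    config: StartConfig | None = None,
    reg_data: dict[int, RegressionData] | None = None,
) -> LCVARFit:
    """Alternate M- and E-steps until the log-likelihood stabilizes.

    ``start`` is either a hard label vector (N,) or a posterior matrix
    (N, K).  The first M-step runs on the initial memberships; afterwards
    the relative log-likelihood improvement is tracked and the fit is
    flagged converged when it falls below ``conv_tol``.
    """
    config = config or StartConfig()
    N, K = panel.n_persons, spec.K
    if reg_data is None:
        reg_data = {
            p: build_regression_data(panel, p) for p in set(spec.lags)
        }
    start = np.asarray(start)
    post = start if start.ndim == 2 else _posterior_from_labels(start, K)
    if post.shape != (N, K):
        raise ValueError(f"start has shape {post.shape}, expected {(N, K)}")

    clusters: list[ClusterParams | None] = [None] * K
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        tau = post.mean(axis=0)
        if np.any(tau < 1.0 / (10 * N)):
            raise StartFailedError(
                f"cluster collapse: tau={np.round(tau, 4).tolist()} at iteration {it}"
            )
        # M-step (per cluster, rows weighted by the person's posterior)
        new_clusters = []
        for k in range(K):
            data = reg_data[spec.lags[k]]
            w = post[data.person, k]
            try:
                params = weighted_m_step(data, w, prev=clusters[k])
            except ClusterCollapseError as exc:
                raise StartFailedError(f"cluster {k}: {exc}") from exc
            new_clusters.append(
                ClusterParams(params.mu, params.beta, params.phi, params.sigma,
                              tau=float(tau[k]))
            )
        clusters = new_clusters
        # E-step
        ll = np.column_stack(
            [cluster_logliks(reg_data[spec.lags[k]], clusters[k]) for k in range(K)]
        )
        post, loglik = e_step(ll, tau)
        trace.append(loglik)
        if len(trace) >= 2:
            prev_l = trace[-2]
            denom = abs(prev_l) if prev_l != 0 else 1.0
            if abs(loglik - prev_l) / denom < config.conv_tol:
                converged = True
                break

    eff_T = np.column_stack(
        [reg_data[spec.lags[k]].T for k in range(K)]
    )
    fit = LCVARFit(
        spec=spec,
        clusters=clusters,
        posterior=post,
        loglik_trace=trace,
        converged=converged,
        n_iterations=it,
        effective_T=eff_T,
        persons=panel.persons,
    )
    # final tau consistent with the returned posterior
    tau = post.mean(axis=0)
    fit.clusters = [
        ClusterParams(c.mu, c.beta, c.phi, c.sigma, tau=float(tau[k]))
        for k, c in enumerate(clusters)
    ]
    return fit


def multi_start_fit(
    panel: LongPanel,
    spec: ModelSpec,
    config: StartConfig | None = None,
    reg_data: dict[int, RegressionData] | None = None,
) -> tuple[LCVARFit, pd.DataFrame]:
    """Best-of-many-starts EM fit plus a per-start report.

    Runs ``n_random`` random starts (seeds spawned deterministically from
    ``config.seed``), an optional rational start, and an optional start
    from a previous fit.  The winner is the converged-or-not start with
    the highest final log-likelihood; ties break toward the lowest start
    index.  The report lists every start's final log-likelihood,
    iteration count, convergence flag, and failure reason if any.
    """
    config = config or StartConfig()
    if reg_data is None:
        reg_data = {p: build_regression_data(panel, p) for p in set(spec.lags)}

    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(config.n_random + 1)]
    starts: list[tuple[str, np.ndarray | None]] = []
    for j in range(config.n_random):
        starts.append((f"random_{j}", None))
    if config.use_rational:
        starts.append(("rational", None))
    if config.previous is not None:
        starts.append(("previous", None))
    if not starts:
        raise ValueError("no starts configured")

    records = []
    best: LCVARFit | None = None
    best_key: tuple[float, int] | None = None
    for idx, (name, _) in enumerate(starts):
        try:
            if name.startswith("random_"):
                labels = initialize_partition(
                    panel, spec, "random", seed=child_seeds[int(name.split("_")[1])]
                )
            elif name == "rational":
                labels = initialize_partition(
                    panel, spec, "rational", seed=child_seeds[-1]
                )
            else:
                labels = initialize_partition(
                    panel, spec, "previous", previous=config.previous
                )
            fit = run_em(panel, spec, labels, config, reg_data)
        except (StartFailedError, ValueError) as exc:
            records.append(
                dict(start=name, loglik=np.nan, iterations=np.nan,
                     converged=False, failed=True, reason=str(exc))
            )
            continue
        records.append(
            dict(start=name, loglik=fit.loglik, iterations=fit.n_iterations,
                 converged=fit.converged, failed=False, reason="")
        )
        key = (fit.loglik, -idx)
        if best_key is None or key > best_key:
            best, best_key = fit, key

    report = pd.DataFrame(records)
    if best is None:
        raise StartFailedError(
            "all EM starts failed:\n" + report.to_string(index=False)
        )
    best.n_starts_converged = int(report["converged"].sum())
    return best, report
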