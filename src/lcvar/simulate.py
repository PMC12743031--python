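"""Generate latent class VAR populations and panels, and run recovery
studies over a factor grid.

The generator mirrors a standard EMA-scale simulation design: K equally
mixed clusters of persons, m = 6 outcome variables, innovation
covariance with 1 on the diagonal and 0.5 off the diagonal, N_T time
points per person in one uninterrupted sequence with no missingness.
Between-cluster differences are placed either in the lagged-effects
matrices (diff_locus='phi') or in the means (diff_locus='mu'), never
both; person-level parameters are drawn around their cluster's values
with independent Gaussian noise of standard deviation ``within_sd``
(means and lag-1 entries only — lag-2 matrices carry neither
between-cluster differences nor within-cluster variation, so lag-1 and
lag-2 conditions differ only in the number of parameters estimated).

Base values (the package's fixed study conditions): lag-1 autoregressions
of 0.4 with a 0.1 cross-lagged effect of each variable on the next, and
zero means.  Phi-locus differences shift the autoregressive diagonal in
steps of 0.3 centered on 0.4; mu-locus differences shift all means in
steps of 0.6 centered on 0.  Lag-2 conditions add a common 0.1
autoregressive lag-2 effect.  All cluster matrices are verified stable
(companion spectral radius < 1) and person-level draws are redrawn until
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .em import ModelSpec, StartConfig, multi_start_fit
from .evaluate import adjusted_rand_index, align_clusters, parameter_mad
from .panel import LongPanel, make_panel
from .selection import attach_criteria, build_ic_table, select_lag_combination, \
    select_n_clusters
from .varmodel import ClusterParams, companion_spectral_radius

__all__ = [
    "SimDesign",
    "draw_cluster_parameters",
    "draw_person_parameters",
    "simulate_panel",
    "simulate_design",
    "run_study",
]

#: factor levels of the reference simulation design
K_LEVELS = (1, 2, 3)
P_LEVELS = (1, 2)
N_SUBJ_LEVELS = (50, 200)
N_T_LEVELS = (50, 100, 200)
WITHIN_SD_LEVELS = (0.0, 0.03, 0.0424, 0.085)

_BASE_AUTO = 0.4       # lag-1 autoregression shared by all variables
_BASE_CROSS = 0.1      # lag-1 effect of variable j on variable j+1
_PHI_STEP = 0.3        # between-cluster spacing of the autoregressive diagonal
_MU_STEP = 0.6         # between-cluster spacing of every mean
_LAG2_AUTO = 0.1       # common lag-2 autoregression (no cluster differences)
_BURN_IN = 500


@dataclass(frozen=True)
class SimDesign:
    """One cell of the simulation factor grid."""

    K: int = 2
    p: int = 1
    n_subj: int = 50
    n_t: int = 100
    diff_locus: str = "phi"
    within_sd: float = 0.0
    m: int = 6
    seed: int = 0
    n_reps: int = 1

    def __post_init__(self):
        if self.diff_locus not in ("phi", "mu"):
            raise ValueError("diff_locus must be 'phi' or 'mu'")
        if self.K < 1 or self.p < 1 or self.m < 1:
            raise ValueError("K, p and m must be positive")
        if self.within_sd < 0:
            raise ValueError("within_sd must be >= 0")

    @property
    def sigma(self) -> np.ndarray:
        """Innovation covariance: 1 on the diagonal, 0.5 off-diagonal."""
        return 0.5 * np.eye(self.m) + 0.5 * np.ones((self.m, self.m))


def _base_phi1(m: int) -> np.ndarray:
    P = _BASE_AUTO * np.eye(m)
    idx = np.arange(m - 1)
    P[idx, idx + 1] = _BASE_CROSS
    return P


def draw_cluster_parameters(design: SimDesign) -> list[ClusterParams]:
    """True cluster-level parameters for one design cell.

    Between-cluster differences live only in the locus parameter; all
    other parameters are identical across clusters.  Every cluster's
    lagged-effects matrices are stable.
    """
    m, K = design.m, design.K
    offsets = (np.arange(K) - (K - 1) / 2.0)
    clusters = []
    for k in range(K):
        phi1 = _base_phi1(m)
        mu = np.zeros(m)
        if design.diff_locus == "phi":
            phi1 = phi1 + offsets[k] * _PHI_STEP * np.eye(m)
        else:
            mu = mu + offsets[k] * _MU_STEP
        phi = (phi1,) if design.p == 1 else (phi1, _LAG2_AUTO * np.eye(m))
        if companion_spectral_radius(phi) >= 1:
            raise ValueError(
                f"cluster {k} base parameters are unstable (radius >= 1)"
            )
        clusters.append(
            ClusterParams(mu=mu, beta=np.zeros((m, 0)), phi=phi,
                          sigma=design.sigma, tau=1.0 / K)
        )
    return clusters


def draw_person_parameters(
    cluster: ClusterParams, within_sd: float, rng: np.random.Generator
) -> ClusterParams:
    """Person-level parameters around a cluster's values.

    Each mean entry and each lag-1 entry of Phi gets independent
    N(0, within_sd^2) noise; draws are repeated (at most 100 times) until
    the resulting VAR is stable.  ``within_sd = 0`` returns the cluster
    values exactly.
    """
    if within_sd < 0:
        raise ValueError("within_sd must be >= 0")
    if within_sd == 0:
        return cluster
    m = cluster.m
    for _ in range(100):
        mu = cluster.mu + rng.normal(0.0, within_sd, size=m)
        phi1 = cluster.phi[0] + rng.normal(0.0, within_sd, size=(m, m))
        phi = (phi1, *cluster.phi[1:])
        radius = companion_spectral_radius(phi)
        if radius < 1:
            return replace(cluster, mu=mu, phi=phi)
    raise RuntimeError(
        f"no stable person-level draw in 100 attempts (last radius {radius:.3f})"
    )


def simulate_panel(
    person_params: list[ClusterParams],
    sigma: np.ndarray,
    n_t: int,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
    outcome_names: list[str] | None = None,
) -> tuple[LongPanel, np.ndarray]:
    """Simulate one panel from per-person VAR parameters.

    Each person's centered process w_t = sum_a Phi_a w_{t-a} + u_t,
    u_t ~ N(0, Sigma), starts from zero and runs a 500-step burn-in
    before the ``n_t`` retained points; y_t = mu + w_t.  The panel has a
    single day per person with beeps 1..n_t and no missingness.
    """
    m = person_params[0].m
    if labels is None:
        labels = np.zeros(len(person_params), dtype=int)
    names = outcome_names or [f"V{j + 1}" for j in range(m)]
    chol = np.linalg.cholesky(sigma)
    frames = []
    for i, params in enumerate(person_params):
        if companion_spectral_radius(params.phi) >= 1:
            raise ValueError(f"person {i} has unstable lagged effects")
        p = params.p
        total = _BURN_IN + n_t
        u = rng.standard_normal((total, m)) @ chol.T
        w = np.zeros((total + p, m))
        for t in range(total):
            acc = u[t].copy()
            for a in range(p):
                acc += params.phi[a] @ w[t + p - 1 - a]
            w[t + p] = acc
        y = params.mu + w[p + _BURN_IN :]
        df = pd.DataFrame(y, columns=names)
        df.insert(0, "beep", np.arange(1, n_t + 1))
        df.insert(0, "day", 1)
        df.insert(0, "person_id", f"P{i + 1:04d}")
        frames.append(df)
    panel = make_panel(pd.concat(frames, ignore_index=True), outcomes=names)
    return panel, np.asarray(labels, int)


def simulate_design(
    design: SimDesign, seed: int | None = None
) -> tuple[LongPanel, np.ndarray, list[ClusterParams]]:
    """Simulate one replication of a design cell.

    Returns (panel, true labels, true cluster parameters).  Persons are
    assigned to clusters in equal proportions (remainders go to the
    lowest cluster indices) and person-level parameters are drawn with
    the design's within-cluster SD.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    clusters = draw_cluster_parameters(design)
    labels = np.arange(design.n_subj) % design.K
    labels = np.sort(labels)
    person_params = [
        draw_person_parameters(clusters[k], design.within_sd, rng) for k in labels
    ]
    panel, labels = simulate_panel(person_params, design.sigma, design.n_t,
                                   rng, labels)
    return panel, labels, clusters


def run_study(
    designs: list[SimDesign],
    k_max: int | None = None,
    candidate_lags: tuple[int, ...] | None = None,
    n_random: int = 10,
    max_iter: int = 100,
    conv_tol: float = 1e-6,
    select_lags: bool = False,
) -> pd.DataFrame:
    """Scaled-down recovery study over a list of design cells.

    Per replication: simulate; fit K = 1..k_max (default K_true + 1) at
    the true common lag and select K by BIC and ICL; optionally fit all
    lag-order multisets over ``candidate_lags`` at the true K and select
    the combination by HQ and SC; fit the true (K, p) model and record
    the ARI of modal assignments against the generating labels plus
    label-aligned parameter MADs.  Failed replications are recorded with
    their error, never dropped silently.
    """
    rows = []
    for design in designs:
        kmax = k_max or design.K + 1
        rep_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(design.seed).spawn(design.n_reps)
        ]
        for rep in range(design.n_reps):
            rec: dict = {
                "K_true": design.K, "p": design.p, "n_subj": design.n_subj,
                "n_t": design.n_t, "diff_locus": design.diff_locus,
                "within_sd": design.within_sd, "rep": rep, "error": "",
            }
            try:
                panel, labels, truth = simulate_design(design, seed=rep_seeds[rep])
                fits = {}
                for K in range(1, kmax + 1):
                    cfg = StartConfig(n_random=n_random, seed=rep_seeds[rep] + K,
                                      max_iter=max_iter, conv_tol=conv_tol)
                    fit, _ = multi_start_fit(panel, ModelSpec(K, (design.p,) * K),
                                             cfg)
                    fits[K] = attach_criteria(fit)
                table = build_ic_table(list(fits.values()))
                rec["selected_K_bic"] = select_n_clusters(table, "BIC")
                rec["selected_K_icl"] = select_n_clusters(table, "ICL")
                if select_lags:
                    lag_fits = []
                    from .selection import lag_combinations

                    for combo in lag_combinations(design.K,
                                                  candidate_lags or (1, 2)):
                        cfg = StartConfig(n_random=n_random,
                                          seed=rep_seeds[rep] + 97 + sum(combo),
                                          max_iter=max_iter, conv_tol=conv_tol)
                        f, _ = multi_start_fit(panel,
                                               ModelSpec(design.K, combo), cfg)
                        lag_fits.append(attach_criteria(f))
                    ltable = build_ic_table(lag_fits)
                    rec["selected_lags_hq"] = select_lag_combination(
                        ltable, design.K, "HQ")
                    rec["selected_lags_sc"] = select_lag_combination(
                        ltable, design.K, "SC")
                best = fits[design.K]
                rec["ari"] = adjusted_rand_index(best.modal_assignment, labels)
                perm = align_clusters(best.clusters, truth)
                rec["mad_mu"] = parameter_mad(best.clusters, truth, "mu", perm)
                rec["mad_phi"] = parameter_mad(best.clusters, truth, "phi", perm)
                rec["mad_phi_auto"] = parameter_mad(best.clusters, truth,
                                                    "phi_auto", perm)
                rec["mad_phi_cross"] = parameter_mad(best.clusters, truth,
                                                     "phi_cross", perm)
                rec["converged"] = best.converged
                rec["loglik"] = best.loglik
            except Exception as exc:  # noqa: BLE001 - logged, not dropped
                rec["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(rec)
    return pd.DataFrame(rows)
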