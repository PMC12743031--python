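"""Information criteria for latent class VAR model selection.

Two selection problems arise and no single criterion handles both:

* the *lag-order combination* at a fixed number of clusters is chosen by
  cluster-weighted extensions of the Hannan–Quinn (HQ) and Schwarz (SC)
  time-series criteria.  Each cluster contributes its forecasting
  precision, log det(Sigma_k), plus a penalty on the within-cluster lag
  parameters scaled by the cluster's posterior-weighted effective number
  of time points T_k = sum_i pi_{ik} T_{ik}; cluster terms are weighted
  by the prior proportions tau_k:

      HQ = sum_k tau_k [ log det Sigma_k + 2 d_k log log T_k / T_k ]
      SC = sum_k tau_k [ log det Sigma_k +   d_k log T_k     / T_k ]

  with d_k = p_k m^2 lag parameters.  For K = 1 these reduce to the
  classical single-series criteria.

* the *number of clusters* at a fixed common lag order is chosen by BIC
  and ICL on the mixture log-likelihood:

      BIC = -2 l + d log(T_eff)
      ICL = BIC + 2 * entropy(posterior)

  where d counts all free parameters (each cluster's mu, beta, Phi and
  Sigma, plus K - 1 mixing proportions), T_eff is the total number of
  effective time points, and the entropy term penalizes uncertain
  classifications, so ICL >= BIC with equality at 0/1 posteriors.

Models with different lag-order combinations have likelihoods over
different effective samples and are not comparable; mixing them in a
BIC/ICL comparison is a hard error.  Lower is better for all four.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .em import LCVARFit

__all__ = [
    "lag_combinations",
    "compute_hq_sc",
    "compute_bic_icl",
    "attach_criteria",
    "build_ic_table",
    "select_lag_combination",
    "select_n_clusters",
]


def lag_combinations(K: int, candidate_lags) -> list[tuple[int, ...]]:
    """All size-K multisets over the candidate lag orders.

    Cluster order is arbitrary, so (1, 2) and (2, 1) are the same
    combination and are emitted once, sorted ascending.
    """
    lags = sorted(set(int(l) for l in candidate_lags))
    if not lags:
        raise ValueError("candidate lag set is empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    return list(combinations_with_replacement(lags, K))


def _n_free_params(fit: LCVARFit) -> int:
    d = 0
    for c in fit.clusters:
        d += c.m + c.m * c.q + c.p * c.m * c.m + c.m * (c.m + 1) // 2
    return d + (fit.K - 1)


def compute_hq_sc(fit: LCVARFit) -> tuple[float, float]:
    """Cluster-weighted Hannan–Quinn and Schwarz lag-selection criteria."""
    hq = sc = 0.0
    for k, c in enumerate(fit.clusters):
        sign, logdet = np.linalg.slogdet(c.sigma)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"innovation covariance of cluster {k} is not positive definite"
            )
        T_k = float(fit.posterior[:, k] @ fit.effective_T[:, k])
        if T_k <= 1:
            raise ValueError(f"cluster {k} holds too few effective time points")
        d_k = c.p * c.m * c.m
        hq += c.tau * (logdet + 2.0 * d_k * np.log(np.log(T_k)) / T_k)
        sc += c.tau * (logdet + d_k * np.log(T_k) / T_k)
    return float(hq), float(sc)


def compute_bic_icl(fit: LCVARFit) -> tuple[float, float]:
    """BIC and ICL for cluster-number selection at a common lag order."""
    if fit.spec.common_lag is None:
        raise ValueError(
            "BIC/ICL require one common lag order across clusters; "
            f"got lags {fit.spec.lags} (cross-lag likelihoods are not comparable)"
        )
    T_eff = float(fit.effective_T[:, 0].sum())
    d = _n_free_params(fit)
    bic = -2.0 * fit.loglik + d * np.log(T_eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(fit.posterior > 0,
                         fit.posterior * np.log(fit.posterior), 0.0)
    entropy = -float(plogp.sum())
    icl = bic + 2.0 * entropy
    return float(bic), float(icl)


def attach_criteria(fit: LCVARFit) -> LCVARFit:
    """Populate ``fit.criteria`` with HQ/SC (always) and BIC/ICL (when the
    lag order is common across clusters)."""
    hq, sc = compute_hq_sc(fit)
    fit.criteria.update(HQ=hq, SC=sc)
    if fit.spec.common_lag is not None:
        bic, icl = compute_bic_icl(fit)
        fit.criteria.update(BIC=bic, ICL=icl)
    return fit


def build_ic_table(fits: list[LCVARFit]) -> pd.DataFrame:
    """One row per fitted candidate model with its criteria."""
    rows = []
    for f in fits:
        if not f.criteria:
            attach_criteria(f)
        rows.append(
            dict(
                K=f.K,
                lags=f.spec.lags,
                loglik=f.loglik,
                n_params=_n_free_params(f),
                total_effective_T=float(f.effective_T[:, 0].sum()),
                HQ=f.criteria.get("HQ", np.nan),
                SC=f.criteria.get("SC", np.nan),
                BIC=f.criteria.get("BIC", np.nan),
                ICL=f.criteria.get("ICL", np.nan),
                converged=f.converged,
            )
        )
    return pd.DataFrame(rows)


def select_lag_combination(
    table: pd.DataFrame, K: int, criterion: str = "HQ"
) -> tuple[int, ...]:
    """Lag multiset minimizing HQ or SC among fits with the given K.

    Ties break toward the smaller total number of lags.
    """
    if criterion not in ("HQ", "SC"):
        raise ValueError("criterion must be 'HQ' or 'SC'")
    sub = table[table["K"] == K]
    if sub.empty:
        raise ValueError(f"no candidate models with K={K}")
    if sub["K"].nunique() != 1:  # pragma: no cover - guarded by filter
        raise ValueError("HQ/SC comparisons require equal K")
    order = sub.assign(total_lags=sub["lags"].map(sum)).sort_values(
        [criterion, "total_lags"], kind="mergesort"
    )
    return tuple(order.iloc[0]["lags"])


def select_n_clusters(table: pd.DataFrame, criterion: str = "ICL") -> int:
    """Number of clusters minimizing BIC or ICL among common-lag fits.

    All rows must share one lag order; ties break toward smaller K.
    """
    if criterion not in ("BIC", "ICL"):
        raise ValueError("criterion must be 'BIC' or 'ICL'")
    if table.empty:
        raise ValueError("empty candidate table")
    lag_sets = {tuple(sorted(set(l))) for l in table["lags"]}
    if len(lag_sets) != 1 or len(next(iter(lag_sets))) != 1:
        raise ValueError(
            "cluster-number selection requires a single common lag order "
            f"across all candidates; got {sorted(lag_sets)}"
        )
    order = table.sort_values([criterion, "K"], kind="mergesort")
    return int(order.iloc[0]["K"])
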