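"""Recovery and fit metrics for latent class VAR models.

Covers the measures used to judge a clustering of multivariate time
series: the Hubert–Arabie adjusted Rand index between partitions,
label-aligned mean absolute deviation of parameters, model-selection
recovery rates, and per-person one-step-ahead R-squared.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy.special import comb

from .em import LCVARFit
from .panel import LongPanel
from .varmodel import ClusterParams, build_regression_data

__all__ = [
    "adjusted_rand_index",
    "align_clusters",
    "parameter_mad",
    "recovery_rates",
    "variance_explained",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Computed from the pair-counting contingency table; 1 for identical
    partitions (up to relabeling), ~0 expected under chance, can be
    negative for worse-than-chance agreement.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_cells = comb(table, 2).sum()
    sum_rows = comb(table.sum(axis=1), 2).sum()
    sum_cols = comb(table.sum(axis=0), 2).sum()
    n_pairs = comb(a.size, 2)
    expected = sum_rows * sum_cols / n_pairs
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions put everything in one block
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def align_clusters(
    est: list[ClusterParams], truth: list[ClusterParams]
) -> tuple[int, ...]:
    """Permutation of the estimated clusters minimizing total absolute
    parameter deviation (mu and Phi) from the true clusters.

    Exhaustive over K! permutations; intended for K <= 6.
    """
    if len(est) != len(truth):
        raise ValueError("cluster counts differ")
    K = len(est)
    if est[0].m != truth[0].m:
        raise ValueError("variable counts differ")

    def dist(e: ClusterParams, t: ClusterParams) -> float:
        d = np.abs(e.mu - t.mu).sum()
        for a in range(min(e.p, t.p)):
            d += np.abs(e.phi[a] - t.phi[a]).sum()
        return d

    D = np.array([[dist(e, t) for t in truth] for e in est])
    best, best_cost = None, np.inf
    for perm in permutations(range(K)):
        cost = sum(D[perm[k], k] for k in range(K))
        if cost < best_cost:
            best, best_cost = perm, cost
    return tuple(best)


def parameter_mad(
    est: list[ClusterParams],
    truth: list[ClusterParams],
    which: str = "mu",
    alignment: tuple[int, ...] | None = None,
) -> float:
    """Mean absolute deviation between aligned estimated and true
    parameters, pooled entry-wise with equal weight across clusters.

    ``which``: 'mu', 'phi' (all lag entries), 'phi_auto' (diagonals of
    each lag matrix) or 'phi_cross' (off-diagonals).
    """
    if alignment is None:
        alignment = align_clusters(est, truth)
    est = [est[j] for j in alignment]
    devs: list[np.ndarray] = []
    for e, t in zip(est, truth):
        if which == "mu":
            if e.mu.shape != t.mu.shape:
                raise ValueError("mu shape mismatch")
            devs.append(np.abs(e.mu - t.mu).ravel())
        elif which in ("phi", "phi_auto", "phi_cross"):
            if e.p != t.p or e.m != t.m:
                raise ValueError("phi shape mismatch")
            for a in range(e.p):
                d = np.abs(e.phi[a] - t.phi[a])
                if which == "phi_auto":
                    devs.append(np.diag(d))
                elif which == "phi_cross":
                    devs.append(d[~np.eye(e.m, dtype=bool)])
                else:
                    devs.append(d.ravel())
        else:
            raise ValueError(f"unknown parameter selector {which!r}")
    return float(np.concatenate(devs).mean())


def recovery_rates(selected, truth: int) -> tuple[float, float, float]:
    """(accuracy, over_rate, under_rate) of selected model sizes."""
    sel = np.asarray(list(selected))
    if sel.size == 0:
        raise ValueError("empty selection list")
    return (
        float((sel == truth).mean()),
        float((sel > truth).mean()),
        float((sel < truth).mean()),
    )


def variance_explained(panel: LongPanel, fit: LCVARFit) -> pd.DataFrame:
    """One-step-ahead R-squared per (person, variable).

    Predictions use the person's modal cluster parameters (including any
    covariate contribution) on that cluster's predictable rows;
    R^2 = 1 - var(residual) / var(observed) over those rows.  Values can
    be negative (the VAR predicts worse than the person's mean) and are
    reported as-is; persons with fewer than 3 predictable rows get NaN.
    A ``cluster`` column supports per-cluster and overall averaging.
    """
    modal = fit.modal_assignment
    reg = {p: build_regression_data(panel, p) for p in set(fit.spec.lags)}
    rows = []
    for i, person in enumerate(fit.persons):
        k = int(modal[i])
        params = fit.clusters[k]
        data = reg[params.p]
        sel = data.person == i
        rec = {"person": person, "cluster": k}
        if sel.sum() < 3:
            for j, v in enumerate(panel.outcomes):
                rec[v] = np.nan
            rows.append(rec)
            continue
        mean = np.broadcast_to(params.mu, data.Y[sel].shape).copy()
        if params.q:
            mean = mean + data.X[sel] @ params.beta.T
        for a in range(params.p):
            centered = data.L[sel, a, :] - params.mu
            if params.q:
                centered = centered - data.XL[sel, a, :] @ params.beta.T
            mean = mean + centered @ params.phi[a].T
        resid = data.Y[sel] - mean
        var_y = data.Y[sel].var(axis=0)
        var_r = resid.var(axis=0)
        r2 = np.where(var_y > 0, 1.0 - var_r / np.where(var_y > 0, var_y, 1.0),
                      np.nan)
        for j, v in enumerate(panel.outcomes):
            rec[v] = r2[j]
        rows.append(rec)
    return pd.DataFrame(rows)
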