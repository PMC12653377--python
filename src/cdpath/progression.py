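"""Ability-scaled, tiered learning progression.

Three steps turn the categorical knowledge states into a macro-level
progression: (1) each rare state is absorbed into its nearest dominant
state by Hamming distance on the mastery vectors (a single nearest-centroid
assignment with the dominant states as fixed centers — no centroid
updates); (2) a unidimensional two-parameter logistic (2PL) IRT model is
fitted to the raw responses by marginal maximum likelihood and each
examinee receives an EAP ability theta under a standard-normal prior;
(3) cluster-mean thetas order the states on the ability continuum, which is
cut into tiers either at user-supplied boundaries or into equal-count
groups.

The 2PL IRF is P(x=1 | theta) = 1 / (1 + exp(-a_j (theta - b_j))) with
discrimination a_j and difficulty b_j; the latent scale is identified by
the N(0,1) prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .models import string_to_profile
from .qmatrix import ResponseMatrix

logger = logging.getLogger("cdpath")

__all__ = [
    "TwoPLFit",
    "ProgressionTable",
    "assign_rare_states",
    "fit_2pl",
    "state_ability_table",
    "set_levels",
]


@dataclass(frozen=True)
class TwoPLFit:
    discrimination: np.ndarray     # a_j
    difficulty: np.ndarray         # b_j
    theta: np.ndarray              # per-examinee EAP ability
    kept_items: np.ndarray         # indices of items retained in the fit
    loglik: float
    converged: bool
    n_iter: int
    quad_nodes: np.ndarray
    quad_weights: np.ndarray


@dataclass(frozen=True)
class ProgressionTable:
    """Per-state ability summary with cluster membership and tier labels."""

    rows: pd.DataFrame             # columns: state, n, mean_theta, tier
    boundaries: tuple[float, ...]  # theta cut points between tiers

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("tier boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)


def assign_rare_states(rare: dict, centers: dict) -> dict:
    """Map each rare state to its nearest dominant state.

    Distance is squared Euclidean on the 0/1 mastery vectors, i.e. Hamming
    distance.  Ties go to the higher-count center, then to the
    lexicographically smallest center string.  Centers map to themselves.
    """
    if not centers:
        raise ValueError("no centers to assign to")
    center_states = sorted(centers)
    cmat = np.array([string_to_profile(s) for s in center_states])
    mapping = {s: s for s in center_states}
    for s in rare:
        if s in mapping:
            continue
        v = string_to_profile(s)
        d = np.abs(cmat - v).sum(axis=1)
        dmin = d.min()
        tied = [center_states[i] for i in np.flatnonzero(d == dmin)]
        if len(tied) > 1:
            best_count = max(centers[c] for c in tied)
            tied = sorted(c for c in tied if centers[c] == best_count)
            logger.info(
                "rare state %s equidistant from several centers; chose %s",
                s, tied[0],
            )
        mapping[s] = tied[0]
    return mapping


def _quadrature(n_nodes: int, bound: float):
    nodes = np.linspace(-bound, bound, n_nodes)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


def fit_2pl(
    data: ResponseMatrix,
    *,
    n_quad: int = 61,
    bound: float = 6.0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> TwoPLFit:
    """Marginal maximum likelihood 2PL fit with EAP ability estimates.

    Fixed rectangular quadrature (``n_quad`` nodes on [-bound, bound]) under
    a standard-normal prior; the M-step runs damped Newton updates of each
    item's slope-intercept parameters against the expected node-level
    counts.  Items with zero score variance are dropped with a warning.
    """
    X_all = data.entries.astype(float)
    if X_all.shape[0] < 2:
        raise ValueError("need at least two examinees")
    variances = X_all.var(axis=0)
    kept = np.flatnonzero(variances > 0)
    if kept.size < X_all.shape[1]:
        warnings.warn(
            f"dropping {X_all.shape[1] - kept.size} constant item(s) from the "
            "2PL fit",
            UserWarning,
        )
    if kept.size == 0:
        raise ValueError("no items with score variance")
    X = X_all[:, kept]
    N, J = X.shape
    nodes, wq = _quadrature(n_quad, bound)
    logw = np.log(wq)

    a = np.ones(J)
    pbar = X.mean(axis=0).clip(0.02, 0.98)
    d = np.log(pbar / (1 - pbar))  # intercepts: logit P = a*theta + d

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Z = np.outer(nodes, a) + d          # Q x J
        P = expit(Z).clip(1e-9, 1 - 1e-9)
        L = X @ np.log(P).T + (1 - X) @ np.log1p(-P).T + logw  # N x Q
        m = L.max(axis=1, keepdims=True)
        W = np.exp(L - m)
        s = W.sum(axis=1, keepdims=True)
        new_loglik = float(np.sum(m + np.log(s)))
        post = W / s                        # N x Q
        nq = post.sum(axis=0)               # expected count per node
        rq = post.T @ X                     # Q x J expected correct per node
        max_change = 0.0
        for j in range(J):
            aj, dj = a[j], d[j]
            for _ in range(5):
                p = expit(aj * nodes + dj).clip(1e-9, 1 - 1e-9)
                resid = rq[:, j] - nq * p
                g = np.array([resid @ nodes, resid.sum()])
                wgt = nq * p * (1 - p)
                H = np.array(
                    [
                        [wgt @ (nodes ** 2), wgt @ nodes],
                        [wgt @ nodes, wgt.sum()],
                    ]
                )
                try:
                    step = np.linalg.solve(H + 1e-10 * np.eye(2), g)
                except np.linalg.LinAlgError:
                    break
                step = np.clip(step, -1.0, 1.0)  # damp early wild steps
                aj, dj = aj + step[0], dj + step[1]
                if np.max(np.abs(step)) < 1e-8:
                    break
            max_change = max(max_change, abs(aj - a[j]), abs(dj - d[j]))
            a[j], d[j] = aj, dj
        if max_change < tol and new_loglik - loglik < 1e-6 * max(1, abs(loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    if not converged:
        warnings.warn(f"2PL EM did not converge in {it} iterations", RuntimeWarning)

    Z = np.outer(nodes, a) + d
    P = expit(Z).clip(1e-9, 1 - 1e-9)
    L = X @ np.log(P).T + (1 - X) @ np.log1p(-P).T + logw
    m = L.max(axis=1, keepdims=True)
    W = np.exp(L - m)
    post = W / W.sum(axis=1, keepdims=True)
    theta = post @ nodes
    b = -d / a
    return TwoPLFit(
        discrimination=a,
        difficulty=b,
        theta=theta,
        kept_items=kept,
        loglik=float(np.sum(m + np.log(W.sum(axis=1, keepdims=True)))),
        converged=converged,
        n_iter=it,
        quad_nodes=nodes,
        quad_weights=wq,
    )


def state_ability_table(
    map_states, cluster_of: dict, theta: np.ndarray
) -> pd.DataFrame:
    """Mean EAP theta per cluster-center state, with examinee counts.

    ``map_states`` are per-examinee MAP state strings, ``cluster_of`` maps
    every observed state to its center (see :func:`assign_rare_states`), and
    ``theta`` holds per-examinee abilities in the same order.
    """
    theta = np.asarray(theta, dtype=float)
    if len(map_states) != theta.size:
        raise ValueError("map_states and theta lengths differ")
    centers = np.array([cluster_of[s] for s in map_states])
    rows = []
    for c in sorted(set(cluster_of.values())):
        mask = centers == c
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"cluster {c} received no examinees; excluded", UserWarning)
            continue
        rows.append(
            {
                "state": c,
                "level": int(string_to_profile(c).sum()),
                "n": n,
                "mean_theta": float(theta[mask].mean()),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_theta").reset_index(drop=True)


def _weighted_quantile_boundaries(values, weights, n_tiers):
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w) / w.sum()
    bounds = []
    for t in range(1, n_tiers):
        target = t / n_tiers
        idx = int(np.searchsorted(cum, target))
        idx = min(idx, len(v) - 2)
        bounds.append(float((v[idx] + v[idx + 1]) / 2))
    return bounds


def set_levels(
    table: pd.DataFrame,
    n_tiers: int = 3,
    boundaries=None,
) -> ProgressionTable:
    """Assign each state a tier on the theta scale.

    With explicit ``boundaries`` (length n_tiers - 1, strictly increasing)
    tier t collects states with mean theta in (b_{t-1}, b_t].  Without
    boundaries, cut points are weighted quantiles of the state means
    (weights = examinee counts), giving roughly equal-count tiers.
    """
    if table.empty:
        raise ValueError("empty progression table")
    if n_tiers < 1:
        raise ValueError("n_tiers must be >= 1")
    if boundaries is not None:
        boundaries = [float(b) for b in boundaries]
        if sorted(boundaries) != boundaries or len(set(boundaries)) != len(boundaries):
            raise ValueError("boundaries must be strictly increasing")
    elif n_tiers == 1:
        boundaries = []
    else:
        boundaries = _weighted_quantile_boundaries(
            table["mean_theta"].to_numpy(), table["n"].to_numpy(), n_tiers
        )
        logger.info("equal-count tier boundaries: %s", boundaries)
    tier = 1 + np.searchsorted(boundaries, table["mean_theta"].to_numpy(), side="left")
    out = table.copy()
    out["tier"] = tier.astype(int)
    return ProgressionTable(rows=out, boundaries=tuple(boundaries))
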