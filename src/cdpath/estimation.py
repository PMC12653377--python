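"""Marginal maximum likelihood EM for (possibly mixed) diagnostic models.

The observed-data likelihood is a finite mixture over the 2^K knowledge
states: L_i = sum_c pi_c prod_j P_j(alpha_c)^{x_ij} (1-P_j(alpha_c))^{1-x_ij}.
The E-step computes each examinee's posterior over states; the M-step
updates the mixing proportions as mean posteriors and each item's
parameters by posterior-weighted maximization.  For the saturated G-DINA
family the item update is closed form (each reduced-profile success
probability is the posterior-weighted proportion correct in that group);
DINA/DINO collapse the groups to two and are also closed form; the additive
families (ACDM/LLM/RRUM) take damped Fisher-scoring steps on the link
scale, accepting only feasible, non-decreasing steps so EM monotonicity is
preserved (a generalized EM).

Examinees are classified by maximum a posteriori (MAP): the single state
with the highest posterior mass, ties broken toward the lower class index
(and logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .models import (
    PROB_FLOOR,
    ItemParameterSet,
    gdina_design,
    item_class_probs,
    profile_space,
    profile_to_string,
    reduced_index_map,
)
from .qmatrix import QMatrix, ResponseMatrix

logger = logging.getLogger("cdpath")

__all__ = [
    "MixedCDMFit",
    "PosteriorClassification",
    "FitIndices",
    "em_fit",
    "classify",
    "fit_indices",
    "classification_reliability",
]

_PMIN = 1e-4  # feasibility margin for link-scale item updates


@dataclass(frozen=True)
class MixedCDMFit:
    """Result of an EM fit: per-item parameters plus the class distribution."""

    items: tuple[ItemParameterSet, ...]
    class_probs: np.ndarray            # pi over the 2^K classes
    loglik: float
    n_params: int
    n_obs: int
    n_attributes: int
    trace: np.ndarray                  # per-iteration marginal loglik
    converged: bool
    n_iter: int

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def item_probs(self) -> np.ndarray:
        """J x 2^K success probabilities over the full class space."""
        return item_class_probs(self.items, self.n_attributes)


@dataclass(frozen=True)
class PosteriorClassification:
    """Posterior over knowledge states and the derived MAP classification."""

    posterior: np.ndarray              # N x 2^K, rows sum to 1
    map_index: np.ndarray              # N, class index of the MAP state
    map_prob: np.ndarray               # N, posterior mass of the MAP state
    marginal_mastery: np.ndarray       # N x K, per-attribute posterior mastery
    n_attributes: int
    examinee_ids: tuple[str, ...] = field(default=())

    @property
    def map_states(self) -> list[str]:
        space = profile_space(self.n_attributes)
        return [profile_to_string(space[c]) for c in self.map_index]


@dataclass(frozen=True)
class FitIndices:
    aic: float
    bic: float
    deviance: float
    rmsea: float
    item_rmsea: np.ndarray
    cronbach_alpha: float


# ---------------------------------------------------------------------------
# per-family M-step machinery
# ---------------------------------------------------------------------------

def _link_fns(family):
    if family in ("ACDM",):
        return (lambda p: p), (lambda z: z)
    if family == "LLM":
        return logit, expit
    if family == "RRUM":
        return np.log, np.exp
    raise ValueError(family)


def _additive_design(n_required: int) -> np.ndarray:
    red = profile_space(n_required).astype(float)
    return np.column_stack([np.ones(red.shape[0]), red])


def _expected_loglik(p, R, N):
    p = np.clip(p, PROB_FLOOR, 1 - PROB_FLOOR)
    return float(np.sum(R * np.log(p) + (N - R) * np.log1p(-p)))


def _fisher_step(family, Z, beta, R, N, max_inner=25):
    """Damped Fisher scoring on link-scale coefficients.

    Candidate steps are projected onto nonnegative main effects (in the
    additive families, mastering an attribute may not lower the success
    probability — their standard interpretation, and what keeps attribute
    labels from drifting during long EM runs).  A step is accepted only if
    the implied probabilities stay inside (PMIN, 1-PMIN) and the expected
    complete-data log-likelihood does not decrease; otherwise it is halved
    (up to 20 times) and finally rejected, leaving beta unchanged.
    """
    link, linkinv = _link_fns(family)
    for _ in range(max_inner):
        p = np.clip(linkinv(Z @ beta), _PMIN, 1 - _PMIN)
        obj = _expected_loglik(p, R, N)
        resid = R - N * p
        if family == "LLM":
            score = Z.T @ resid
            w = N * p * (1 - p)
        elif family == "ACDM":
            score = Z.T @ (resid / (p * (1 - p)))
            w = N / (p * (1 - p))
        else:  # RRUM, log link
            score = Z.T @ (resid / (1 - p))
            w = N * p / (1 - p)
        info = Z.T @ (w[:, None] * Z)
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(len(beta)), score)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        t, accepted = 1.0, False
        for _half in range(20):
            cand = beta + t * step
            cand[1:] = np.maximum(cand[1:], 0.0)
            pc = linkinv(Z @ cand)
            if np.all(pc > _PMIN) and np.all(pc < 1 - _PMIN):
                if _expected_loglik(pc, R, N) >= obj - 1e-12:
                    beta, accepted = cand, True
                    break
            t *= 0.5
        if not accepted or np.max(np.abs(t * step)) < 1e-9:
            break
    return beta


def _feasible_beta_init(family, Z, p_target):
    """Link-scale least squares toward p_target, shrunk into feasibility."""
    link, linkinv = _link_fns(family)
    p_target = np.clip(p_target, 0.02, 0.98)
    beta, *_ = np.linalg.lstsq(Z, link(p_target), rcond=None)
    beta[1:] = np.maximum(beta[1:], 0.0)
    safe = np.zeros_like(beta)
    safe[0] = link(np.clip(p_target.mean(), 0.05, 0.95))
    t = 1.0
    for _ in range(30):
        cand = safe + t * (beta - safe)
        p = linkinv(Z @ cand)
        if np.all(p > _PMIN) and np.all(p < 1 - _PMIN):
            return cand
        t *= 0.5
    return safe


class _ItemState:
    """Mutable per-item state during EM (probabilities + coefficients)."""

    def __init__(self, family, required, n_attributes, rng, p_init=None):
        self.family = family
        self.required = tuple(int(a) for a in required)
        self.k = len(self.required)
        self.rmap = reduced_index_map(self.required, n_attributes)
        self.n_reduced = 2 ** self.k
        red = profile_space(self.k)
        self.mastered = red.sum(axis=1)
        self.eta_dina = red.all(axis=1)
        self.eta_dino = red.any(axis=1)
        if p_init is not None:
            p0 = np.clip(np.asarray(p_init, dtype=float), 0.02, 0.98)
        else:
            # default init: success probability rises linearly 0.2 -> 0.8 in
            # the number of mastered required attributes, with seeded jitter
            base = 0.2 + 0.6 * self.mastered / self.k
            p0 = np.clip(
                base + rng.uniform(-0.05, 0.05, self.n_reduced), 0.05, 0.95
            )
        self.Z = _additive_design(self.k)
        self.beta = None
        if family in ("ACDM", "LLM", "RRUM"):
            self.beta = _feasible_beta_init(family, self.Z, p0)
            _, linkinv = _link_fns(family)
            self.p = np.clip(linkinv(self.Z @ self.beta), _PMIN, 1 - _PMIN)
        elif family in ("DINA", "DINO"):
            g = float(p0[0])
            s = float(1 - p0[-1])
            eta = self.eta_dina if family == "DINA" else self.eta_dino
            self.p = np.where(eta, 1 - s, g)
        else:
            self.p = p0

    @property
    def n_free(self) -> int:
        return {"GDINA": self.n_reduced, "DINA": 2, "DINO": 2}.get(
            self.family, self.k + 1
        )

    def class_probs(self) -> np.ndarray:
        return self.p[self.rmap]

    def update(self, R_red, N_red):
        """Posterior-weighted M-step; returns max |delta p|."""
        old = self.p.copy()
        N_safe = np.maximum(N_red, PROB_FLOOR)
        if self.family == "GDINA":
            self.p = np.clip(R_red / N_safe, _PMIN, 1 - _PMIN)
        elif self.family in ("DINA", "DINO"):
            eta = self.eta_dina if self.family == "DINA" else self.eta_dino
            hi = float(R_red[eta].sum() / max(N_red[eta].sum(), PROB_FLOOR))
            lo = float(R_red[~eta].sum() / max(N_red[~eta].sum(), PROB_FLOOR))
            g = np.clip(lo, _PMIN, 1 - _PMIN)
            one_minus_s = np.clip(hi, _PMIN, 1 - _PMIN)
            self.p = np.where(eta, one_minus_s, g)
        else:
            self.beta = _fisher_step(self.family, self.Z, self.beta, R_red, N_red)
            _, linkinv = _link_fns(self.family)
            self.p = np.clip(linkinv(self.Z @ self.beta), _PMIN, 1 - _PMIN)
        return float(np.max(np.abs(self.p - old)))

    def to_parameter_set(self, label) -> ItemParameterSet:
        if self.family == "GDINA":
            params = np.linalg.solve(gdina_design(self.k), self.p)
        elif self.family in ("DINA", "DINO"):
            eta = self.eta_dina if self.family == "DINA" else self.eta_dino
            params = np.array([self.p[~eta][0], 1 - self.p[eta][0]])
        else:
            params = self.beta.copy()
        return ItemParameterSet(self.family, self.required, params, label=label)


# ---------------------------------------------------------------------------
# E-step / likelihood
# ---------------------------------------------------------------------------

def _posterior_rows(X, P, log_pi):
    """Posterior over classes and per-row marginal log-likelihoods.

    ``X`` is N x J, ``P`` is J x C (class-conditional success probabilities).
    """
    Pc = np.clip(P, PROB_FLOOR, 1 - PROB_FLOOR)
    logP = np.log(Pc)
    log1mP = np.log1p(-Pc)
    L = X @ logP + (1.0 - X) @ log1mP + log_pi  # N x C
    m = L.max(axis=1, keepdims=True)
    W = np.exp(L - m)
    s = W.sum(axis=1, keepdims=True)
    return W / s, (m + np.log(s)).ravel()


def _posterior_matrix(X, P, log_pi):
    """Posterior over classes and the total marginal log-likelihood."""
    post, rows = _posterior_rows(X, P, log_pi)
    return post, float(rows.sum())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _resolve_families(families, q: QMatrix):
    J = q.n_items
    if families is None:
        return ["GDINA"] * J
    if isinstance(families, str):
        return [families] * J
    if isinstance(families, dict):
        return [families.get(lab, "GDINA") for lab in q.item_labels]
    families = list(families)
    if len(families) != J:
        raise ValueError("family assignment length does not match item count")
    return families


def em_fit(
    data: ResponseMatrix,
    q: QMatrix,
    families=None,
    *,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int = 0,
    init_probs=None,
    init_class_probs=None,
) -> MixedCDMFit:
    """Fit a mixed diagnostic model by marginal maximum likelihood EM.

    Parameters
    ----------
    families
        ``None`` (all saturated G-DINA), a single family name, a per-item
        list, or a dict keyed by item label.
    tol
        convergence threshold on the maximum absolute change of any item
        success probability or mixing proportion.
    seed
        seeds the jittered initialization only; the algorithm itself is
        deterministic.
    init_probs
        optional warm start: per-item reduced-profile success probabilities
        (length-J list of arrays).  Constrained families project them onto
        their link scale.  Used when refitting a mixed model from a
        saturated solution, which pins the attribute labeling.
    init_class_probs
        optional warm start for the mixing proportions.
    """
    if data.n_items != q.n_items:
        raise ValueError("response matrix and Q-matrix disagree on item count")
    if data.n_examinees < 2:
        raise ValueError("need at least two examinees")
    fams = _resolve_families(families, q)
    K = q.n_attributes
    C = 2 ** K
    rng = np.random.default_rng(seed)
    states = [
        _ItemState(
            f, q.required_attributes(j), K, rng,
            p_init=None if init_probs is None else init_probs[j],
        )
        for j, f in enumerate(fams)
    ]
    N, J = data.entries.shape
    # EM cost scales with the number of distinct response patterns, not N
    Xu, counts = np.unique(data.entries, axis=0, return_counts=True)
    X = Xu.astype(float)
    w = counts.astype(float)
    wX = w[:, None] * X
    if init_class_probs is None:
        pi = np.full(C, 1.0 / C)
    else:
        pi = np.asarray(init_class_probs, dtype=float)
        pi = pi / pi.sum()

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = np.stack([st.class_probs() for st in states], axis=0)  # J x C
        post, rows = _posterior_rows(X, P, np.log(np.clip(pi, PROB_FLOOR, 1)))
        trace.append(float(rows @ w))
        Nc = w @ post                              # expected class counts
        Rc = post.T @ wX                           # C x J expected correct
        new_pi = Nc / N
        delta = float(np.max(np.abs(new_pi - pi)))
        pi = new_pi
        for j, st in enumerate(states):
            N_red = np.bincount(st.rmap, weights=Nc, minlength=st.n_reduced)
            R_red = np.bincount(st.rmap, weights=Rc[:, j], minlength=st.n_reduced)
            delta = max(delta, st.update(R_red, N_red))
        if delta < tol:
            converged = True
            break
    P = np.stack([st.class_probs() for st in states], axis=0)
    _, rows = _posterior_rows(X, P, np.log(np.clip(pi, PROB_FLOOR, 1)))
    loglik = float(rows @ w)
    trace.append(loglik)
    if not converged:
        warnings.warn(
            f"EM did not converge in {it} iterations (last delta above tol)",
            RuntimeWarning,
        )
    items = tuple(
        st.to_parameter_set(q.item_labels[j]) for j, st in enumerate(states)
    )
    n_params = sum(st.n_free for st in states) + (C - 1)
    return MixedCDMFit(
        items=items,
        class_probs=pi,
        loglik=loglik,
        n_params=n_params,
        n_obs=N,
        n_attributes=K,
        trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def classify(fit: MixedCDMFit, data: ResponseMatrix) -> PosteriorClassification:
    """MAP classification of each examinee into a knowledge state."""
    if data.n_items != len(fit.items):
        raise ValueError("fit and data disagree on item count")
    X = data.entries.astype(float)
    P = fit.item_probs()  # J x C
    post, _ = _posterior_matrix(X, P, np.log(np.clip(fit.class_probs, PROB_FLOOR, 1)))
    map_index = post.argmax(axis=1)  # argmax takes the lowest index on ties
    map_prob = post[np.arange(post.shape[0]), map_index]
    row_max_count = (post == map_prob[:, None]).sum(axis=1)
    n_ties = int((row_max_count > 1).sum())
    if n_ties:
        logger.info("MAP ties for %d examinee(s); broke toward lower class index", n_ties)
    space = profile_space(fit.n_attributes).astype(float)
    marginal = post @ space
    return PosteriorClassification(
        posterior=post,
        map_index=map_index,
        map_prob=map_prob,
        marginal_mastery=marginal,
        n_attributes=fit.n_attributes,
        examinee_ids=data.examinee_ids,
    )


def cronbach_alpha(X: np.ndarray) -> float:
    """Cronbach's alpha on raw item scores (sample variances, ddof=1)."""
    X = np.asarray(X, dtype=float)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    J = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    return float(J / (J - 1) * (1.0 - item_var / total_var))


def fit_indices(fit: MixedCDMFit, data: ResponseMatrix) -> FitIndices:
    """Deviance/AIC/BIC, mean item RMSEA, and Cronbach's alpha.

    Item RMSEA compares the model's class-conditional success probabilities
    with the posterior-weighted observed proportions correct:
    RMSEA_j = sqrt( sum_c pi_c (P_j(alpha_c) - Ptilde_jc)^2 ), averaged over
    items for the overall index.
    """
    X = data.entries.astype(float)
    P = fit.item_probs()  # J x C
    post, _ = _posterior_matrix(
        X, P, np.log(np.clip(fit.class_probs, PROB_FLOOR, 1))
    )
    Nc = post.sum(axis=0)
    Rc = post.T @ X  # C x J
    with np.errstate(invalid="ignore", divide="ignore"):
        Ptilde = (Rc / Nc[:, None]).T  # J x C
    empty = Nc < 1e-8
    Ptilde[:, empty] = P[:, empty]  # empty classes contribute no misfit
    item_rmsea = np.sqrt(((P - Ptilde) ** 2 @ fit.class_probs))
    deviance = -2.0 * fit.loglik
    aic = deviance + 2.0 * fit.n_params
    bic = deviance + fit.n_params * np.log(fit.n_obs)
    return FitIndices(
        aic=float(aic),
        bic=float(bic),
        deviance=float(deviance),
        rmsea=float(item_rmsea.mean()),
        item_rmsea=item_rmsea,
        cronbach_alpha=cronbach_alpha(X),
    )


def classification_reliability(
    fit: MixedCDMFit,
    n_examinees: int = 2000,
    n_reps: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Simulation-based attribute classification reliability.

    Draws simulees from the fitted class distribution, generates responses
    from the fitted IRFs, re-classifies them by MAP with the same fitted
    parameters, and reports the per-attribute agreement rate between
    generating and recovered mastery, averaged over replications.

    Returns ``(per_attribute, mean)``.
    """
    rng = np.random.default_rng(seed)
    K = fit.n_attributes
    space = profile_space(K)
    P = fit.item_probs()  # J x C
    pi = fit.class_probs / fit.class_probs.sum()
    agree = np.zeros(K)
    for _ in range(n_reps):
        cls = rng.choice(len(pi), size=n_examinees, p=pi)
        probs = P[:, cls].T  # N x J
        X = (rng.random(probs.shape) < probs).astype(np.int8)
        sim = ResponseMatrix(X)
        est = classify(fit, sim)
        agree += (space[est.map_index] == space[cls]).mean(axis=0)
    per_attr = agree / n_reps
    return per_attr, float(per_attr.mean())
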