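"""Item-level Wald tests against saturated G-DINA and mixed-model assembly.

Each reduced family is a set of linear restrictions on (a link transform
of) the item's reduced-profile success probabilities p = (p_1..p_{2^{K*}}):

* DINA / DINO — all non-distinguished profiles share one probability
  (every profile except the all-mastered one for DINA, except the
  none-mastered one for DINO): df = 2^{K*} - 2, identity scale.
* ACDM / LLM / RRUM — all interaction coefficients of the saturated
  decomposition vanish on the identity / logit / log scale:
  df = 2^{K*} - K* - 1.

The statistic is W = (C f(p))' (C Sigma_f C')^{-1} (C f(p)) with Sigma_f
obtained from the covariance of p by the delta method; the covariance of p
comes from the posterior-weighted outer-product (empirical) information of
the saturated EM solution.  W is referred to chi-square with df degrees of
freedom.

Selection per item follows four rules: (1) admit reduced families with
p > alpha; (2) among admitted, keep the highest p-value; (3) optionally
prefer DINA/DINO among the admitted when parsimony is prioritised;
(4) fall back to saturated G-DINA when nothing is admitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit
from scipy.stats import chi2

from .estimation import MixedCDMFit, em_fit, _posterior_matrix
from .models import PROB_FLOOR, gdina_design, reduced_index_map
from .qmatrix import QMatrix, ResponseMatrix

logger = logging.getLogger("cdpath")

__all__ = [
    "WaldResult",
    "MixedModelPlan",
    "wald_test",
    "select_item_model",
    "build_mixed_model",
]

REDUCED_FAMILIES = ("DINA", "DINO", "ACDM", "LLM", "RRUM")

# precedence for exact p-value ties: later entries win
_TIE_ORDER = ("RRUM", "LLM", "ACDM", "DINO", "DINA")


@dataclass(frozen=True)
class WaldResult:
    item_label: str
    family: str
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class MixedModelPlan:
    """Per-item family assignment with the Wald evidence behind it."""

    item_labels: tuple[str, ...]
    families: tuple[str, ...]
    wald_results: dict = field(default_factory=dict)   # label -> list[WaldResult]
    rule_trace: dict = field(default_factory=dict)     # label -> str

    def selected_p_value(self, label: str):
        fam = dict(zip(self.item_labels, self.families))[label]
        for r in self.wald_results.get(label, ()):
            if r.family == fam:
                return r.p_value
        return None

    def to_dict(self) -> dict:
        return {
            lab: {
                "family": fam,
                "rule": self.rule_trace.get(lab, ""),
                "p_values": {
                    r.family: r.p_value for r in self.wald_results.get(lab, ())
                },
            }
            for lab, fam in zip(self.item_labels, self.families)
        }


def _restriction(family: str, k: int):
    """Contrast matrix C and the link scale for a reduced family."""
    m = 2 ** k
    if family in ("DINA", "DINO"):
        distinguished = m - 1 if family == "DINA" else 0
        group = [r for r in range(m) if r != distinguished]
        C = np.zeros((len(group) - 1, m))
        for i, r in enumerate(group[1:]):
            C[i, group[0]] = 1.0
            C[i, r] = -1.0
        return C, "identity"
    if family in ("ACDM", "LLM", "RRUM"):
        Minv = np.linalg.inv(gdina_design(k))
        C = Minv[k + 1:, :]  # rows for interaction coefficients
        link = {"ACDM": "identity", "LLM": "logit", "RRUM": "log"}[family]
        return C, link
    raise ValueError(f"{family!r} is not a reduced family")


def _link_transform(p, link):
    if link == "identity":
        return p, np.ones_like(p)
    if link == "logit":
        return logit(p), 1.0 / (p * (1.0 - p))
    if link == "log":
        return np.log(p), 1.0 / p
    raise ValueError(link)


def item_prob_covariance(post, x_j, rmap, p_red) -> np.ndarray:
    """Covariance of one item's reduced success probabilities.

    Uses the outer product of per-examinee scores with respect to the
    reduced-profile probabilities (empirical information), where group
    membership is posterior-weighted.
    """
    m = p_red.size
    G = np.zeros((post.shape[1], m))
    G[np.arange(post.shape[1]), rmap] = 1.0
    gp = post @ G  # N x m posterior mass per reduced group
    denom = np.clip(p_red * (1.0 - p_red), PROB_FLOOR, None)
    S = gp * ((x_j[:, None] - p_red) / denom)
    info = S.T @ S
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("singular item information; using pseudo-inverse", RuntimeWarning)
        cov = np.linalg.pinv(info)
    return cov


def wald_test(
    fit: MixedCDMFit,
    data: ResponseMatrix,
    item_index: int,
    family: str,
    posterior: np.ndarray | None = None,
) -> WaldResult:
    """Test whether a reduced family fits item ``item_index`` as well as
    the saturated G-DINA parameterisation it was fitted with."""
    item = fit.items[item_index]
    if item.family != "GDINA":
        raise ValueError("Wald test requires a saturated (G-DINA) item fit")
    k = item.n_required
    if k < 2:
        raise ValueError("Wald test is defined only for multi-attribute items")
    if posterior is None:
        posterior, _ = _posterior_matrix(
            data.entries.astype(float),
            fit.item_probs(),
            np.log(np.clip(fit.class_probs, PROB_FLOOR, 1)),
        )
    p_red = np.clip(item.reduced_probs(), 1e-6, 1 - 1e-6)
    rmap = reduced_index_map(item.required_attributes, fit.n_attributes)
    cov_p = item_prob_covariance(
        posterior, data.entries[:, item_index].astype(float), rmap, p_red
    )
    C, link = _restriction(family, k)
    f, deriv = _link_transform(p_red, link)
    cov_f = cov_p * np.outer(deriv, deriv)
    v = C @ f
    V = C @ cov_f @ C.T
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular restricted covariance; using pseudo-inverse", RuntimeWarning
        )
        Vinv = np.linalg.pinv(V)
    stat = float(v @ Vinv @ v)
    stat = max(stat, 0.0)
    df = C.shape[0]
    return WaldResult(
        item_label=item.label or f"Item{item_index + 1}",
        family=family,
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
    )


def select_item_model(
    results, alpha: float = 0.05, prefer_parsimony: bool = False
) -> tuple[str, str]:
    """Apply the four selection rules to one item's Wald results.

    Returns ``(family, rule_trace)``.
    """
    results = list(results)
    if not results:
        return "GDINA", "no candidates"
    admitted = [r for r in results if r.p_value > alpha]
    if not admitted:
        return "GDINA", "rule 4: all reduced families rejected"
    pool = admitted
    rule = "rule 1+2: highest p among admitted"
    if prefer_parsimony:
        parsimonious = [r for r in admitted if r.family in ("DINA", "DINO")]
        if parsimonious:
            pool = parsimonious
            rule = "rule 3: parsimony preference (DINA/DINO)"
    best_p = max(r.p_value for r in pool)
    tied = [r for r in pool if r.p_value == best_p]
    if len(tied) > 1:
        logger.info(
            "Wald selection tie at p=%.4g among %s; broke by family precedence",
            best_p,
            [r.family for r in tied],
        )
        rule += " (tie broken by precedence)"
    choice = max(tied, key=lambda r: _TIE_ORDER.index(r.family))
    return choice.family, rule


def build_mixed_model(
    data: ResponseMatrix,
    q: QMatrix,
    alpha: float = 0.05,
    *,
    prefer_parsimony: bool = False,
    candidates=REDUCED_FAMILIES,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> tuple[MixedModelPlan, MixedCDMFit]:
    """Fit saturated G-DINA, Wald-test every multi-attribute item, and refit
    the assembled mixed model.

    Single-attribute items are always assigned the saturated model (for
    K*=1 the reduced families are not restrictions).  With three or more
    attributes on an item, Wald inference is unreliable below roughly
    n = 1000 examinees; this is warned about, not blocked.
    """
    ks = q.entries.sum(axis=1)
    if (ks >= 3).any() and data.n_examinees <= 1000:
        warnings.warn(
            "items measure 3+ attributes but n <= 1000; Wald type-I error "
            "may be inflated",
            UserWarning,
        )
    saturated = em_fit(data, q, "GDINA", tol=tol, max_iter=max_iter, seed=seed)
    posterior, _ = _posterior_matrix(
        data.entries.astype(float),
        saturated.item_probs(),
        np.log(np.clip(saturated.class_probs, PROB_FLOOR, 1)),
    )
    families, wald_results, rule_trace = [], {}, {}
    for j, label in enumerate(q.item_labels):
        if ks[j] < 2:
            families.append("GDINA")
            rule_trace[label] = "single-attribute: saturated model applied directly"
            continue
        res = [
            wald_test(saturated, data, j, fam, posterior=posterior)
            for fam in candidates
        ]
        fam, rule = select_item_model(res, alpha, prefer_parsimony)
        families.append(fam)
        wald_results[label] = res
        rule_trace[label] = rule
    plan = MixedModelPlan(
        item_labels=tuple(q.item_labels),
        families=tuple(families),
        wald_results=wald_results,
        rule_trace=rule_trace,
    )
    # warm-start the mixed refit from the saturated solution so the refit
    # keeps the saturated fit's attribute labeling (a fresh random start can
    # wander to a label-switched mode of near-equal likelihood)
    mixed = em_fit(
        data, q, families, tol=tol, max_iter=max_iter, seed=seed,
        init_probs=[it.reduced_probs() for it in saturated.items],
        init_class_probs=saturated.class_probs,
    )
    return plan, mixed
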