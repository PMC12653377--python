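"""Latent class space and item response functions for diagnostic models.

An examinee's knowledge state is a length-K binary mastery vector
``(alpha_1, ..., alpha_K)``.  States are rendered as 0/1 strings with the
*leftmost* character attribute 1, so with K=7 the string ``"0000010"``
means only attribute 6 is mastered.  The class space enumerates all 2^K
states in ascending integer order of that string read as a binary number
(attribute 1 is the most significant bit); this single ordering is used
everywhere — posterior columns, mixing proportions, tie-breaks.

Item response functions (IRFs) give P(X_j = 1 | state) and depend on the
state only through the attributes the item requires (its Q-matrix row).
Six families are supported:

* ``GDINA`` — saturated: identity link with intercept, main effects and all
  interactions over the required attributes (2^{K*} free parameters).
* ``DINA`` / ``DINO`` — conjunctive / disjunctive, with guessing ``g`` and
  slip ``s``.
* ``ACDM`` / ``LLM`` / ``RRUM`` — additive (intercept + main effects) under
  the identity, logit and log links respectively.

The saturated log-linear parameterisation (LCDM) is fit-equivalent to
saturated G-DINA and is not implemented as a separate family.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "FAMILIES",
    "AttributeProfile",
    "LatentClassSpace",
    "ItemParameterSet",
    "profile_space",
    "profile_to_string",
    "string_to_profile",
    "profile_index",
    "reduce_profile",
    "gdina_design",
    "irf",
    "item_class_probs",
    "response_vector_loglik",
    "PROB_FLOOR",
]

FAMILIES = ("GDINA", "DINA", "DINO", "ACDM", "LLM", "RRUM")

#: floor applied to success probabilities inside log-likelihoods so that
#: boundary parameters (g=0, s=0) never produce -inf
PROB_FLOOR = 1e-10


def profile_space(n_attributes: int) -> np.ndarray:
    """All 2^K mastery profiles, shape (2^K, K), row c = bits of c MSB-first."""
    if n_attributes < 1:
        raise ValueError("need at least one attribute")
    idx = np.arange(2 ** n_attributes)
    shifts = np.arange(n_attributes - 1, -1, -1)
    return ((idx[:, None] >> shifts) & 1).astype(np.int8)


def profile_to_string(bits) -> str:
    return "".join(str(int(b)) for b in bits)


def string_to_profile(s: str) -> np.ndarray:
    bits = np.array([int(c) for c in s], dtype=np.int8)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError(f"invalid profile string {s!r}")
    return bits


def profile_index(bits) -> int:
    """Index of a profile in the class space (its MSB-first binary value)."""
    bits = np.asarray(bits)
    shifts = np.arange(len(bits) - 1, -1, -1)
    return int((bits.astype(int) << shifts).sum())


@dataclass(frozen=True)
class AttributeProfile:
    """A knowledge state: binary mastery vector over the K attributes."""

    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8).ravel()
        if bits.size == 0 or not np.isin(bits, (0, 1)).all():
            raise ValueError("profile bits must be a non-empty 0/1 vector")
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    def __str__(self) -> str:
        return profile_to_string(self.bits)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def index(self) -> int:
        return profile_index(self.bits)

    @property
    def level(self) -> int:
        """Number of mastered attributes."""
        return int(self.bits.sum())

    @classmethod
    def from_string(cls, s: str) -> "AttributeProfile":
        return cls(string_to_profile(s))


@dataclass(frozen=True)
class LatentClassSpace:
    """Ordered enumeration of all 2^K knowledge states."""

    n_attributes: int
    profiles: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "profiles", profile_space(self.n_attributes))

    def __len__(self) -> int:
        return self.profiles.shape[0]

    def strings(self) -> list[str]:
        return [profile_to_string(p) for p in self.profiles]


def _subsets(n: int) -> list[tuple[int, ...]]:
    """All subsets of range(n), ordered by size then lexicographically.

    This fixes the column order of the saturated design matrix: intercept,
    main effects in attribute order, two-way interactions, and so on.
    """
    out: list[tuple[int, ...]] = []
    for size in range(n + 1):
        out.extend(itertools.combinations(range(n), size))
    return out


def gdina_design(n_required: int) -> np.ndarray:
    """Saturated design matrix M (2^{K*} x 2^{K*}).

    Row r is the reduced profile with index r; column t is the subset S_t of
    required attributes; M[r, t] = 1 iff every attribute in S_t is mastered
    in r.  Success probabilities are P = M @ delta.
    """
    red = profile_space(n_required)
    cols = _subsets(n_required)
    M = np.empty((red.shape[0], len(cols)), dtype=float)
    for t, S in enumerate(cols):
        M[:, t] = red[:, list(S)].all(axis=1) if S else 1.0
    return M


def reduce_profile(profile, required) -> np.ndarray:
    """Restrict a full profile to an item's required attributes, in order."""
    bits = profile.bits if isinstance(profile, AttributeProfile) else np.asarray(profile)
    required = np.asarray(required, dtype=int)
    return bits[required]


@dataclass(frozen=True)
class ItemParameterSet:
    """One item's family, required attributes and coefficients.

    ``required_attributes`` are 0-based attribute indices (ascending).
    ``params`` depends on the family:

    * DINA / DINO: ``(g, s)``
    * ACDM / LLM / RRUM: ``(intercept, effect_1, ..., effect_{K*})`` on the
      identity / logit / log scale
    * GDINA: delta coefficients over all subsets of the required attributes
      (order: intercept, main effects, interactions by size then lex),
      identity link — length 2^{K*}
    """

    family: str
    required_attributes: tuple[int, ...]
    params: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        req = tuple(sorted(int(a) for a in self.required_attributes))
        if len(req) == 0:
            raise ValueError("an item must require at least one attribute")
        if len(set(req)) != len(req):
            raise ValueError("duplicate required attributes")
        object.__setattr__(self, "required_attributes", req)
        params = np.asarray(self.params, dtype=float).ravel()
        k = len(req)
        expected = {
            "DINA": 2,
            "DINO": 2,
            "ACDM": k + 1,
            "LLM": k + 1,
            "RRUM": k + 1,
            "GDINA": 2 ** k,
        }[self.family]
        if params.size != expected:
            raise ValueError(
                f"{self.family} item over {k} attributes needs {expected} "
                f"parameters, got {params.size}"
            )
        params.setflags(write=False)
        object.__setattr__(self, "params", params)
        probs = self._raw_reduced_probs()
        if (probs < -1e-9).any() or (probs > 1 + 1e-9).any():
            raise ValueError(
                f"parameters imply success probabilities outside [0,1]: {probs}"
            )

    @property
    def n_required(self) -> int:
        return len(self.required_attributes)

    @property
    def n_free_params(self) -> int:
        return self.params.size

    def reduced_probs(self) -> np.ndarray:
        """Success probability for each of the 2^{K*} reduced profiles."""
        return np.clip(self._raw_reduced_probs(), 0.0, 1.0)

    def _raw_reduced_probs(self) -> np.ndarray:
        k = self.n_required
        red = profile_space(k).astype(float)
        if self.family == "GDINA":
            p = gdina_design(k) @ self.params
        elif self.family in ("DINA", "DINO"):
            g, s = self.params
            eta = red.all(axis=1) if self.family == "DINA" else red.any(axis=1)
            p = np.where(eta, 1.0 - s, g)
        else:
            z = self.params[0] + red @ self.params[1:]
            if self.family == "ACDM":
                p = z
            elif self.family == "LLM":
                p = expit(z)
            else:  # RRUM
                p = np.exp(z)
        return p

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "family": self.family,
            "required_attributes": list(self.required_attributes),
            "params": self.params.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemParameterSet":
        return cls(
            d["family"],
            tuple(d["required_attributes"]),
            np.asarray(d["params"], dtype=float),
            d.get("label", ""),
        )


def irf(item: ItemParameterSet, profile) -> float:
    """P(correct | knowledge state) — depends only on the required bits."""
    reduced = reduce_profile(profile, item.required_attributes)
    return float(item.reduced_probs()[profile_index(reduced)])


def reduced_index_map(required, n_attributes: int) -> np.ndarray:
    """Map each of the 2^K global classes to its reduced-profile index."""
    space = profile_space(n_attributes)
    required = np.asarray(required, dtype=int)
    shifts = np.arange(len(required) - 1, -1, -1)
    return (space[:, required].astype(int) << shifts).sum(axis=1)


def item_class_probs(items, n_attributes: int) -> np.ndarray:
    """J x 2^K matrix of success probabilities over the full class space."""
    out = np.empty((len(items), 2 ** n_attributes))
    for j, item in enumerate(items):
        rmap = reduced_index_map(item.required_attributes, n_attributes)
        out[j] = item.reduced_probs()[rmap]
    return out


def response_vector_loglik(responses, profile, items, eps: float = PROB_FLOOR) -> float:
    """log P(x | state) under conditional independence of items given state."""
    x = np.asarray(responses, dtype=float).ravel()
    if x.size != len(items):
        raise ValueError("response vector length does not match item count")
    p = np.array([irf(item, profile) for item in items])
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.sum(x * np.log(p) + (1.0 - x) * np.log1p(-p)))


def items_to_json(items, path=None) -> str:
    payload = json.dumps([it.to_dict() for it in items], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def items_from_json(source) -> list[ItemParameterSet]:
    if isinstance(source, str) and source.lstrip().startswith("["):
        data = json.loads(source)
    else:
        with open(source) as fh:
            data = json.load(fh)
    return [ItemParameterSet.from_dict(d) for d in data]
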