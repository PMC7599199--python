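"""The polytomous local independence model (PoLIM).

Each respondent occupies a latent state ``K`` of a polytomous structure with
probability ``pi_K``.  Given the state, the observed response to each item
``q`` is drawn independently from the row ``K(q)`` of a per-item
row-stochastic error matrix ``E_q``, whose entry ``(i, j)`` is
``eps_q(i, j) = P(R_q = j | K_q = i)``.  The marginal probability of a
response pattern ``R`` is the mixture ``P(R) = sum_K P(R|K) pi_K``.  The
dichotomous basic local independence model (BLIM) is the two-level special
case with ``eps_q(1,0) = beta_q`` (careless error) and
``eps_q(0,1) = eta_q`` (lucky guess).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import (
    Domain,
    LevelSet,
    PolytomousStructure,
    ResponseData,
    state_to_string,
)

__all__ = [
    "ErrorMatrix",
    "StateDistribution",
    "PolimParameters",
    "conditional_pattern_prob",
    "marginal_pattern_prob",
    "log_conditional_matrix",
    "log_likelihood",
    "count_free_parameters",
    "simulate_responses",
    "PROB_FLOOR",
]

#: Floor applied to estimated probabilities, approximating the open-interval
#: constraint eps in (0,1), pi in (0,1) while avoiding log(0).
PROB_FLOOR = 1e-12

_ROW_SUM_TOL = 1e-10


def _check_row_stochastic(probs: np.ndarray, what: str) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError(f"{what} must be a square matrix, got {probs.shape}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError(f"{what} entries must lie in [0, 1]")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0):
        raise ValueError(f"{what} rows must sum to 1 within {_ROW_SUM_TOL}")
    return probs


@dataclass
class ErrorMatrix:
    """Conditional response probabilities of one item.

    ``probs[i, j] = P(R_q = level j | K_q = level i)``; rows sum to one.
    """

    item: object
    probs: np.ndarray

    def __post_init__(self):
        self.probs = _check_row_stochastic(self.probs, f"error matrix of {self.item!r}")

    @property
    def n_levels(self) -> int:
        return self.probs.shape[0]


@dataclass
class StateDistribution:
    """Probability distribution ``pi`` over the states of a structure."""

    structure: PolytomousStructure
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.structure.n_states,):
            raise ValueError("one probability per state required")
        if np.any(self.probs < 0):
            raise ValueError("state probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > _ROW_SUM_TOL:
            raise ValueError("state probabilities must sum to 1")


class PolimParameters:
    """Full parameter set: per-item error matrices plus a state distribution.

    Parameters
    ----------
    structure : PolytomousStructure
    epsilon : ndarray of shape (|Q|, |L|, |L|)
        Row-stochastic error matrix per item, in domain order.
    pi : ndarray of shape (|K|,)
        State probabilities, summing to one.
    """

    def __init__(self, structure: PolytomousStructure, epsilon, pi):
        self.structure = structure
        eps = np.asarray(epsilon, dtype=float)
        L, Q = structure.n_levels, structure.n_items
        if eps.shape != (Q, L, L):
            raise ValueError(
                f"epsilon must have shape ({Q}, {L}, {L}), got {eps.shape}"
            )
        for q in range(Q):
            _check_row_stochastic(eps[q], f"error matrix of item {structure.domain.items[q]!r}")
        self.epsilon = eps
        self.pi = StateDistribution(structure, pi).probs

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def uniform(cls, structure: PolytomousStructure) -> "PolimParameters":
        """Fully uniform parameters: eps = 1/|L| everywhere, pi = 1/|K|."""
        L, Q, S = structure.n_levels, structure.n_items, structure.n_states
        eps = np.full((Q, L, L), 1.0 / L)
        pi = np.full(S, 1.0 / S)
        return cls(structure, eps, pi)

    @classmethod
    def from_blim(cls, structure: PolytomousStructure, beta, eta, pi) -> "PolimParameters":
        """Dichotomous special case from careless-error/lucky-guess rates."""
        if structure.n_levels != 2:
            raise ValueError("from_blim requires a 2-level structure")
        beta = np.asarray(beta, dtype=float)
        eta = np.asarray(eta, dtype=float)
        Q = structure.n_items
        eps = np.empty((Q, 2, 2))
        eps[:, 0, 0] = 1.0 - eta
        eps[:, 0, 1] = eta
        eps[:, 1, 0] = beta
        eps[:, 1, 1] = 1.0 - beta
        return cls(structure, eps, pi)

    def error_matrix(self, item) -> ErrorMatrix:
        q = self.structure.domain.index_of(item)
        return ErrorMatrix(item, self.epsilon[q].copy())

    def copy(self) -> "PolimParameters":
        return PolimParameters(self.structure, self.epsilon.copy(), self.pi.copy())

    def __repr__(self) -> str:
        return f"PolimParameters({self.structure!r})"


def count_free_parameters(structure: PolytomousStructure) -> int:
    """``|Q| |L| (|L|-1) + |K| - 1`` free parameters of the PoLIM."""
    Q, L, S = structure.n_items, structure.n_levels, structure.n_states
    return Q * L * (L - 1) + S - 1


def _conform(state, params: PolimParameters) -> np.ndarray:
    arr = np.asarray(state, dtype=np.int64)
    Q, L = params.structure.n_items, params.structure.n_levels
    if arr.shape != (Q,):
        raise ValueError(f"pattern/state must have {Q} entries, got {arr.shape}")
    if arr.min() < 0 or arr.max() >= L:
        raise ValueError(f"levels must lie in 0..{L - 1}")
    return arr


def conditional_pattern_prob(R, K, params: PolimParameters) -> float:
    """``P(R | K) = prod_q eps_q(K(q), R(q))`` (local independence)."""
    R = _conform(R, params)
    K = _conform(K, params)
    q_idx = np.arange(params.structure.n_items)
    return float(np.prod(params.epsilon[q_idx, K, R]))


def log_conditional_matrix(patterns, params: PolimParameters) -> np.ndarray:
    """Log of ``P(R|K)`` for every (pattern, state) pair, shape (P, S).

    Accumulates per-item log probabilities so long domains cannot underflow.
    """
    pats = np.asarray(patterns, dtype=np.int64)
    states = params.structure.states
    with np.errstate(divide="ignore"):
        log_eps = np.log(params.epsilon)
    out = np.zeros((pats.shape[0], states.shape[0]))
    for q in range(params.structure.n_items):
        out += log_eps[q][states[:, q][None, :], pats[:, q][:, None]]
    return out


def marginal_pattern_prob(R, params: PolimParameters) -> float:
    """``P(R) = sum_K P(R|K) pi_K``."""
    R = _conform(R, params)
    logc = log_conditional_matrix(R[None, :], params)[0]
    with np.errstate(divide="ignore"):
        terms = np.where(params.pi > 0, np.exp(logc) * params.pi, 0.0)
    return float(terms.sum())


def log_likelihood(data: ResponseData, params: PolimParameters) -> float:
    """Multinomial log-likelihood ``sum_R n_R ln P(R)`` over distinct patterns."""
    logc = log_conditional_matrix(data.patterns, params)
    with np.errstate(divide="ignore"):
        probs = np.exp(logc) @ params.pi
    if np.any(probs <= 0):
        bad = int(np.argmin(probs))
        pat = state_to_string(data.patterns[bad], params.structure.n_levels)
        raise ValueError(f"pattern {pat} has zero marginal probability")
    return float(data.frequencies @ np.log(probs))


def simulate_responses(params: PolimParameters, n: int,
                       seed: int | np.random.Generator):
    """Simulate ``n`` respondents from the PoLIM.

    Per respondent a latent state is drawn from ``pi`` and each item response
    from the corresponding error-matrix row.  Returns ``(data, latent)``
    where ``latent`` is the (n, |Q|) array of drawn latent states in
    respondent order.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    struct = params.structure
    state_idx = rng.choice(struct.n_states, size=n, p=params.pi)
    latent = struct.states[state_idx]
    responses = np.empty_like(latent)
    u = rng.random(size=latent.shape)
    for q in range(struct.n_items):
        cdf = np.cumsum(params.epsilon[q], axis=1)
        # row of the respondent's latent level, inverted by its CDF
        rows = cdf[latent[:, q]]
        responses[:, q] = (u[:, q][:, None] > rows).sum(axis=1)
    data = ResponseData.from_responses(responses, domain=struct.domain,
                                       levels=struct.levels)
    return data, latent
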