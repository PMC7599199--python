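"""Maximum-likelihood estimation of PoLIM parameters by EM.

The unconstrained M-step is the complete-data maximizer of this latent-class
likelihood:

* ``pi_K <- (1/N) sum_R n_R P(K|R)``
* ``eps_q(i,j) <- [sum_R n_R sum_{K: K(q)=i, R(q)=j} P(K|R)]
  / [sum_R n_R sum_{K: K(q)=i} P(K|R)]``

which reduces to the classical BLIM EM when ``|L| = 2``.  The constrained
variant keeps every error-matrix row inside the half-monotone family by
working on the overrate/underrate decay rates: each row's expected
complete-data log-likelihood is maximized numerically over logit-transformed
rates, and a step is accepted only if it improves that row's objective
(a generalized-EM scheme, so the observed log-likelihood still never
decreases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .model import (
    PROB_FLOOR,
    PolimParameters,
    log_conditional_matrix,
)
from .monotonicity import RateParameters, rates_to_epsilon
from .structures import PolytomousStructure, ResponseData

__all__ = [
    "FitResult",
    "posterior_states",
    "em_fit",
    "em_fit_constrained",
    "identifiability_check",
    "default_init",
    "random_init",
]

#: Slack allowed on the EM's monotone log-likelihood guarantee (float noise).
LOGLIK_SLACK = 1e-8


@dataclass
class FitResult:
    """Outcome of one EM run."""

    params: PolimParameters
    loglik_trace: list[float]
    iterations: int
    converged: bool
    seed: int | None = None
    rates: list[RateParameters] | None = None
    settings: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _floor_normalize(p: np.ndarray, axis=-1) -> np.ndarray:
    p = np.maximum(p, PROB_FLOOR)
    return p / p.sum(axis=axis, keepdims=True)


def posterior_states(data: ResponseData, params: PolimParameters) -> np.ndarray:
    """Posterior ``P(K|R)`` for every distinct pattern; rows sum to one."""
    post, ll = _e_step(data, params)
    return post

def _e_step(data: ResponseData, params: PolimParameters):
    logc = log_conditional_matrix(data.patterns, params)
    with np.errstate(divide="ignore"):
        log_joint = logc + np.log(params.pi)[None, :]
    log_marg = logsumexp(log_joint, axis=1)
    if np.any(~np.isfinite(log_marg)):
        bad = int(np.argmin(log_marg))
        raise ValueError(
            f"pattern index {bad} has zero marginal probability"
        )
    post = np.exp(log_joint - log_marg[:, None])
    loglik = float(data.frequencies @ log_marg)
    return post, loglik


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    return np.eye(n_levels)[codes]


def _expected_counts(data: ResponseData, structure: PolytomousStructure,
                     weighted_post: np.ndarray) -> np.ndarray:
    """Expected (latent level, observed level) counts per item, shape (Q,L,L)."""
    L, Q = structure.n_levels, structure.n_items
    C = np.empty((Q, L, L))
    for q in range(Q):
        s1h = _one_hot(structure.states[:, q], L)      # (S, L)
        p1h = _one_hot(data.patterns[:, q], L)         # (P, L)
        C[q] = p1h.T @ (weighted_post @ s1h)           # (L_obs, L_lat)
        C[q] = C[q].T                                  # rows = latent level i
    return C


def default_init(structure: PolytomousStructure,
                 diag_nudge: float = 0.5) -> PolimParameters:
    """Deterministic default start: uniform ``pi``, near-uniform ``eps``.

    The exactly uniform error matrix (``eps = 1/|L|``) is a saddle point of
    the EM map — it makes ``P(R|K)`` independent of ``K``, so every update
    returns the same point.  The default therefore tilts each row slightly
    toward its diagonal, ``eps(i,j) = (1 + diag_nudge*[i=j])/(|L| +
    diag_nudge)``, which is deterministic and aligns the latent levels with
    the observed coding.
    """
    L, Q, S = structure.n_levels, structure.n_items, structure.n_states
    row = np.ones(L)
    eps = np.tile(row, (Q, L, 1))
    eps += diag_nudge * np.eye(L)[None, :, :]
    eps /= eps.sum(axis=2, keepdims=True)
    pi = np.full(S, 1.0 / S)
    return PolimParameters(structure, eps, pi)


def random_init(structure: PolytomousStructure,
                rng: np.random.Generator) -> PolimParameters:
    """Random start: flat-Dirichlet error rows and state distribution."""
    L, Q, S = structure.n_levels, structure.n_items, structure.n_states
    eps = rng.dirichlet(np.ones(L), size=(Q, L))
    pi = rng.dirichlet(np.ones(S))
    return PolimParameters(structure, eps, pi)


def _resolve_init(init, structure) -> PolimParameters:
    if init == "default" or init is None:
        return default_init(structure)
    if isinstance(init, PolimParameters):
        return init.copy()
    raise TypeError("init must be PolimParameters or 'default'")


def em_fit(data: ResponseData, structure: PolytomousStructure,
           init: PolimParameters | str = "default", tol: float = 1e-6,
           max_iter: int = 2000, seed: int | None = None) -> FitResult:
    """Unconstrained EM fit of the PoLIM.

    Stops when the absolute log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations.  The log-likelihood trace is
    non-decreasing up to float noise.
    """
    if data.patterns.shape[1] != structure.n_items:
        raise ValueError("data and structure have different numbers of items")
    if data.patterns.max() >= structure.n_levels:
        raise ValueError("data contain levels outside the structure's level set")
    params = _resolve_init(init, structure)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, ll = _e_step(data, params)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        W = data.frequencies[:, None] * post
        pi = _floor_normalize(W.sum(axis=0))
        C = _expected_counts(data, structure, W)
        eps = _floor_normalize(C, axis=2)
        params = PolimParameters(structure, eps, pi)
    return FitResult(params, trace, it, converged, seed=seed,
                     settings={"tol": tol, "max_iter": max_iter,
                               "constrained": False})


# ---------------------------------------------------------------------------
# constrained EM (half-monotone rows via decay rates)
# ---------------------------------------------------------------------------

def _row_from_rates_flat(theta_row: np.ndarray, i: int, n: int) -> np.ndarray:
    """Build error-matrix row ``i`` from its (0,1) rates laid out flat.

    Layout: underrate rates for columns ``i-1 .. 0`` then overrate rates for
    columns ``i+1 .. n-1`` (each stepping away from the diagonal).
    """
    t = np.empty(n)
    t[i] = 1.0
    pos = 0
    for j in range(i - 1, -1, -1):
        t[j] = t[j + 1] * theta_row[pos]
        pos += 1
    for j in range(i + 1, n):
        t[j] = t[j - 1] * theta_row[pos]
        pos += 1
    return t / t.sum()


def _row_neg_objective(z: np.ndarray, counts: np.ndarray, i: int, n: int) -> float:
    rates = expit(z)
    row = _row_from_rates_flat(rates, i, n)
    return -float(counts @ np.log(np.maximum(row, PROB_FLOOR)))


def _rates_matrices_to_flat(rates: RateParameters, i: int) -> np.ndarray:
    n = rates.n_levels
    vals = [rates.upsilon[i, j] for j in range(i - 1, -1, -1)]
    vals += [rates.omega[i, j] for j in range(i + 1, n)]
    return np.array(vals)


def _flat_to_rates_row(flat: np.ndarray, i: int, n: int, omega, upsilon):
    pos = 0
    for j in range(i - 1, -1, -1):
        upsilon[i, j] = flat[pos]
        pos += 1
    for j in range(i + 1, n):
        omega[i, j] = flat[pos]
        pos += 1


def default_rate_init(structure: PolytomousStructure,
                      value: float = 0.5) -> list[RateParameters]:
    """All decay rates at ``value``; rows are unimodal from the start."""
    L = structure.n_levels
    out = []
    for item in structure.domain.items:
        omega = np.full((L, L), np.nan)
        upsilon = np.full((L, L), np.nan)
        for i in range(L):
            upsilon[i, :i] = value
            omega[i, i + 1:] = value
        out.append(RateParameters(item, omega, upsilon))
    return out


def _params_from_rates(structure: PolytomousStructure,
                       rates: list[RateParameters], pi) -> PolimParameters:
    eps = np.stack([rates_to_epsilon(r).probs for r in rates])
    return PolimParameters(structure, eps, pi)


def em_fit_constrained(data: ResponseData, structure: PolytomousStructure,
                       init_rates: list[RateParameters] | str = "default",
                       tol: float = 1e-6, max_iter: int = 2000,
                       seed: int | None = None) -> FitResult:
    """EM fit with every error-matrix row half-monotone by construction.

    The M-step for each item row maximizes the row's expected complete-data
    log-likelihood over logit-transformed decay rates (L-BFGS-B), starting
    from the previous iterate; a proposal is kept only when it improves the
    row objective, so the overall scheme is a generalized EM.
    """
    if init_rates == "default" or init_rates is None:
        rates = default_rate_init(structure)
    else:
        rates = [RateParameters(r.item, r.omega.copy(), r.upsilon.copy())
                 for r in init_rates]
    L, Q, S = structure.n_levels, structure.n_items, structure.n_states
    pi = np.full(S, 1.0 / S)
    params = _params_from_rates(structure, rates, pi)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, ll = _e_step(data, params)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        W = data.frequencies[:, None] * post
        pi = _floor_normalize(W.sum(axis=0))
        C = _expected_counts(data, structure, W)
        for q in range(Q):
            for i in range(L):
                if L - 1 == 0:
                    continue
                flat0 = _rates_matrices_to_flat(rates[q], i)
                z0 = logit(np.clip(flat0, 1e-9, 1 - 1e-9))
                counts = C[q, i]
                f0 = _row_neg_objective(z0, counts, i, L)
                res = minimize(_row_neg_objective, z0,
                               args=(counts, i, L), method="L-BFGS-B",
                               options={"maxiter": 60})
                if np.isfinite(res.fun) and res.fun < f0:
                    new_flat = expit(res.x)
                    # keep strictly inside (0,1)
                    new_flat = np.clip(new_flat, 1e-9, 1 - 1e-9)
                    _flat_to_rates_row(new_flat, i, L,
                                       rates[q].omega, rates[q].upsilon)
        params = _params_from_rates(structure, rates, pi)
    return FitResult(params, trace, it, converged, seed=seed, rates=rates,
                     settings={"tol": tol, "max_iter": max_iter,
                               "constrained": True})


def identifiability_check(data: ResponseData, structure: PolytomousStructure,
                          n_restarts: int, seed: int,
                          loglik_window: float = 1e-3,
                          constrained: bool = False,
                          tol: float = 1e-8, max_iter: int = 2000) -> dict:
    """Empirical identifiability probe by multistart EM.

    Fits the model ``n_restarts`` times from random starts, keeps the fits
    whose log-likelihood lies within ``loglik_window`` of the best one, and
    reports the maximum standard deviation over all parameters among those
    fits (values below 1e-3 are conventionally read as "identifiable"),
    together with the log-likelihood range of the kept fits.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_restarts):
        if constrained:
            init = default_rate_init(structure)
            for r in init:
                mask_u = ~np.isnan(r.upsilon)
                mask_o = ~np.isnan(r.omega)
                r.upsilon[mask_u] = rng.uniform(0.05, 0.95, mask_u.sum())
                r.omega[mask_o] = rng.uniform(0.05, 0.95, mask_o.sum())
            fits.append(em_fit_constrained(data, structure, init_rates=init,
                                           tol=tol, max_iter=max_iter))
        else:
            init = random_init(structure, rng)
            fits.append(em_fit(data, structure, init=init, tol=tol,
                               max_iter=max_iter))
    best = max(f.loglik for f in fits)
    kept = [f for f in fits if best - f.loglik <= loglik_window]
    stacks = np.array([
        np.concatenate([f.params.epsilon.ravel(), f.params.pi]) for f in kept
    ])
    sds = stacks.std(axis=0, ddof=0)
    return {
        "n_kept": len(kept),
        "loglik_range": float(max(f.loglik for f in kept)
                              - min(f.loglik for f in kept)),
        "max_param_sd": float(sds.max()),
        "logliks": [f.loglik for f in fits],
    }
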