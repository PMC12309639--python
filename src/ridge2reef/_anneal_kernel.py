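"""JIT-compiled simulated-annealing core for reserve selection.

The kernel works on flat arrays so numba can compile it: unit costs,
the unit-by-feature amount matrix, per-unit condition probabilities,
per-feature flags/targets/penalties, and a CSR adjacency (shared
boundary lengths). State maintained incrementally per flip: selected
cost, exposed boundary, held amount, and the mean/variance of the
random held amount for probabilistic features.

Objective semantics must match :func:`ridge2reef.prioritize.objective`
exactly; a test asserts the two agree.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _prob_met(mu, s2, target):
    if s2 <= 1e-300:
        return 1.0 if mu >= target - 1e-9 else 0.0
    return 0.5 * math.erfc((target - mu) / math.sqrt(2.0 * s2))


@njit(cache=False)
def _shortfall(held, mu, s2, target, certainty, probabilistic):
    """Feature shortfall in amount units.

    Deterministic: max(0, T - held). Probabilistic: max(0, P - p_met) * T,
    except that with zero variance (all contributing units certain) the
    deterministic shortfall max(0, T - mu) is used, which makes the
    probabilistic mode collapse exactly onto the deterministic one when
    every p_i = 1 and gives the annealer a gradient instead of a step.
    """
    if not probabilistic:
        d = target - held
        return d if d > 0.0 else 0.0
    if s2 <= 1e-300:
        d = target - mu
        return d if d > 0.0 else 0.0
    d = (certainty - _prob_met(mu, s2, target)) * target
    return d if d > 0.0 else 0.0


@njit(cache=False)
def _flip_delta(
    i, x, cost, amounts, p, prob_flag, target, spf, certainty,
    blm, perim, adj_indptr, adj_indices, adj_shared, held, mu, s2,
):
    sign = -1.0 if x[i] else 1.0
    delta = sign * cost[i]
    if blm > 0.0:
        shared_sel = 0.0
        for k in range(adj_indptr[i], adj_indptr[i + 1]):
            if x[adj_indices[k]]:
                shared_sel += adj_shared[k]
        delta += blm * sign * (perim[i] - 2.0 * shared_sel)
    M = target.shape[0]
    for j in range(M):
        a = amounts[i, j]
        if a == 0.0:
            continue
        old = _shortfall(held[j], mu[j], s2[j], target[j], certainty[j], prob_flag[j])
        h = held[j] + sign * a
        m = mu[j] + sign * a * p[i]
        v = s2[j] + sign * a * a * p[i] * (1.0 - p[i])
        if v < 0.0:
            v = 0.0
        new = _shortfall(h, m, v, target[j], certainty[j], prob_flag[j])
        delta += spf[j] * (new - old)
    return delta


@njit(cache=False)
def _apply_flip(i, x, amounts, p, held, mu, s2):
    sign = -1.0 if x[i] else 1.0
    x[i] = 0 if x[i] else 1
    for j in range(amounts.shape[1]):
        a = amounts[i, j]
        if a == 0.0:
            continue
        held[j] += sign * a
        mu[j] += sign * a * p[i]
        s2[j] += sign * a * a * p[i] * (1.0 - p[i])
        if s2[j] < 0.0:
            s2[j] = 0.0


@njit(cache=False)
def anneal_kernel(
    cost, amounts, p, prob_flag, target, spf, certainty,
    blm, perim, adj_indptr, adj_indices, adj_shared,
    n_iter, t0, cooling, seed, final_improvement, init_frac,
):
    """Single annealing run; returns the selection vector (uint8)."""
    np.random.seed(seed)
    N = cost.shape[0]
    M = target.shape[0]
    x = np.zeros(N, dtype=np.uint8)
    held = np.zeros(M)
    mu = np.zeros(M)
    s2 = np.zeros(M)
    for i in range(N):
        if np.random.random() < init_frac:
            _apply_flip(i, x, amounts, p, held, mu, s2)

    temp = t0
    for _ in range(n_iter):
        i = np.random.randint(0, N)
        delta = _flip_delta(
            i, x, cost, amounts, p, prob_flag, target, spf, certainty,
            blm, perim, adj_indptr, adj_indices, adj_shared, held, mu, s2,
        )
        accept = delta <= 0.0
        if not accept and temp > 1e-12:
            accept = np.random.random() < math.exp(-delta / temp)
        if accept:
            _apply_flip(i, x, amounts, p, held, mu, s2)
        temp *= cooling

    if final_improvement:
        improved = True
        while improved:
            improved = False
            for i in range(N):
                delta = _flip_delta(
                    i, x, cost, amounts, p, prob_flag, target, spf, certainty,
                    blm, perim, adj_indptr, adj_indices, adj_shared, held, mu, s2,
                )
                if delta < -1e-12:
                    _apply_flip(i, x, amounts, p, held, mu, s2)
                    improved = True
    return x
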