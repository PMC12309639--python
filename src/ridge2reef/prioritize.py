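"""Minimum-set reserve selection by simulated annealing.

Selects a set of planning units minimizing opportunity cost plus a
boundary-compactness term, subject to feature representation targets
enforced through penalties:

    minimize  sum_i c_i x_i + BLM * boundary(x) + sum_j SPF_j * shortfall_j

Two target modes per feature: deterministic (the held amount must reach
the target T_j) and probabilistic (the probability that the target is
met, with each unit's contribution a Bernoulli amount surviving with its
condition probability p_i, must reach a certainty level P_j — the
cyclone-risk treatment of coral). The attainment probability uses a
normal approximation to the sum of independent Bernoulli amounts; an
exact Poisson-binomial oracle is provided for testing.

The annealer runs single-unit flips under geometric cooling, optionally
followed by a greedy improvement pass, and is deterministic per seed.
An ensemble of runs yields the best solution and per-unit selection
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy.stats import norm

from ._anneal_kernel import anneal_kernel

__all__ = [
    "FeatureSpec",
    "Problem",
    "AnnealConfig",
    "SolutionEnsemble",
    "held_amount",
    "prob_target_met",
    "exact_prob_target_met",
    "objective",
    "default_spf",
    "auto_initial_temp",
    "anneal",
    "solve_ensemble",
    "reduce_check_deterministic",
]


@dataclass
class FeatureSpec:
    """A conservation feature with a representation target.

    ``target`` is the absolute amount (km^2) the reserve must hold;
    ``spf`` weights its shortfall in the objective; probabilistic
    features additionally need a ``certainty`` level in (0, 1) — the
    required probability that the target is met under unit-level
    condition uncertainty.
    """

    feature_id: int
    name: str
    target: float
    spf: float
    certainty: float | None = None
    probabilistic: bool = False

    def __post_init__(self) -> None:
        if self.target < 0:
            raise ValueError("target must be >= 0")
        if self.spf <= 0:
            raise ValueError("spf must be > 0")
        if self.probabilistic:
            if self.certainty is None or not 0 < self.certainty < 1:
                raise ValueError("probabilistic feature needs certainty in (0, 1)")
        elif self.certainty is not None:
            raise ValueError("certainty given for a deterministic feature")


@dataclass
class Problem:
    """Planning units x features with costs and condition probabilities."""

    pu_ids: np.ndarray
    cost: np.ndarray
    amounts: np.ndarray  # (N, M)
    features: list[FeatureSpec]
    prob_good: np.ndarray | None = None  # p_i, default all 1
    adjacency: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # (i, j, km)
    perimeter: np.ndarray | None = None  # exposed length if isolated (km)

    def __post_init__(self) -> None:
        self.pu_ids = np.asarray(self.pu_ids)
        self.cost = np.asarray(self.cost, dtype=float)
        self.amounts = np.atleast_2d(np.asarray(self.amounts, dtype=float))
        n, m = self.amounts.shape
        if len(self.cost) != n or len(self.pu_ids) != n:
            raise ValueError("inconsistent unit dimensions")
        if len(self.features) != m:
            raise ValueError("feature list does not match amounts columns")
        if (self.cost < 0).any() or (self.amounts < 0).any():
            raise ValueError("costs and amounts must be >= 0")
        if self.prob_good is None:
            self.prob_good = np.ones(n)
        self.prob_good = np.asarray(self.prob_good, dtype=float)
        if ((self.prob_good < 0) | (self.prob_good > 1)).any():
            raise ValueError("prob_good must lie in [0, 1]")
        if self.adjacency is None:
            self.adjacency = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
        ai, aj, ab = (np.asarray(a) for a in self.adjacency)
        self.adjacency = (ai.astype(np.int64), aj.astype(np.int64), ab.astype(float))
        if self.perimeter is None:
            self.perimeter = np.zeros(n)
        self.perimeter = np.asarray(self.perimeter, dtype=float)

    @property
    def n_units(self) -> int:
        return self.amounts.shape[0]

    def effective_p(self, feature_index: int) -> np.ndarray:
        """Unit condition probabilities as seen by a feature (1 when the
        feature is deterministic)."""
        if self.features[feature_index].probabilistic:
            return self.prob_good
        return np.ones(self.n_units)

    def to_deterministic(self) -> "Problem":
        """Same problem with every feature treated deterministically."""
        feats = [
            replace(f, probabilistic=False, certainty=None) for f in self.features
        ]
        return replace(self, features=feats)

    def _adjacency_csr(self):
        ai, aj, ab = self.adjacency
        n = self.n_units
        src = np.concatenate([ai, aj])
        dst = np.concatenate([aj, ai])
        w = np.concatenate([ab, ab])
        order = np.argsort(src, kind="stable")
        src, dst, w = src[order], dst[order], w[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr[1:], src, 1)
        indptr = np.cumsum(indptr)
        return indptr, dst.astype(np.int64), w.astype(float)


@dataclass
class AnnealConfig:
    """Annealing schedule and ensemble size.

    ``initial_temp="auto"`` sets the start temperature to the 90th
    percentile of |objective change| over random flips, so early moves
    are mostly accepted. Cooling is geometric per iteration;
    ``cooling_factor="auto"`` spans the whole run, bringing the
    temperature down to ``final_temp_fraction`` of its start by the last
    iteration (a fixed per-iteration factor freezes long runs early and
    wastes most iterations on pure descent).
    """

    n_iterations: int = 300_000
    initial_temp: float | str = "auto"
    cooling_factor: float | str = "auto"
    final_temp_fraction: float = 1e-4
    blm: float = 0.0
    n_solutions: int = 100
    base_seed: int = 0
    final_improvement: bool = True
    init_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cooling_factor != "auto" and not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must be in (0, 1) or 'auto'")
        if not 0 < self.final_temp_fraction < 1:
            raise ValueError("final_temp_fraction must be in (0, 1)")
        if self.blm < 0:
            raise ValueError("blm must be >= 0")
        if self.n_solutions < 1:
            raise ValueError("n_solutions must be >= 1")

    @property
    def effective_cooling(self) -> float:
        if self.cooling_factor == "auto":
            return float(np.exp(np.log(self.final_temp_fraction) / self.n_iterations))
        return float(self.cooling_factor)


@dataclass
class SolutionEnsemble:
    """Solutions from repeated annealing runs."""

    selections: np.ndarray  # (n_solutions, N) bool
    objective_breakdowns: list[dict]
    best_index: int
    selection_frequency: np.ndarray  # per-unit count in [0, n_solutions]

    @property
    def best_selection(self) -> np.ndarray:
        return self.selections[self.best_index]


def held_amount(selection: np.ndarray, amounts: np.ndarray, feature_index: int) -> float:
    """Amount of a feature held by the selected units."""
    sel = np.asarray(selection, dtype=bool)
    return float(np.asarray(amounts)[sel, feature_index].sum())


def prob_target_met(
    selection: np.ndarray, amounts: np.ndarray, p: np.ndarray, target: float
) -> float:
    """Normal-approximation probability that the selected units' random
    held amount reaches the target.

    The held amount is sum over selected units of a_i B_i with
    independent B_i ~ Bernoulli(p_i); the approximation uses its mean
    and variance. With zero variance the probability degenerates to the
    deterministic comparison.
    """
    sel = np.asarray(selection, dtype=bool)
    a = np.asarray(amounts, dtype=float).reshape(len(sel))[sel]
    pp = np.asarray(p, dtype=float)[sel]
    mu = float((a * pp).sum())
    s2 = float((a * a * pp * (1 - pp)).sum())
    if s2 <= 1e-300:
        return 1.0 if mu >= target - 1e-9 else 0.0
    return float(norm.sf((target - mu) / np.sqrt(s2)))


def exact_prob_target_met(
    selection: np.ndarray, amounts: np.ndarray, p: np.ndarray, target: float
) -> float:
    """Exact P(held >= target) for the independent-Bernoulli model.

    Equal-amount selections use the Poisson-binomial convolution over
    the survival count; unequal amounts fall back to enumeration over
    at most 2^20 outcomes. Test oracle, not the production path.
    """
    sel = np.asarray(selection, dtype=bool)
    a = np.asarray(amounts, dtype=float).reshape(len(sel))[sel]
    pp = np.asarray(p, dtype=float)[sel]
    n = len(a)
    if n == 0:
        return 1.0 if target <= 1e-9 else 0.0
    if np.allclose(a, a[0]):
        # Poisson-binomial over the number of surviving units
        dist = np.array([1.0])
        for pi in pp:
            dist = np.convolve(dist, [1 - pi, pi])
        k_min = int(np.ceil(target / a[0] - 1e-9))
        return float(dist[max(k_min, 0):].sum())
    if n > 20:
        raise ValueError("exact enumeration limited to 20 unequal-amount units")
    total = 0.0
    for bits in product((0, 1), repeat=n):
        b = np.asarray(bits, dtype=float)
        if (a * b).sum() >= target - 1e-9:
            pr = np.prod(np.where(b > 0, pp, 1 - pp))
            total += pr
    return float(total)


def _shortfalls(selection: np.ndarray, problem: Problem) -> np.ndarray:
    sel = np.asarray(selection, dtype=bool)
    out = np.zeros(len(problem.features))
    for j, f in enumerate(problem.features):
        held = held_amount(sel, problem.amounts, j)
        if not f.probabilistic:
            out[j] = max(0.0, f.target - held)
            continue
        a = problem.amounts[sel, j]
        pp = problem.prob_good[sel]
        mu = float((a * pp).sum())
        s2 = float((a * a * pp * (1 - pp)).sum())
        if s2 <= 1e-300:
            out[j] = max(0.0, f.target - mu)
        else:
            pm = float(norm.sf((f.target - mu) / np.sqrt(s2)))
            out[j] = max(0.0, (f.certainty - pm) * f.target)
    return out


def boundary_length(selection: np.ndarray, problem: Problem) -> float:
    """Exposed perimeter (km) of the selected set."""
    sel = np.asarray(selection, dtype=bool)
    ai, aj, ab = problem.adjacency
    exposed = float(problem.perimeter[sel].sum())
    both = sel[ai] & sel[aj]
    return exposed - 2.0 * float(ab[both].sum())


def objective(selection: np.ndarray, problem: Problem, config: AnnealConfig) -> tuple[float, dict]:
    """Total objective and its breakdown for a selection."""
    sel = np.asarray(selection, dtype=bool)
    cost = float(problem.cost[sel].sum())
    bound = boundary_length(sel, problem)
    sf = _shortfalls(sel, problem)
    det_pen = prob_pen = 0.0
    for j, f in enumerate(problem.features):
        if f.probabilistic:
            prob_pen += f.spf * sf[j]
        else:
            det_pen += f.spf * sf[j]
    total = cost + config.blm * bound + det_pen + prob_pen
    return total, {
        "cost": cost,
        "boundary": bound,
        "boundary_penalty": config.blm * bound,
        "shortfall_penalty": det_pen,
        "probability_penalty": prob_pen,
        "total": total,
    }


def default_spf(problem: Problem, factor: float = 10.0) -> np.ndarray:
    """Per-feature penalty factor: ``factor * max cost / mean amount``.

    Scales shortfall penalties so that buying even the most expensive
    unit is always preferable to leaving a comparable shortfall; with a
    heterogeneous cost surface a mean-cost scaling lets targets whose
    features sit on expensive units go unmet.
    """
    max_cost = max(problem.cost.max(), 1e-12)
    out = np.empty(len(problem.features))
    for j in range(len(problem.features)):
        col = problem.amounts[:, j]
        nz = col[col > 0]
        mean_amt = nz.mean() if len(nz) else 1.0
        out[j] = factor * max_cost / max(mean_amt, 1e-12)
    return out


def _kernel_args(problem: Problem, config: AnnealConfig):
    feats = problem.features
    prob_flag = np.array([f.probabilistic for f in feats], dtype=np.bool_)
    target = np.array([f.target for f in feats], dtype=float)
    spf = np.array([f.spf for f in feats], dtype=float)
    certainty = np.array(
        [f.certainty if f.certainty is not None else 1.0 for f in feats], dtype=float
    )
    indptr, indices, shared = problem._adjacency_csr()
    return (
        problem.cost,
        problem.amounts,
        problem.prob_good,
        prob_flag,
        target,
        spf,
        certainty,
        float(config.blm),
        problem.perimeter,
        indptr,
        indices,
        shared,
    )


def auto_initial_temp(problem: Problem, config: AnnealConfig, n_probe: int = 1000) -> float:
    """90th percentile of |objective change| over random single flips."""
    rng = np.random.default_rng(np.random.SeedSequence([config.base_seed, 0x7E4D]))
    n = problem.n_units
    deltas = []
    for _ in range(n_probe):
        sel = rng.random(n) < config.init_fraction
        i = int(rng.integers(n))
        base, _ = objective(sel, problem, config)
        flipped = sel.copy()
        flipped[i] = ~flipped[i]
        new, _ = objective(flipped, problem, config)
        deltas.append(abs(new - base))
    temp = float(np.percentile(deltas, 90))
    return max(temp, 1e-6)


def anneal(problem: Problem, config: AnnealConfig, seed: int) -> tuple[np.ndarray, dict]:
    """One annealing run; returns the selection and objective breakdown."""
    t0 = (
        auto_initial_temp(problem, config)
        if config.initial_temp == "auto"
        else float(config.initial_temp)
    )
    args = _kernel_args(problem, config)
    x = anneal_kernel(
        *args,
        np.int64(config.n_iterations),
        t0,
        config.effective_cooling,
        np.int64(seed % 2**31),
        config.final_improvement,
        config.init_fraction,
    )
    sel = x.astype(bool)
    _, breakdown = objective(sel, problem, config)
    return sel, breakdown


def solve_ensemble(problem: Problem, config: AnnealConfig) -> SolutionEnsemble:
    """Run ``n_solutions`` annealing restarts (seeds = base_seed + index).

    The best solution has the lowest total objective (ties break to the
    lowest run index); selection frequency counts how often each unit
    appears across the ensemble.
    """
    t0 = (
        auto_initial_temp(problem, config)
        if config.initial_temp == "auto"
        else float(config.initial_temp)
    )
    args = _kernel_args(problem, config)
    selections = np.zeros((config.n_solutions, problem.n_units), dtype=bool)
    breakdowns = []
    for k in range(config.n_solutions):
        x = anneal_kernel(
            *args,
            np.int64(config.n_iterations),
            t0,
            config.effective_cooling,
            np.int64((config.base_seed + k) % 2**31),
            config.final_improvement,
            config.init_fraction,
        )
        selections[k] = x.astype(bool)
        _, bd = objective(selections[k], problem, config)
        breakdowns.append(bd)
    totals = np.array([bd["total"] for bd in breakdowns])
    best = int(np.argmin(totals))  # argmin takes the first (lowest index) tie
    return SolutionEnsemble(
        selections=selections,
        objective_breakdowns=breakdowns,
        best_index=best,
        selection_frequency=selections.sum(axis=0),
    )


def reduce_check_deterministic(problem: Problem, config: AnnealConfig | None = None) -> bool:
    """Verify the probabilistic mode collapses onto the deterministic one
    when every unit's condition probability is 1.

    Runs the annealer in both modes with paired seeds and compares the
    resulting objectives; also spot-checks shortfall agreement on random
    selections.
    """
    if not np.allclose(problem.prob_good, 1.0):
        raise ValueError("reduction check requires all p_i = 1")
    config = config or AnnealConfig(n_iterations=5000, n_solutions=5)
    det = problem.to_deterministic()
    rng = np.random.default_rng(np.random.SeedSequence([config.base_seed, 0x4ED]))
    for _ in range(20):
        sel = rng.random(problem.n_units) < 0.5
        if not np.allclose(_shortfalls(sel, problem), _shortfalls(sel, det)):
            return False
    for k in range(config.n_solutions):
        seed = config.base_seed + k
        _, bd_p = anneal(problem, config, seed)
        _, bd_d = anneal(det, config, seed)
        if not np.isclose(bd_p["total"], bd_d["total"], rtol=1e-12, atol=1e-9):
            return False
    return True
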