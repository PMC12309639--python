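"""Scenario comparison: baseline vs cyclone-risk reserve designs.

Summarizes each scenario's best solution (area, cost, per-feature
representation), the overlap between the two selected sets, and the
high-priority area — units selected in strictly more than a threshold
fraction of the solution ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prioritize import Problem, held_amount, prob_target_met

__all__ = ["ScenarioComparison", "compare_best", "high_priority_area", "summarize_solution"]


@dataclass
class ScenarioComparison:
    """Cross-scenario summary of two best solutions (A and B)."""

    scenario_a: dict
    scenario_b: dict
    overlap_frac_a: float  # |A n B| / |A|
    overlap_frac_b: float  # |A n B| / |B|
    area_difference_pct_region: float
    region_area_km2: float


def summarize_solution(
    selection: np.ndarray, problem: Problem, unit_areas: np.ndarray
) -> dict:
    """Area, cost, and per-feature representation of one selection."""
    sel = np.asarray(selection, dtype=bool)
    features = {}
    for j, f in enumerate(problem.features):
        held = held_amount(sel, problem.amounts, j)
        entry = {"held_km2": held, "target_km2": f.target, "target_met": held >= f.target - 1e-9}
        if f.probabilistic:
            pm = prob_target_met(sel, problem.amounts[:, j], problem.prob_good, f.target)
            entry["prob_target_met"] = pm
            entry["certainty"] = f.certainty
            entry["certainty_met"] = pm >= f.certainty - 1e-9
        features[f.name] = entry
    return {
        "n_units": int(sel.sum()),
        "area_km2": float(np.asarray(unit_areas)[sel].sum()),
        "cost": float(problem.cost[sel].sum()),
        "features": features,
    }


def compare_best(
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    problem: Problem,
    unit_areas: np.ndarray,
    region_area_km2: float | None = None,
) -> ScenarioComparison:
    """Compare two best solutions over the same planning-unit universe.

    Overlap fractions share a single intersection: |A n B|/|A| and
    |A n B|/|B|. An empty selection yields overlap 0 by convention.
    """
    a = np.asarray(selection_a, dtype=bool)
    b = np.asarray(selection_b, dtype=bool)
    if a.shape != b.shape or len(a) != problem.n_units:
        raise ValueError("selections must share the problem's planning-unit universe")
    unit_areas = np.asarray(unit_areas, dtype=float)
    if region_area_km2 is None:
        region_area_km2 = float(unit_areas.sum())
    inter = float(unit_areas[a & b].sum())
    area_a = float(unit_areas[a].sum())
    area_b = float(unit_areas[b].sum())
    return ScenarioComparison(
        scenario_a=summarize_solution(a, problem, unit_areas),
        scenario_b=summarize_solution(b, problem, unit_areas),
        overlap_frac_a=inter / area_a if area_a > 0 else 0.0,
        overlap_frac_b=inter / area_b if area_b > 0 else 0.0,
        area_difference_pct_region=100.0 * (area_b - area_a) / region_area_km2,
        region_area_km2=region_area_km2,
    )


def high_priority_area(
    selection_frequency: np.ndarray,
    unit_areas: np.ndarray,
    threshold: float = 0.8,
    n_solutions: int | None = None,
) -> float:
    """Area (km^2) of units selected in strictly more than ``threshold``
    of the ensemble (counts are normalized by ``n_solutions`` if given)."""
    freq = np.asarray(selection_frequency, dtype=float)
    if n_solutions is not None:
        freq = freq / n_solutions
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("frequencies must be normalized to [0, 1]")
    return float(np.asarray(unit_areas, dtype=float)[freq > threshold].sum())
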