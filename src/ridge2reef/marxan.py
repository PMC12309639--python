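"""Marxan file-dialect interchange for planning problems.

Writes and reads the four classic tab-separated input tables so
problems can move between this package and Marxan-family tools:

- ``pu.dat``      — id, cost, status
- ``spec.dat``    — id, target, spf, name [, prob, ptarget]
- ``puvspr.dat``  — species, pu, amount (sorted by pu then species)
- ``bound.dat``   — id1, id2, boundary

Probabilistic features carry their certainty in a ``ptarget`` column and
per-unit condition probabilities ride along in a ``prob`` column of
``pu.dat`` (the probability dialect). A round trip preserves the
problem up to float formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .prioritize import FeatureSpec, Problem

__all__ = ["write_marxan", "read_marxan"]


def write_marxan(problem: Problem, directory: str | Path) -> dict[str, Path]:
    """Write the problem as Marxan input tables; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    pu = pd.DataFrame(
        {
            "id": problem.pu_ids,
            "cost": problem.cost,
            "status": 0,
            "prob": problem.prob_good,
        }
    )
    files["pu"] = directory / "pu.dat"
    pu.to_csv(files["pu"], sep="\t", index=False)

    rows = []
    for f in problem.features:
        row = {"id": f.feature_id, "target": f.target, "spf": f.spf, "name": f.name}
        if f.probabilistic:
            row["ptarget"] = f.certainty
        rows.append(row)
    spec = pd.DataFrame(rows)
    files["spec"] = directory / "spec.dat"
    spec.to_csv(files["spec"], sep="\t", index=False)

    unit_idx, feat_idx = np.nonzero(problem.amounts)
    puvspr = pd.DataFrame(
        {
            "species": [problem.features[j].feature_id for j in feat_idx],
            "pu": problem.pu_ids[unit_idx],
            "amount": problem.amounts[unit_idx, feat_idx],
        }
    ).sort_values(["pu", "species"], kind="stable")
    files["puvspr"] = directory / "puvspr.dat"
    puvspr.to_csv(files["puvspr"], sep="\t", index=False)

    ai, aj, ab = problem.adjacency
    bound = pd.DataFrame(
        {"id1": problem.pu_ids[ai], "id2": problem.pu_ids[aj], "boundary": ab}
    )
    files["bound"] = directory / "bound.dat"
    bound.to_csv(files["bound"], sep="\t", index=False)
    return files


def read_marxan(directory: str | Path, perimeter_per_unit: float = 4.0) -> Problem:
    """Reassemble a :class:`Problem` from Marxan input tables.

    ``perimeter_per_unit`` sets each unit's isolated exposed boundary
    (4 km for 1x1-km grid units), which the dialect does not store.
    """
    directory = Path(directory)
    pu = pd.read_csv(directory / "pu.dat", sep="\t")
    spec = pd.read_csv(directory / "spec.dat", sep="\t")
    puvspr = pd.read_csv(directory / "puvspr.dat", sep="\t")
    bound_path = directory / "bound.dat"
    bound = pd.read_csv(bound_path, sep="\t") if bound_path.exists() else None

    pu_ids = pu["id"].to_numpy()
    id_to_idx = {int(i): k for k, i in enumerate(pu_ids)}
    features = []
    fid_to_col = {}
    for j, row in enumerate(spec.itertuples()):
        certainty = getattr(row, "ptarget", None)
        probabilistic = certainty is not None and not pd.isna(certainty)
        features.append(
            FeatureSpec(
                feature_id=int(row.id),
                name=str(row.name) if "name" in spec.columns else str(row.id),
                target=float(row.target),
                spf=float(row.spf),
                certainty=float(certainty) if probabilistic else None,
                probabilistic=probabilistic,
            )
        )
        fid_to_col[int(row.id)] = j

    amounts = np.zeros((len(pu_ids), len(features)))
    for row in puvspr.itertuples():
        amounts[id_to_idx[int(row.pu)], fid_to_col[int(row.species)]] = row.amount

    adjacency = None
    if bound is not None and len(bound):
        ai = np.array([id_to_idx[int(i)] for i in bound["id1"]])
        aj = np.array([id_to_idx[int(i)] for i in bound["id2"]])
        adjacency = (ai, aj, bound["boundary"].to_numpy(dtype=float))

    prob = pu["prob"].to_numpy(dtype=float) if "prob" in pu.columns else None
    return Problem(
        pu_ids=pu_ids,
        cost=pu["cost"].to_numpy(dtype=float),
        amounts=amounts,
        features=features,
        prob_good=prob,
        adjacency=adjacency,
        perimeter=np.full(len(pu_ids), perimeter_per_unit),
    )
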