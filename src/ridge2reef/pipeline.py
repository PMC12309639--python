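"""End-to-end pipeline: synthetic world -> runoff -> plume -> coral ->
prioritization -> scenario comparison.

Every stage reads only the config and the previous stage's artifacts on
disk (ASCII grids, CSV, GeoJSON, JSON), writes its own artifacts, and
registers them in a manifest with SHA-256 checksums, so re-running any
stage with an unchanged config reproduces its outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coral as coral_mod
from . import hydro, plume, report, synth
from .grid import Grid, read_ascii_grid, write_ascii_grid
from .prioritize import (
    AnnealConfig,
    FeatureSpec,
    Problem,
    SolutionEnsemble,
    default_spf,
    solve_ensemble,
)

__all__ = ["PipelineConfig", "run_pipeline", "problem_from_artifacts"]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("coral", "mangrove", "seagrass", "turtle_grounds")

DEFAULT_FEATURES = [
    {"name": "coral", "target_fraction": 0.30, "probabilistic": True, "certainty": 0.90},
    {"name": "mangrove", "target_fraction": 0.30, "probabilistic": False},
    {"name": "seagrass", "target_fraction": 0.30, "probabilistic": False},
    {"name": "turtle_grounds", "target_fraction": 0.10, "probabilistic": False},
]


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run.

    ``features`` entries: name, target_fraction (of the feature's total
    amount), probabilistic flag, certainty (probabilistic only) and an
    optional spf (defaulting to 10 x mean cost / mean amount).
    """

    seed: int = 0
    out_dir: str = "artifacts"
    landscape: dict = field(default_factory=dict)
    musle: dict = field(default_factory=dict)
    dispersion: dict = field(default_factory=dict)
    surveys: dict = field(default_factory=lambda: {"n_sites": 72, "transects": 3, "points_per_transect": 100})
    coral_fit: dict = field(default_factory=lambda: {"n_basis": 10, "n_draws": 1000, "threshold": 0.30})
    features: list = field(default_factory=lambda: [dict(f) for f in DEFAULT_FEATURES])
    anneal: dict = field(default_factory=dict)
    cost_floor_frac: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, val in raw.items():
            cur = getattr(base, key)
            if isinstance(cur, dict) and isinstance(val, dict):
                cur.update(val)
            else:
                setattr(base, key, val)
        return base

    @property
    def out_path(self) -> Path:
        return Path(self.out_dir)


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data: dict = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, seed: int, files: list[Path], inputs: list[Path] = ()):
        self.data[stage] = {
            "seed": seed,
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in files},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> list[Path]:
    """Generate the synthetic world and write its layers."""
    out = config.out_path
    out.mkdir(parents=True, exist_ok=True)
    lc = synth.LandscapeConfig(**config.landscape)
    bundle = synth.generate_landscape(lc, seed=config.seed)
    files = []
    grids = {
        "dem": bundle.dem,
        "landcover": bundle.landcover,
        "c_factor": bundle.c_factor,
        "k_factor": bundle.k_factor,
        "curve_number": bundle.curve_number,
        "storm_precip": bundle.storm_precip,
        "sea_mask": bundle.sea_mask.like(np.asarray(bundle.sea_mask.values, dtype=float)),
        "cost": bundle.cost,
    }
    for name, g in bundle.feature_grids.items():
        grids[f"feature_{name}"] = g
    for name, g in grids.items():
        p = out / f"{name}.asc"
        write_ascii_grid(g, p)
        files.append(p)

    towns = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"population": w},
            }
            for x, y, w in bundle.population_points
        ],
    }
    p = out / "population.geojson"
    _write_json(p, towns)
    files.append(p)

    truth = {
        "cover_intercept": bundle.truth.cover_intercept,
        "site_sd": bundle.truth.site_sd,
        "seed": bundle.truth.seed,
        "curve": "default",
    }
    p = out / "truth.json"
    _write_json(p, truth)
    files.append(p)
    _Manifest(out).record("simulate", config.seed, files)
    return files


def _load_truth(out: Path) -> synth.SyntheticTruth:
    d = json.loads((out / "truth.json").read_text())
    if d.get("curve", "default") != "default":
        raise ValueError("only the default truth curve is disk-serializable")
    return synth.SyntheticTruth(
        cover_intercept=d["cover_intercept"], site_sd=d["site_sd"], seed=int(d["seed"])
    )


def stage_runoff(config: PipelineConfig) -> list[Path]:
    """Fill, route, run MUSLE, and export pour-point loads."""
    out = config.out_path
    inputs = [out / f"{n}.asc" for n in ("dem", "storm_precip", "curve_number", "k_factor", "c_factor")]
    dem, precip, cn, k, c = (read_ascii_grid(p) for p in inputs)
    params = hydro.MusleParams(**config.musle)
    loads, grids = hydro.storm_sediment_loads(dem, precip, cn, k, c, params)
    files = []
    for name in ("filled_dem", "directions", "watersheds", "yield"):
        p = out / f"{name}.asc"
        write_ascii_grid(grids[name], p)
        files.append(p)
    rows = []
    for ld in loads:
        x, y = dem.cell_center(ld.row, ld.col)
        rows.append((ld.outlet_id, ld.row, ld.col, float(x), float(y), ld.watershed_id, ld.load))
    df = pd.DataFrame(rows, columns=["outlet_id", "row", "col", "x", "y", "watershed_id", "load"])
    p = out / "pour_points.csv"
    df.to_csv(p, index=False)
    files.append(p)
    _Manifest(out).record("runoff", config.seed, files, inputs)
    return files


def _load_pour_points(out: Path) -> list[hydro.PourPointLoad]:
    df = pd.read_csv(out / "pour_points.csv")
    return [
        hydro.PourPointLoad(int(r.outlet_id), int(r.row), int(r.col), int(r.watershed_id), float(r.load))
        for r in df.itertuples()
    ]


def stage_disperse(config: PipelineConfig) -> list[Path]:
    """Spread pour-point loads over the sea as a relative TSS field."""
    out = config.out_path
    inputs = [out / "sea_mask.asc", out / "pour_points.csv"]
    sea = read_ascii_grid(out / "sea_mask.asc")
    sea = sea.like(np.asarray(sea.values) > 0.5)
    loads = _load_pour_points(out)
    params = plume.DispersionParams(**config.dispersion)
    f = plume.tss_field(loads, sea, params)
    files = []
    for name, g in (("tss", f.tss), ("log_tss", f.log_tss)):
        p = out / f"{name}.asc"
        write_ascii_grid(g, p)
        files.append(p)
    _Manifest(out).record("disperse", config.seed, files, inputs)
    return files


def stage_coral(config: PipelineConfig) -> list[Path]:
    """Survey, fit the condition model, and map P(cover > threshold)."""
    out = config.out_path
    inputs = [out / "log_tss.asc", out / "feature_coral.asc", out / "truth.json"]
    log_tss = read_ascii_grid(out / "log_tss.asc")
    coral_amt = read_ascii_grid(out / "feature_coral.asc")
    coral_mask = coral_amt.like(np.asarray(coral_amt.values) > 0)
    truth = _load_truth(out)

    sv_cfg = dict(config.surveys)
    surveys = synth.generate_surveys(
        log_tss, coral_mask, truth, seed=config.seed, **sv_cfg
    )
    files = []
    p = out / "surveys.csv"
    surveys.to_csv(p, index=False)
    files.append(p)

    fit_cfg = dict(config.coral_fit)
    n_draws = int(fit_cfg.pop("n_draws", 1000))
    threshold = float(fit_cfg.pop("threshold", 0.30))
    model = coral_mod.fit_condition_model(surveys, **fit_cfg)
    ratio, verdict = coral_mod.check_overdispersion(model, surveys)
    draws = coral_mod.posterior_draws(model, n_draws, seed=config.seed)
    surface = coral_mod.prob_good_condition(model, draws, log_tss, coral_mask, threshold)

    p = out / "prob_good.asc"
    write_ascii_grid(surface.prob_good, p)
    files.append(p)
    summary = {
        "coefficients": model.coefficients.tolist(),
        "smoothing_param": model.smoothing_param,
        "site_lambda": model.site_lambda,
        "site_effect_sd": model.site_effect_sd,
        "deviance_explained": model.deviance_explained,
        "edf": model.edf,
        "overdispersion_ratio": ratio,
        "overdispersion_verdict": verdict,
        "threshold": threshold,
        "n_draws": n_draws,
    }
    p = out / "coral_model.json"
    _write_json(p, summary)
    files.append(p)
    _Manifest(out).record("coral", config.seed, files, inputs)
    return files


def problem_from_artifacts(config: PipelineConfig, scenario: str) -> tuple[Problem, np.ndarray]:
    """Assemble the planning problem from on-disk artifacts.

    Planning units are the sea cells; unit cost is the kernel density
    times the cell area; feature amounts come from the synthetic feature
    layers; targets resolve target fractions against each feature's
    total amount. The cyclone scenario attaches the coral condition
    probabilities; the baseline treats every feature deterministically.
    Returns the problem and the per-unit areas (km^2).
    """
    if scenario not in ("baseline", "cyclone"):
        raise ValueError(f"unknown scenario {scenario!r}")
    out = config.out_path
    sea_g = read_ascii_grid(out / "sea_mask.asc")
    sea = np.asarray(sea_g.values) > 0.5
    cost_g = read_ascii_grid(out / "cost.asc")
    rows, cols = np.nonzero(sea)
    n = len(rows)
    cell_area = sea_g.cell_area_km2
    cell_km = sea_g.cell_size_m / 1000.0

    cost = np.asarray(cost_g.values, dtype=float)[rows, cols] * sea_g.cell_size_m**2
    # area-based cost floor: units the fishery never touches still carry a
    # small acquisition cost, so the minimum-set solution has no free units
    pos = cost[cost > 0]
    floor = config.cost_floor_frac * (pos.mean() if len(pos) else 1.0)
    cost = cost + max(floor, 1e-9)
    amounts = np.zeros((n, len(config.features)))
    feats: list[FeatureSpec] = []
    for j, fc in enumerate(config.features):
        g = read_ascii_grid(out / f"feature_{fc['name']}.asc")
        amounts[:, j] = np.asarray(g.values, dtype=float)[rows, cols]

    prob_good = np.ones(n)
    if scenario == "cyclone":
        pg = read_ascii_grid(out / "prob_good.asc")
        vals = np.asarray(pg.values, dtype=float)[rows, cols]
        valid = pg.valid()[rows, cols]
        has_coral = amounts[:, _coral_index(config)] > 0
        prob_good[has_coral & valid] = vals[has_coral & valid]

    # rook adjacency over sea cells, shared boundary = one cell side
    idx = np.full(sea.shape, -1, dtype=np.int64)
    idx[rows, cols] = np.arange(n)
    ai, aj = [], []
    for dr, dc in ((0, 1), (1, 0)):
        rr, cc = rows + dr, cols + dc
        ok = (rr < sea.shape[0]) & (cc < sea.shape[1])
        ok[ok] &= sea[rr[ok], cc[ok]]
        ai.extend(idx[rows[ok], cols[ok]])
        aj.extend(idx[rr[ok], cc[ok]])
    adjacency = (np.asarray(ai), np.asarray(aj), np.full(len(ai), cell_km))
    perimeter = np.full(n, 4 * cell_km)

    for j, fc in enumerate(config.features):
        total = amounts[:, j].sum()
        probabilistic = bool(fc.get("probabilistic", False)) and scenario == "cyclone"
        feats.append(
            FeatureSpec(
                feature_id=j,
                name=fc["name"],
                target=float(fc["target_fraction"]) * total,
                spf=float(fc["spf"]) if "spf" in fc else 1.0,  # placeholder, set below
                certainty=float(fc.get("certainty", 0.9)) if probabilistic else None,
                probabilistic=probabilistic,
            )
        )
    problem = Problem(
        pu_ids=rows * sea.shape[1] + cols,
        cost=cost,
        amounts=amounts,
        features=feats,
        prob_good=prob_good,
        adjacency=adjacency,
        perimeter=perimeter,
    )
    spf = default_spf(problem)
    for j, fc in enumerate(config.features):
        if "spf" not in fc:
            problem.features[j].spf = float(spf[j])
    unit_areas = np.full(n, cell_area)
    return problem, unit_areas


def _coral_index(config: PipelineConfig) -> int:
    for j, fc in enumerate(config.features):
        if fc["name"] == "coral":
            return j
    raise ValueError("no coral feature configured")


def stage_prioritize(config: PipelineConfig, scenario: str) -> list[Path]:
    """Solve one scenario's ensemble and write solutions + frequencies."""
    out = config.out_path
    problem, unit_areas = problem_from_artifacts(config, scenario)
    cfg = AnnealConfig(base_seed=config.seed, **config.anneal)
    logger.info(
        "scenario %s: %d units, blm=%g, iterations=%d, solutions=%d, spf=%s",
        scenario, problem.n_units, cfg.blm, cfg.n_iterations, cfg.n_solutions,
        [round(f.spf, 3) for f in problem.features],
    )
    ens = solve_ensemble(problem, cfg)
    best = ens.best_selection
    files = []
    df = pd.DataFrame(
        {
            "pu_id": problem.pu_ids,
            "best_solution": best.astype(int),
            "selection_frequency": ens.selection_frequency,
        }
    )
    p = out / f"solution_{scenario}.csv"
    df.to_csv(p, index=False)
    files.append(p)

    # rasterized best solution (0/1) and selection frequency (0-1)
    sea_g = read_ascii_grid(out / "sea_mask.asc")
    sea = np.asarray(sea_g.values) > 0.5
    rows_, cols_ = np.nonzero(sea)
    for name, vec in (
        ("best", best.astype(float)),
        ("freq", ens.selection_frequency / cfg.n_solutions),
    ):
        arr = np.zeros(sea.shape)
        arr[rows_, cols_] = vec
        p = out / f"solution_{scenario}_{name}.asc"
        write_ascii_grid(sea_g.like(arr, nodata_mask=~sea), p)
        files.append(p)

    summary = {
        "scenario": scenario,
        "best_index": ens.best_index,
        "best_breakdown": ens.objective_breakdowns[ens.best_index],
        "summary": report.summarize_solution(best, problem, unit_areas),
        "n_solutions": cfg.n_solutions,
    }
    p = out / f"solution_{scenario}.json"
    _write_json(p, summary)
    files.append(p)
    _Manifest(out).record(f"prioritize_{scenario}", config.seed, files)
    return files


def stage_compare(config: PipelineConfig) -> list[Path]:
    """Compare the baseline and cyclone-risk scenario outputs."""
    out = config.out_path
    problem, unit_areas = problem_from_artifacts(config, "cyclone")
    sols = {}
    freqs = {}
    for scen in ("baseline", "cyclone"):
        df = pd.read_csv(out / f"solution_{scen}.csv")
        sols[scen] = df["best_solution"].to_numpy(dtype=bool)
        n_sol = json.loads((out / f"solution_{scen}.json").read_text())["n_solutions"]
        freqs[scen] = df["selection_frequency"].to_numpy(dtype=float) / n_sol
    sea_area = float(unit_areas.sum())
    comp = report.compare_best(
        sols["baseline"], sols["cyclone"], problem, unit_areas, region_area_km2=sea_area
    )
    result = {
        "baseline": comp.scenario_a,
        "cyclone": comp.scenario_b,
        "overlap_cyclone_in_baseline": comp.overlap_frac_b,
        "overlap_baseline_in_cyclone": comp.overlap_frac_a,
        "area_difference_pct_region": comp.area_difference_pct_region,
        "region_area_km2": comp.region_area_km2,
        "high_priority_area_km2": {
            scen: report.high_priority_area(freqs[scen], unit_areas, 0.8) for scen in freqs
        },
    }
    p = out / "comparison.json"
    _write_json(p, result)
    _Manifest(out).record("compare", config.seed, [p])
    logger.info(
        "baseline: %.0f km2 cost %.0f | cyclone: %.0f km2 cost %.0f | overlap %.0f%%/%.0f%%",
        comp.scenario_a["area_km2"], comp.scenario_a["cost"],
        comp.scenario_b["area_km2"], comp.scenario_b["cost"],
        100 * comp.overlap_frac_b, 100 * comp.overlap_frac_a,
    )
    return [p]


STAGES = ("simulate", "runoff", "disperse", "coral", "prioritize", "compare")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order; returns the artifact directory."""
    for stage in STAGES:
        try:
            if stage == "prioritize":
                stage_prioritize(config, "baseline")
                stage_prioritize(config, "cyclone")
            else:
                globals()[f"stage_{stage}"](config)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return config.out_path
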