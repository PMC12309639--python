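"""Synthetic land-sea study systems with known ground truth.

Generates everything the pipeline consumes for a volcanic-island
seascape: a fractal-noise island DEM draining to multiple coastal river
mouths, categorical land cover with per-class cover-management (C)
factors and curve numbers, soil erodibility, storm rainfall, a marine
planning grid carrying coral / mangrove / seagrass / turtle-ground
amounts, coastal population centres with a kernel-density fishing-cost
surface, and binomial point-intercept reef surveys whose hard-coral
cover follows a known smooth function of log-TSS plus site-level random
intercepts.

Because the data-generating process is known exactly, every downstream
stage (routing, dispersion, condition modelling, prioritization) can be
tested for parameter recovery rather than only for plumbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid

__all__ = [
    "LandscapeConfig",
    "SyntheticTruth",
    "LandscapeBundle",
    "default_cover_curve",
    "generate_landscape",
    "kernel_density_cost",
    "generate_surveys",
]

# land-cover class codes
FOREST, GRASSLAND, AGRICULTURE, URBAN = 1, 2, 3, 4

DEFAULT_C_FACTORS = {FOREST: 0.003, GRASSLAND: 0.05, AGRICULTURE: 0.35, URBAN: 0.01}
DEFAULT_CURVE_NUMBERS = {FOREST: 58.0, GRASSLAND: 69.0, AGRICULTURE: 78.0, URBAN: 92.0}


def default_cover_curve(log_tss: np.ndarray) -> np.ndarray:
    """Default smooth declining trend of logit hard-coral cover vs log-TSS.

    Monotone-decreasing with a gentle bend; combined with the default
    intercept it sweeps cover from roughly 80% in clear water down to
    below 10% at the most turbid cells of a default landscape.
    """
    x = np.asarray(log_tss, dtype=float)
    return -0.78 * x - 0.2 * np.sin(x / 1.5)


@dataclass
class SyntheticTruth:
    """Ground-truth data-generating process for the coral condition model.

    logit(cover) at a cell is ``cover_intercept + cover_curve(log_tss)``
    plus a site-level random intercept with SD ``site_sd``.
    """

    cover_intercept: float = 6.0
    cover_curve: Callable[[np.ndarray], np.ndarray] = default_cover_curve
    site_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_sd < 0:
            raise ValueError("site_sd must be >= 0")

    def logit_cover(self, log_tss: np.ndarray) -> np.ndarray:
        return self.cover_intercept + self.cover_curve(np.asarray(log_tss, dtype=float))

    def true_cover(self, log_tss: np.ndarray) -> np.ndarray:
        eta = self.logit_cover(log_tss)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class LandscapeConfig:
    """Size, shape, and class-mix parameters of the synthetic system.

    Defaults describe a single ~25-km volcanic island on a 64 km x 64 km
    region at 1-km resolution — the planning grid and the terrain grid
    coincide, so every sea cell is a 1 x 1 km planning unit.
    """

    nrows: int = 64
    ncols: int = 64
    cell_size_m: float = 1000.0
    n_islands: int = 1
    land_fraction: float = 0.22
    relief_m: float = 700.0
    smooth_sigma: float = 3.0
    storm_precip_mm: float = 300.0
    c_factors: dict = field(default_factory=lambda: dict(DEFAULT_C_FACTORS))
    curve_numbers: dict = field(default_factory=lambda: dict(DEFAULT_CURVE_NUMBERS))
    reef_offset_cells: tuple[float, float] = (3.0, 7.0)
    n_towns: int = 5
    total_population: int = 60000
    cost_radius_cells: float = 10.0

    def __post_init__(self) -> None:
        if self.nrows < 32 or self.ncols < 32:
            raise ValueError("grid must be at least 32x32")
        if self.n_islands < 1:
            raise ValueError("need at least one island")
        if not 0 < self.land_fraction < 1:
            raise ValueError("land_fraction must be in (0, 1)")


@dataclass
class LandscapeBundle:
    """Complete synthetic study system (terrain + sea + truth)."""

    dem: Grid
    landcover: Grid
    c_factor_table: dict
    c_factor: Grid
    k_factor: Grid
    curve_number: Grid
    storm_precip: Grid
    sea_mask: Grid
    feature_grids: dict[str, Grid]
    population_points: list[tuple[float, float, float]]
    cost: Grid
    truth: SyntheticTruth


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def generate_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> LandscapeBundle:
    """Build a complete synthetic island system, deterministically per seed.

    The DEM is a sum of radial island bumps plus smoothed fractal noise,
    thresholded at the sea level giving the requested land fraction; the
    outer two cell rings are forced to sea so every watershed reaches a
    coastal outlet. Raises if the configuration degenerates to all sea
    or all land.
    """
    config = config or LandscapeConfig()
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    nrows, ncols = config.nrows, config.ncols
    shape = (nrows, ncols)

    # --- terrain -----------------------------------------------------------
    rng = rngs[0]
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    raw = 0.45 * _smooth_noise(rng, shape, config.smooth_sigma)
    half = min(nrows, ncols) / 2.0
    for _ in range(config.n_islands):
        cy = nrows / 2 + rng.uniform(-0.15, 0.15) * nrows
        cx = ncols / 2 + rng.uniform(-0.15, 0.15) * ncols
        rad = half * rng.uniform(0.5, 0.7)
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        raw += np.maximum(0.0, 1.0 - (d / rad) ** 1.5)

    raw[:2, :] = raw[-2:, :] = raw.min() - 1.0
    raw[:, :2] = raw[:, -2:] = raw.min() - 1.0
    sea_level = np.quantile(raw, 1.0 - config.land_fraction)
    land = raw > sea_level
    # keep the n_islands largest connected components
    labels, n_comp = ndimage.label(land)
    if n_comp == 0:
        raise ValueError("degenerate config: all sea")
    sizes = ndimage.sum_labels(np.ones(shape), labels, index=np.arange(1, n_comp + 1))
    keep = np.argsort(sizes)[::-1][: config.n_islands] + 1
    land = np.isin(labels, keep)
    if land.all():
        raise ValueError("degenerate config: all land")
    if not land.any():
        raise ValueError("degenerate config: all sea")

    elev = np.where(land, (raw - sea_level) / (raw.max() - sea_level), 0.0)
    elev = np.where(land, 5.0 + elev * config.relief_m, 0.0)
    dem = Grid(elev, config.cell_size_m, nodata_mask=~land)

    # --- land cover, soils, rainfall --------------------------------------
    rng = rngs[1]
    suit = 0.6 * (elev / max(elev.max(), 1.0)) + 0.4 * _smooth_noise(rng, shape, 2.0)
    vals = suit[land]
    q = np.quantile(vals, [0.05, 0.30, 0.60])
    lc = np.full(shape, FOREST, dtype=np.int64)
    lc[suit < q[2]] = GRASSLAND
    lc[suit < q[1]] = AGRICULTURE
    lc[suit < q[0]] = URBAN
    lc[~land] = 0
    landcover = Grid(lc, config.cell_size_m, nodata_mask=~land)

    c_vals = np.zeros(shape)
    cn_vals = np.zeros(shape)
    for cls, cval in config.c_factors.items():
        c_vals[lc == cls] = cval
    for cls, cn in config.curve_numbers.items():
        cn_vals[lc == cls] = cn
    cn_vals += np.where(land, rng.normal(0.0, 2.0, shape), 0.0)
    cn_vals = np.clip(cn_vals, 30.0, 100.0)
    cn_vals[~land] = 0.0
    c_factor = Grid(c_vals, config.cell_size_m, nodata_mask=~land)
    curve_number = Grid(cn_vals, config.cell_size_m, nodata_mask=~land)

    k_vals = np.clip(0.18 + 0.08 * _smooth_noise(rng, shape, 2.5), 0.02, None)
    k_vals[~land] = 0.0
    k_factor = Grid(k_vals, config.cell_size_m, nodata_mask=~land)

    precip = config.storm_precip_mm * (1.0 + 0.25 * _smooth_noise(rng, shape, 6.0))
    precip = np.clip(precip, 50.0, None)
    precip[~land] = 0.0
    storm_precip = Grid(precip, config.cell_size_m, nodata_mask=~land)

    sea = ~land
    sea_mask = Grid(sea, config.cell_size_m)

    # --- marine conservation features -------------------------------------
    rng = rngs[2]
    dist_to_land = ndimage.distance_transform_edt(sea)
    cell_area = (config.cell_size_m / 1000.0) ** 2
    lo, hi = config.reef_offset_cells
    mid = 0.5 * (lo + hi)

    reef_noise = _smooth_noise(rng, shape, 2.0)
    in_band = sea & (dist_to_land >= lo) & (dist_to_land <= hi)
    band_score = 1.0 - np.abs(dist_to_land - mid) / (hi - lo)
    coral_presence = in_band & (reef_noise + band_score > 0.35)
    coral = np.where(coral_presence, cell_area * np.clip(0.3 + 0.4 * band_score, 0, 1), 0.0)

    mangrove_zone = sea & (dist_to_land <= 1.5)
    mangrove = np.where(
        mangrove_zone & (rng.random(shape) < 0.6), cell_area * 0.4, 0.0
    )

    sg_noise = _smooth_noise(rng, shape, 1.5)
    seagrass_zone = sea & (dist_to_land >= 1.0) & (dist_to_land <= 3.5)
    seagrass = np.where(seagrass_zone & (sg_noise > 0.3), cell_area * 0.6, 0.0)

    turtle = np.zeros(shape)
    host = np.argwhere((seagrass > 0) | (coral > 0))
    if len(host) > 0:
        n_patches = 3
        picks = host[rng.choice(len(host), size=min(n_patches, len(host)), replace=False)]
        for py, px in picks:
            d = np.sqrt((yy - py) ** 2 + (xx - px) ** 2)
            turtle[sea & (d <= 4.0)] = cell_area * 0.8

    feature_grids = {
        name: Grid(arr, config.cell_size_m, nodata_mask=~sea)
        for name, arr in [
            ("coral", coral),
            ("mangrove", mangrove),
            ("seagrass", seagrass),
            ("turtle_grounds", turtle),
        ]
    }

    # --- population centres and fishing-cost surface -----------------------
    rng = rngs[3]
    coast_dist = ndimage.distance_transform_edt(land)  # distance to sea, on land
    coastal = np.argwhere(land & (coast_dist <= 2.0))
    towns: list[tuple[float, float, float]] = []
    if len(coastal) > 0:
        n_towns = min(config.n_towns, len(coastal))
        picks = coastal[rng.choice(len(coastal), size=n_towns, replace=False)]
        weights = rng.dirichlet(np.full(n_towns, 1.5)) * config.total_population
        for (py, px), w in zip(picks, weights):
            x, y = dem.cell_center(int(py), int(px))
            towns.append((float(x), float(y), float(w)))
    cost = kernel_density_cost(
        towns, sea_mask, radius_m=config.cost_radius_cells * config.cell_size_m
    )

    truth = SyntheticTruth(seed=seed)
    bundle = LandscapeBundle(
        dem=dem,
        landcover=landcover,
        c_factor_table=dict(config.c_factors),
        c_factor=c_factor,
        k_factor=k_factor,
        curve_number=curve_number,
        storm_precip=storm_precip,
        sea_mask=sea_mask,
        feature_grids=feature_grids,
        population_points=towns,
        cost=cost,
        truth=truth,
    )
    _validate_bundle(bundle)
    return bundle


def _validate_bundle(bundle: LandscapeBundle) -> None:
    land = bundle.dem.valid()
    cn = np.asarray(bundle.curve_number.values)[land]
    if ((cn < 30) | (cn > 100)).any():
        raise AssertionError("curve numbers out of [30, 100] on land")
    if (np.asarray(bundle.k_factor.values)[land] < 0).any():
        raise AssertionError("negative soil erodibility")
    sea = np.asarray(bundle.sea_mask.values, dtype=bool)
    area = bundle.dem.cell_area_km2
    for name, g in bundle.feature_grids.items():
        v = np.asarray(g.values)
        if (v < 0).any() or (v > area + 1e-9).any():
            raise AssertionError(f"feature {name} amount outside [0, cell area]")
        if (v[~sea] > 0).any():
            raise AssertionError(f"feature {name} present on land")


def kernel_density_cost(
    population_points: list[tuple[float, float, float]],
    grid_template: Grid,
    radius_m: float,
) -> Grid:
    """Quartic (biweight) kernel density of population, per m^2.

    A point of weight w contributes ``w * 3/(pi r^2) * (1 - (d/r)^2)^2``
    at distance d < r and nothing beyond; contributions add. The kernel
    integrates to w over the plane, so the density times cell area sums
    back to the total population (up to discretization error).
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    if not population_points:
        warnings.warn("no population points; cost surface is zero", stacklevel=2)
        return grid_template.like(np.zeros(grid_template.shape), nodata_mask=np.zeros(grid_template.shape, bool))
    nrows, ncols = grid_template.shape
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    cx, cy = grid_template.cell_center(rows.ravel(), cols.ravel())
    pts = np.asarray([(x, y) for x, y, _ in population_points], dtype=float)
    w = np.asarray([p[2] for p in population_points], dtype=float)
    d2 = (cx[:, None] - pts[None, :, 0]) ** 2 + (cy[:, None] - pts[None, :, 1]) ** 2
    u2 = d2 / radius_m**2
    kern = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0) * (3.0 / (np.pi * radius_m**2))
    dens = (kern * w[None, :]).sum(axis=1).reshape(nrows, ncols)
    return grid_template.like(dens, nodata_mask=np.zeros(grid_template.shape, bool))


def generate_surveys(
    tss_log_grid: Grid,
    coral_mask: Grid,
    truth: SyntheticTruth,
    n_sites: int = 72,
    transects: int = 3,
    points_per_transect: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate point-intercept reef surveys at sites stratified over log-TSS.

    Each site pools ``transects * points_per_transect`` benthic points
    (default 3 x 100). A site draws a random intercept
    ``u ~ N(0, site_sd^2)``, its cover is
    ``invlogit(intercept + curve(log_tss) + u)``, and the hard-coral
    count is binomial. Sites are one-per-stratum over the log-TSS range
    of coral-bearing cells so the covariate is well identified.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA]))
    coral = np.asarray(coral_mask.values, dtype=bool) & coral_mask.valid()
    usable = coral & tss_log_grid.valid()
    cells = np.argwhere(usable)
    if len(cells) < n_sites:
        raise ValueError(
            f"only {len(cells)} coral cells with TSS, need {n_sites} survey sites"
        )
    log_tss = np.asarray(tss_log_grid.values, dtype=float)[cells[:, 0], cells[:, 1]]

    order = np.argsort(log_tss, kind="stable")
    strata = np.array_split(order, n_sites)
    chosen = np.array([s[rng.integers(len(s))] for s in strata])

    n_points = transects * points_per_transect
    records = []
    for sid, ci in enumerate(chosen):
        r, c = cells[ci]
        x, y = tss_log_grid.cell_center(int(r), int(c))
        lt = log_tss[ci]
        u = rng.normal(0.0, truth.site_sd) if truth.site_sd > 0 else 0.0
        p = 1.0 / (1.0 + np.exp(-(truth.logit_cover(lt) + u)))
        k = int(rng.binomial(n_points, p))
        records.append((sid, float(x), float(y), n_points, k, float(lt)))
    return pd.DataFrame(
        records, columns=["site_id", "x", "y", "n_points", "n_hard_coral", "log_tss"]
    )
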