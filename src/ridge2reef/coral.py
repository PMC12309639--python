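"""Hard-coral condition under suspended sediment.

Fits a binomial generalized additive model of hard-coral cover against
log-TSS: logit(p) = f(log_tss) + u_site, where f is a penalized cubic
regression spline (exact integrated second-derivative penalty, knots at
covariate quantiles) and the site intercepts u are ridge-penalized —
the standard mixed-model-as-penalty representation of a random effect.
The smooth's penalty is chosen by GCV on a log grid; the site penalty by
the variance-component fixed point sigma^2 = ||u||^2 / edf_u.

Uncertainty is propagated by empirical-Bayes posterior simulation:
coefficient draws from N(beta_hat, (X'WX + S_lambda)^-1), pushed through
the inverse link, give the per-cell probability that cover exceeds the
good-condition threshold (default 30%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit

from .grid import Grid

__all__ = [
    "SplineBasis",
    "ConditionModel",
    "ConditionSurface",
    "fit_condition_model",
    "check_overdispersion",
    "residual_semivariogram",
    "posterior_draws",
    "prob_good_condition",
]

logger = logging.getLogger(__name__)


@dataclass
class SplineBasis:
    """Clamped cubic B-spline basis with integrated curvature penalty."""

    knots: np.ndarray  # full knot vector (boundary knots repeated degree+1 times)
    degree: int = 3

    @classmethod
    def from_quantiles(cls, x: np.ndarray, n_basis: int = 10, degree: int = 3) -> "SplineBasis":
        """Place interior knots at covariate quantiles.

        ``n_basis`` functions need ``n_basis - degree - 1`` interior
        knots. Duplicate quantiles (heavily tied data) are nudged apart.
        """
        x = np.asarray(x, dtype=float)
        lo, hi = float(x.min()), float(x.max())
        n_interior = n_basis - degree - 1
        if n_interior < 0:
            raise ValueError("n_basis too small for the degree")
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = np.maximum.accumulate(interior + np.arange(n_interior) * 1e-9 * (hi - lo))
        t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        return cls(knots=t, degree=degree)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def support(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Design matrix; covariate clamped to the knot support, so
        prediction beyond the surveyed range holds the boundary value."""
        lo, hi = self.support
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def curvature_penalty(self) -> np.ndarray:
        """Exact Gram matrix of second derivatives, int f_i'' f_j'' dx.

        Second derivatives of cubic B-splines are piecewise linear, so
        two-point Gauss-Legendre per knot span integrates the products
        exactly.
        """
        p = self.n_basis
        d2 = np.empty(p, dtype=object)
        for i in range(p):
            coef = np.zeros(p)
            coef[i] = 1.0
            d2[i] = BSpline(self.knots, coef, self.degree).derivative(2)
        spans = np.unique(self.knots)
        gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        S = np.zeros((p, p))
        for a, b in zip(spans[:-1], spans[1:]):
            half = 0.5 * (b - a)
            pts = 0.5 * (a + b) + half * gauss
            vals = np.stack([f(pts) for f in d2])  # (p, 2)
            S += half * (vals @ vals.T)
        return S


@dataclass
class ConditionModel:
    """Fitted penalized binomial spline with site random intercepts."""

    basis: SplineBasis
    coefficients: np.ndarray  # smooth coefs followed by site intercepts
    coef_covariance: np.ndarray  # empirical-Bayes posterior covariance
    smoothing_param: float  # lambda for the curvature penalty
    site_lambda: float  # ridge penalty on site intercepts
    site_effect_sd: float
    deviance_explained: float
    edf: float
    site_ids: np.ndarray
    fitted_prob: np.ndarray

    @property
    def n_smooth(self) -> int:
        return self.basis.n_basis

    def smooth_coefs(self, coefficients: np.ndarray | None = None) -> np.ndarray:
        c = self.coefficients if coefficients is None else coefficients
        return np.asarray(c)[..., : self.n_smooth]

    def predict_logit(self, log_tss: np.ndarray, coefficients: np.ndarray | None = None) -> np.ndarray:
        """Population-level linear predictor (site effect at its mean, 0)."""
        B = self.basis.design(np.atleast_1d(log_tss))
        return self.smooth_coefs(coefficients) @ B.T if (
            coefficients is not None and np.asarray(coefficients).ndim == 2
        ) else B @ self.smooth_coefs(coefficients)

    def predict_cover(self, log_tss: np.ndarray) -> np.ndarray:
        return expit(self.predict_logit(log_tss))


@dataclass
class ConditionSurface:
    """P(hard-coral cover > threshold) on the coral-bearing sea cells."""

    prob_good: Grid
    threshold: float
    n_draws: int


def _pirls(
    y: np.ndarray,
    n: np.ndarray,
    B: np.ndarray,
    S: np.ndarray,
    lam_f: float,
    lam_s_init: float,
    update_site_lambda: bool,
    max_iter: int = 100,
    tol: float = 1e-9,
):
    """Penalized IRLS for logit(p) = B beta + u with penalties
    lam_f * beta'S beta + lam_s * ||u||^2; one pooled observation per site.

    When ``update_site_lambda`` the site ridge follows the variance
    fixed point lam_s = 1 / sigma_u^2, sigma_u^2 = ||u||^2 / edf_u.
    """
    n_obs, p = B.shape
    X = np.hstack([B, np.eye(n_obs)])
    q = n_obs
    lam_s = lam_s_init
    beta = np.zeros(p + q)
    prop = (y + 0.5) / (n + 1.0)
    eta = np.log(prop / (1 - prop))
    dev_prev = np.inf
    C = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = n * mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - n * mu) / w
        Lam = np.zeros((p + q, p + q))
        Lam[:p, :p] = lam_f * S
        Lam[p:, p:] = lam_s * np.eye(q)
        XtW = X.T * w
        A = XtW @ X + Lam
        C = np.linalg.solve(A, np.eye(p + q))
        beta = C @ (XtW @ z)
        eta = X @ beta
        mu = expit(eta)
        dev = _binomial_deviance(y, n, mu)
        if update_site_lambda:
            u = beta[p:]
            edf_u = q - lam_s * np.trace(C[p:, p:])
            sig2 = float(u @ u) / max(edf_u, 1e-3)
            lam_s = 1.0 / max(sig2, 1e-4)
        if abs(dev - dev_prev) < tol * (abs(dev) + 0.1):
            break
        dev_prev = dev
    mu = expit(eta)
    w = np.maximum(n * mu * (1 - mu), 1e-10)
    XtW = X.T * w
    Lam = np.zeros((p + q, p + q))
    Lam[:p, :p] = lam_f * S
    Lam[p:, p:] = lam_s * np.eye(q)
    A = XtW @ X + Lam
    C = np.linalg.solve(A, np.eye(p + q))
    edf = float(np.trace(C @ (XtW @ X)))
    dev = _binomial_deviance(y, n, mu)
    return beta, C, eta, mu, dev, edf, lam_s


def _binomial_deviance(y, n, mu) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def fit_condition_model(
    surveys: pd.DataFrame,
    n_basis: int = 10,
    lambda_grid: np.ndarray | None = None,
    criterion: str = "gcv",
) -> ConditionModel:
    """Fit the penalized binomial spline to a survey table.

    ``surveys`` needs columns site_id, x, y, n_points, n_hard_coral,
    log_tss (one pooled row per site). The curvature penalty lambda is
    selected on a log grid by GCV, ``n * deviance / (n - edf)^2``; the
    site ridge co-adapts by the variance fixed point inside each fit.
    """
    required = {"site_id", "n_points", "n_hard_coral", "log_tss"}
    missing = required - set(surveys.columns)
    if missing:
        raise ValueError(f"survey table missing columns {sorted(missing)}")
    if surveys["site_id"].nunique() < 10:
        raise ValueError("need at least 10 survey sites")
    x = surveys["log_tss"].to_numpy(dtype=float)
    if np.ptp(x) < 1e-8:
        raise ValueError("covariate log_tss is constant; smooth not identifiable")
    y = surveys["n_hard_coral"].to_numpy(dtype=float)
    n = surveys["n_points"].to_numpy(dtype=float)
    if ((y < 0) | (y > n)).any():
        raise ValueError("invalid counts: need 0 <= n_hard_coral <= n_points")
    if criterion != "gcv":
        raise ValueError(f"unknown smoothing criterion {criterion!r}")

    basis = SplineBasis.from_quantiles(x, n_basis=n_basis)
    B = basis.design(x)
    S = basis.curvature_penalty()
    # scale-free lambda grid: normalize penalty to the data curvature scale
    s_scale = np.trace(B.T @ B) / max(np.trace(S), 1e-12)
    if lambda_grid is None:
        lambda_grid = s_scale * np.logspace(-5, 3, 9)

    n_obs = len(y)
    best = None
    for lam_f in np.atleast_1d(lambda_grid):
        beta, C, eta, mu, dev, edf, lam_s = _pirls(
            y, n, B, S, float(lam_f), lam_s_init=1.0, update_site_lambda=True
        )
        gcv = n_obs * dev / max(n_obs - edf, 0.5) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, float(lam_f), beta, C, eta, mu, dev, edf, lam_s)
    _, lam_f, beta, C, eta, mu, dev, edf, lam_s = best

    p = basis.n_basis
    u = beta[p:]
    edf_u = n_obs - lam_s * np.trace(C[p:, p:])
    site_sd = float(np.sqrt(max(float(u @ u) / max(edf_u, 1e-3), 0.0)))

    p0 = y.sum() / n.sum()
    dev_null = _binomial_deviance(y, n, np.full(n_obs, p0))
    dev_expl = 1.0 - dev / dev_null if dev_null > 0 else np.nan

    return ConditionModel(
        basis=basis,
        coefficients=beta,
        coef_covariance=C,
        smoothing_param=lam_f,
        site_lambda=float(lam_s),
        site_effect_sd=site_sd,
        deviance_explained=float(dev_expl),
        edf=edf,
        site_ids=surveys["site_id"].to_numpy(),
        fitted_prob=mu,
    )


def check_overdispersion(
    model: ConditionModel, surveys: pd.DataFrame, band: tuple[float, float] = (0.7, 1.4)
) -> tuple[float, str]:
    """Pearson chi-square over residual degrees of freedom.

    A ratio near 1 is consistent with binomial variation; above the band
    signals overdispersion (e.g. unmodelled clustering), below it
    underdispersion.
    """
    y = surveys["n_hard_coral"].to_numpy(dtype=float)
    n = surveys["n_points"].to_numpy(dtype=float)
    mu = model.fitted_prob
    pearson = float((((y - n * mu) ** 2) / np.maximum(n * mu * (1 - mu), 1e-12)).sum())
    df = max(len(y) - model.edf, 1e-6)
    ratio = pearson / df
    if ratio > band[1]:
        verdict = "overdispersed"
    elif ratio < band[0]:
        verdict = "underdispersed"
    else:
        verdict = "ok"
    return ratio, verdict


def deviance_residuals(model: ConditionModel, surveys: pd.DataFrame) -> np.ndarray:
    y = surveys["n_hard_coral"].to_numpy(dtype=float)
    n = surveys["n_points"].to_numpy(dtype=float)
    mu = np.clip(model.fitted_prob, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * mu)), 0.0)
    dev_i = 2.0 * (t1 + t2)
    return np.sign(y / n - mu) * np.sqrt(np.maximum(dev_i, 0.0))


def residual_semivariogram(
    model: ConditionModel, surveys: pd.DataFrame, lag_bins: int | np.ndarray = 10
) -> pd.DataFrame:
    """Empirical semivariogram of deviance residuals.

    gamma(h) = sum over site pairs in the lag bin of (r_i - r_j)^2 /
    (2 * n_pairs). A flat semivariogram indicates no residual spatial
    autocorrelation.
    """
    if surveys["site_id"].nunique() < 2:
        raise ValueError("semivariogram needs at least 2 sites")
    r = deviance_residuals(model, surveys)
    xy = surveys[["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(len(r), k=1)
    dist = d[iu]
    sq = (r[iu[0]] - r[iu[1]]) ** 2
    if np.isscalar(lag_bins):
        edges = np.linspace(0.0, dist.max() * (1 + 1e-9), int(lag_bins) + 1)
    else:
        edges = np.asarray(lag_bins, dtype=float)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (dist >= a) & (dist < b)
        n_pairs = int(sel.sum())
        gamma = float(sq[sel].sum() / (2 * n_pairs)) if n_pairs else np.nan
        rows.append((0.5 * (a + b), gamma, n_pairs))
    return pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])


def posterior_draws(model: ConditionModel, n_draws: int, seed: int = 0) -> np.ndarray:
    """Empirical-Bayes coefficient draws, N(beta_hat, V_beta).

    The covariance is symmetrized and eigenvalue-repaired (negative
    eigenvalues within 1e-10 of zero are clipped); a genuinely indefinite
    matrix raises.
    """
    C = np.asarray(model.coef_covariance, dtype=float)
    C = 0.5 * (C + C.T)
    vals, vecs = np.linalg.eigh(C)
    scale = max(vals.max(), 1.0)
    if vals.min() < -1e-10 * scale:
        raise ValueError("coefficient covariance is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC07A1]))
    z = rng.standard_normal((n_draws, len(vals)))
    return model.coefficients[None, :] + z @ root.T


def prob_good_condition(
    model: ConditionModel,
    draws: np.ndarray,
    log_tss: Grid,
    coral_mask: Grid,
    threshold: float = 0.30,
) -> ConditionSurface:
    """Per-cell probability that hard-coral cover exceeds ``threshold``.

    Each posterior coefficient draw defines a cover curve; the cell's
    probability is the fraction of draws whose predicted cover (site
    effect at its population mean of zero) exceeds the threshold,
    clipped to the coral-bearing cells. Coral cells without a TSS value
    are set to no-data and counted in the log.
    """
    coral = np.asarray(coral_mask.values, dtype=bool) & coral_mask.valid()
    usable = coral & log_tss.valid()
    n_missing = int((coral & ~log_tss.valid()).sum())
    if n_missing:
        logger.warning("%d coral cells lack a TSS value; left as no-data", n_missing)
    cells = np.argwhere(usable)
    out = np.zeros(log_tss.shape)
    if len(cells):
        x = np.asarray(log_tss.values, dtype=float)[cells[:, 0], cells[:, 1]]
        B = model.basis.design(x)  # (n_cells, p)
        eta = model.smooth_coefs(draws) @ B.T  # (n_draws, n_cells)
        exceed = expit(eta) > threshold
        out[cells[:, 0], cells[:, 1]] = exceed.mean(axis=0)
    grid = log_tss.like(out, nodata_mask=~usable)
    return ConditionSurface(prob_good=grid, threshold=threshold, n_draws=len(draws))
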