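"""DBH extraction and height-diameter allometry.

The workflow mirrors the photogrammetric DBH chain: a 1.32-1.42 m slice of
the height-normalized point cloud is compressed to a plane and an ordinary
least-squares circle is fit at each detected stem (DBH = 2 x fitted radius).
Extracted height-DBH pairs are screened against the 90% prediction bounds of
a regional power model DBH = b1 * height^b2; the retained pairs fit a
site-specific power model that imputes DBH for trees whose extraction failed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from uasforest.data import (
    NormalizedPointCloud,
    ParameterError,
    TreePlot,
    ValidationError,
)
from uasforest.detection import DetectedTree

__all__ = [
    "CircleFitResult",
    "PowerModel",
    "SLICE_Z_RANGE_M",
    "fit_circle_ls",
    "extract_dbh",
    "fit_power_model",
    "prediction_interval",
    "filter_pairs_by_bounds",
    "impute_missing_dbh",
    "make_synthetic_regional_model",
]

#: breast-height slice of the normalized cloud used for circle fitting (m)
SLICE_Z_RANGE_M = (1.32, 1.42)


@dataclass(frozen=True)
class CircleFitResult:
    center_x_m: float
    center_y_m: float
    radius_m: float
    rms_m: float
    n_pts: int

    @property
    def dbh_cm(self) -> float:
        return 200.0 * self.radius_m


@dataclass(frozen=True)
class PowerModel:
    """Height-diameter power law DBH_cm = beta1 * height_m ** beta2."""

    beta1: float
    beta2: float
    resid_se_cm: float
    n: int
    param_cov: np.ndarray

    def __post_init__(self) -> None:
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValidationError("power-model coefficients must be positive")
        cov = np.asarray(self.param_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("param_cov must be a symmetric 2x2 matrix")
        object.__setattr__(self, "param_cov", cov)

    def predict(self, height_m):
        return self.beta1 * np.asarray(height_m, dtype=float) ** self.beta2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "beta1": self.beta1,
                    "beta2": self.beta2,
                    "resid_se_cm": self.resid_se_cm,
                    "n": self.n,
                    "param_cov": self.param_cov.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PowerModel":
        d = json.loads(Path(path).read_text())
        return cls(
            beta1=d["beta1"],
            beta2=d["beta2"],
            resid_se_cm=d["resid_se_cm"],
            n=d["n"],
            param_cov=np.asarray(d["param_cov"], dtype=float),
        )


# ---------------------------------------------------------------------------
# Circle fitting


def fit_circle_ls(points: np.ndarray) -> CircleFitResult:
    """Least-squares circle through 2-D points.

    Solves the algebraic (Kasa) linear system for an initial circle and
    refines it by Gauss-Newton on the geometric radial residuals
    ``|p - center| - radius``.  The RMS residual of the refined fit is
    reported.

    Raises ``ValidationError`` for fewer than 3 points or (near-)collinear
    configurations, where the circle is not identifiable.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        raise ValidationError("circle fit needs at least 3 points")
    # center the data for conditioning; Kasa system in shifted coordinates
    mean = pts.mean(axis=0)
    u = pts - mean
    A = np.column_stack([2.0 * u, np.ones(n)])
    b = (u**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-10 * sv[0]:
        raise ValidationError("points are collinear: circle fit is degenerate")
    cx, cy = sol[0], sol[1]
    r0 = float(np.sqrt(sol[2] + cx**2 + cy**2))

    def residuals(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    fit = optimize.least_squares(
        residuals, x0=[mean[0] + cx, mean[1] + cy, r0], method="lm"
    )
    cx, cy, r = fit.x
    if r <= 0:
        raise ValidationError("degenerate circle fit (non-positive radius)")
    rms = float(np.sqrt(np.mean(residuals(fit.x) ** 2)))
    return CircleFitResult(
        center_x_m=float(cx), center_y_m=float(cy), radius_m=float(r), rms_m=rms, n_pts=n
    )


def extract_dbh(
    slice_cloud: NormalizedPointCloud,
    tree: DetectedTree,
    search_radius_m: float = 1.0,
    min_points: int = 10,
    max_rms_ratio: float = 0.25,
    max_radius_fraction: float = 0.5,
) -> CircleFitResult | None:
    """Circle-fit DBH at one detected stem from the breast-height slice.

    Points within ``search_radius_m`` of the stem (x, y) are projected to the
    plane and circle-fit.  Returns ``None`` (absence, not an error) when fewer
    than ``min_points`` are in range, the fit is degenerate, or the fit fails
    a quality gate: ``rms / radius <= max_rms_ratio`` and ``radius <=
    max_radius_fraction * search_radius_m`` (a circle comparable in size to
    the whole search neighborhood is a branch artifact, not a stem).
    """
    pts = slice_cloud.slice_z(*SLICE_Z_RANGE_M).points
    if len(pts) == 0:
        return None
    d = np.hypot(pts[:, 0] - tree.x_m, pts[:, 1] - tree.y_m)
    near = pts[d <= search_radius_m, :2]
    if len(near) < min_points:
        return None
    try:
        fit = fit_circle_ls(near)
    except ValidationError:
        return None
    if fit.rms_m / fit.radius_m > max_rms_ratio:
        return None
    if fit.radius_m > max_radius_fraction * search_radius_m:
        return None
    # reject fits whose center wandered away from the detected stem
    if np.hypot(fit.center_x_m - tree.x_m, fit.center_y_m - tree.y_m) > search_radius_m:
        return None
    return fit


# ---------------------------------------------------------------------------
# Power model


def fit_power_model(heights: np.ndarray, dbhs: np.ndarray) -> PowerModel:
    """Nonlinear least-squares fit of DBH = beta1 * height ** beta2.

    Initialized from the log-log linear regression; Levenberg-Marquardt on the
    original (untransformed) scale, converged at relative parameter change
    < 1e-8.  Residual SE is sqrt(SSE / (n - 2)).
    """
    h = np.asarray(heights, dtype=float)
    d = np.asarray(dbhs, dtype=float)
    if h.shape != d.shape or h.ndim != 1:
        raise ParameterError("heights and dbhs must be 1-D vectors of equal length")
    n = len(h)
    if n < 5:
        raise ParameterError("power-model fit needs at least 5 pairs")
    if (h <= 0).any() or (d <= 0).any():
        raise ParameterError("heights and DBH values must be positive")
    slope, intercept = np.polyfit(np.log(h), np.log(d), 1)
    p0 = [float(np.exp(intercept)), float(slope)]

    def model(x, b1, b2):
        return b1 * x**b2

    popt, pcov = optimize.curve_fit(
        model, h, d, p0=p0, maxfev=200 * (n + 2), xtol=1e-8, ftol=1e-12
    )
    resid = d - model(h, *popt)
    sse = float(resid @ resid)
    resid_se = float(np.sqrt(sse / (n - 2)))
    return PowerModel(
        beta1=float(popt[0]),
        beta2=float(popt[1]),
        resid_se_cm=resid_se,
        n=n,
        param_cov=pcov,
    )


def prediction_interval(
    model: PowerModel,
    height_m: float,
    level: float = 0.90,
    method: str = "delta",
    n_draws: int = 5000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided prediction interval for a new DBH observation at a height.

    ``method="delta"`` (default, deterministic) uses t quantiles with the
    delta-method variance resid_se^2 + g' C g, where g is the gradient of the
    fitted curve in (beta1, beta2) and C the parameter covariance.
    ``method="mc"`` propagates parameter uncertainty by Monte Carlo (normal
    parameter draws plus residual noise) and takes empirical quantiles.
    """
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    if model.n <= 2:
        raise ValidationError("model has too few observations for an interval")
    mu = float(model.predict(height_m))
    if method == "delta":
        g = np.array([mu / model.beta1, mu * np.log(height_m)])
        var = model.resid_se_cm**2 + float(g @ model.param_cov @ g)
        t = stats.t.ppf(0.5 + level / 2.0, df=model.n - 2)
        half = t * np.sqrt(var)
        return mu - half, mu + half
    if method == "mc":
        rng = rng or np.random.default_rng(0)
        draws = rng.multivariate_normal(
            [model.beta1, model.beta2], model.param_cov, size=n_draws
        )
        preds = draws[:, 0] * height_m ** draws[:, 1]
        preds = preds + rng.standard_t(df=model.n - 2, size=n_draws) * model.resid_se_cm
        lo, hi = np.quantile(preds, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return float(lo), float(hi)
    raise ParameterError(f"unknown interval method {method!r}")


def filter_pairs_by_bounds(
    pairs: list[tuple[float, float]], regional: PowerModel, level: float = 0.90
) -> list[tuple[float, float]]:
    """Keep (height, dbh) pairs whose DBH lies inside the regional prediction bound."""
    kept = []
    for h, d in pairs:
        lo, hi = prediction_interval(regional, h, level=level)
        if lo <= d <= hi:
            kept.append((h, d))
    return kept


def impute_missing_dbh(plot: TreePlot, site_model: PowerModel) -> TreePlot:
    """Predict DBH from height for trees without one; extracted values untouched.

    Imputed trees get ``dbh_origin="predicted"``; the operation is idempotent.
    """
    out = []
    for t in plot.trees:
        if t.dbh_cm is None:
            out.append(
                replace(
                    t,
                    dbh_cm=float(site_model.predict(t.height_m)),
                    dbh_origin="predicted",
                )
            )
        else:
            out.append(t)
    return plot.with_trees(out)


def make_synthetic_regional_model(
    seed: int = 0,
    n: int = 2000,
    beta1: float = 4.29,
    beta2: float = 0.68,
    resid_sd_cm: float = 6.2,
    height_range_m: tuple[float, float] = (1.5, 30.0),
) -> PowerModel:
    """Fit a stand-in regional height-DBH model on synthetic inventory pairs.

    Emulates fitting a power model to a large regional forest-inventory
    height-DBH sample; defaults put the residual scatter at 6.2 cm around a
    ponderosa-pine-like power curve.  The returned model is synthetic and
    exists so the prediction-bound filter can run without external data.
    """
    rng = np.random.default_rng(seed)
    h = rng.uniform(*height_range_m, size=n)
    d = beta1 * h**beta2 + rng.normal(0.0, resid_sd_cm, size=n)
    keep = d > 0.1
    return fit_power_model(h[keep], d[keep])
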