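"""Detection-parameter grid search and density regression calibration.

Grid search scores each (band, window size, NDVI threshold) combination by
the Pearson correlation between detected and true per-plot counts, per
stratum, with two-tailed t significance at p < 0.05. Density models regress
NT on N' by ordinary least squares — linear or quadratic ("non-linear") —
and are validated by leave-one-out cross-validation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plot_analysis import PlotObservation
from .synthetic_scene import BROADLEAF, CONIFEROUS, UNCLASSIFIED

DEFAULT_STRATA = (CONIFEROUS, BROADLEAF, UNCLASSIFIED)
SIGNIFICANCE_LEVEL = 0.05

MODEL_FORMS = ("linear", "quadratic")


class UndefinedCorrelationError(ValueError):
    pass


class SingularFitError(ValueError):
    pass


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-tailed t-test p-value on n-2 dof.

    t = r * sqrt((n - 2) / (1 - r^2)); |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0 or syy == 0:
        raise UndefinedCorrelationError("correlation undefined: zero variance input")
    r = float(np.dot(dx, dy) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


@dataclass
class GridSearchCell:
    band: str
    window_size: int
    ndvi_threshold: float
    stratum: str
    n: int
    r: float
    p: float
    significant: bool


def _stratum_obs(obs: list[PlotObservation], stratum: str) -> list[PlotObservation]:
    if stratum == UNCLASSIFIED:
        return list(obs)  # every plot belongs to the unclassified pool
    return [o for o in obs if o.stratum == stratum]


def grid_search(
    tables: dict[tuple[str, int, float], list[PlotObservation]],
    strata: tuple[str, ...] = DEFAULT_STRATA,
) -> tuple[list[GridSearchCell], dict[str, GridSearchCell | None]]:
    """Score every combination per stratum; pick the best cell per stratum.

    Best = maximal r among significant cells; if no cell in a stratum is
    significant, the maximal-r cell is returned flagged non-significant; if
    every cell is undefined (constant counts) the stratum maps to None.
    Strata with fewer than 3 plots are skipped with a warning.
    """
    cells: list[GridSearchCell] = []
    for (band, w, t), obs in sorted(tables.items()):
        for stratum in strata:
            sub = _stratum_obs(obs, stratum)
            if len(sub) < 3:
                warnings.warn(
                    f"stratum {stratum!r} has {len(sub)} plots (<3); skipped",
                    stacklevel=2,
                )
                continue
            n_prime = [o.n_prime for o in sub]
            nt = [o.nt for o in sub]
            try:
                r, p = pearson_r(n_prime, nt)
                significant = p < SIGNIFICANCE_LEVEL
            except UndefinedCorrelationError:
                r, p, significant = float("nan"), float("nan"), False
            cells.append(GridSearchCell(band, w, t, stratum, len(sub), r, p, significant))

    best: dict[str, GridSearchCell | None] = {}
    for stratum in strata:
        stratum_cells = [c for c in cells if c.stratum == stratum and not math.isnan(c.r)]
        if not stratum_cells:
            best[stratum] = None
            continue
        significant_cells = [c for c in stratum_cells if c.significant]
        pool = significant_cells if significant_cells else stratum_cells
        best[stratum] = max(pool, key=lambda c: c.r)
    return cells, best


def grid_to_dataframe(cells: list[GridSearchCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "band": [c.band for c in cells],
            "window": [c.window_size for c in cells],
            "threshold": [c.ndvi_threshold for c in cells],
            "stratum": [c.stratum for c in cells],
            "n": [c.n for c in cells],
            "r": [c.r for c in cells],
            "p": [c.p for c in cells],
            "significant": [c.significant for c in cells],
        }
    )


# ---------------------------------------------------------------------------
# density regression
# ---------------------------------------------------------------------------


@dataclass
class DensityModel:
    """OLS regression of true count on detected count per 400 m^2 plot."""

    stratum: str
    form: str  # "linear" or "quadratic"
    coefficients: tuple[float, ...]
    coef_se: tuple[float, ...]
    r_squared: float
    rmse: float  # trees per plot, sqrt(SSE / n)
    f_stat: float
    p_value: float
    dof: tuple[int, int]  # (model, residual)
    shapiro_p: float
    n: int
    r2_cv: float | None = None
    rmse_cv: float | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.coefficients[0])
        if len(self.coefficients) > 1:
            y = y + self.coefficients[1] * x
        if len(self.coefficients) > 2:
            y = y + self.coefficients[2] * x ** 2
        return y

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "form": self.form,
            "coefficients": list(self.coefficients),
            "coef_se": list(self.coef_se),
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "dof": list(self.dof),
            "shapiro_p": self.shapiro_p,
            "n": self.n,
            "r2_cv": self.r2_cv,
            "rmse_cv": self.rmse_cv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityModel":
        return cls(
            stratum=d["stratum"],
            form=d["form"],
            coefficients=tuple(d["coefficients"]),
            coef_se=tuple(d["coef_se"]),
            r_squared=d["r_squared"],
            rmse=d["rmse"],
            f_stat=d["f_stat"],
            p_value=d["p_value"],
            dof=tuple(d["dof"]),
            shapiro_p=d["shapiro_p"],
            n=d["n"],
            r2_cv=d.get("r2_cv"),
            rmse_cv=d.get("rmse_cv"),
        )


def _design_matrix(x: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return np.column_stack([np.ones_like(x), x])
    if form == "quadratic":
        return np.column_stack([np.ones_like(x), x, x ** 2])
    raise ValueError(f"unknown model form {form!r}")


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError("rank-deficient design matrix")
    return beta


def fit_density_model(obs: list[PlotObservation], form: str = "quadratic",
                      stratum: str = UNCLASSIFIED) -> DensityModel:
    """Fit NT on (1, N') or (1, N', N'^2) by OLS with fit diagnostics.

    RMSE uses the plain sqrt(SSE/n) definition; F and its p-value use
    (k, n - k - 1) degrees of freedom; Shapiro-Wilk on residuals is advisory.
    """
    x = np.array([o.n_prime for o in obs], dtype=float)
    y = np.array([o.nt for o in obs], dtype=float)
    n = x.size
    k = 1 if form == "linear" else 2
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for a {form} fit, got {n}")
    if np.all(x == x[0]):
        raise SingularFitError("detected counts are constant; fit is singular")

    X = _design_matrix(x, form)
    beta = _ols(X, y)
    fitted = X @ beta
    resid = y - fitted
    sse = float(np.dot(resid, resid))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - sse / sst if sst > 0 else 1.0
    rmse = math.sqrt(sse / n)
    dof_resid = n - k - 1
    if sse > 0 and dof_resid > 0:
        f_stat = ((sst - sse) / k) / (sse / dof_resid)
        p_value = float(stats.f.sf(f_stat, k, dof_resid))
        sigma2 = sse / dof_resid
        cov = sigma2 * np.linalg.inv(X.T @ X)
        coef_se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    else:
        f_stat = float("inf")
        p_value = 0.0
        coef_se = tuple(0.0 for _ in beta)
    if n >= 3 and np.ptp(resid) > 0:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    else:
        shapiro_p = float("nan")
    return DensityModel(
        stratum=stratum,
        form=form,
        coefficients=tuple(float(b) for b in beta),
        coef_se=coef_se,
        r_squared=r_squared,
        rmse=rmse,
        f_stat=float(f_stat),
        p_value=p_value,
        dof=(k, dof_resid),
        shapiro_p=shapiro_p,
        n=n,
    )


def loocv_predictions(obs: list[PlotObservation], form: str = "quadratic") -> np.ndarray:
    """Leave-one-out predictions: obs i predicted by a refit without it."""
    x = np.array([o.n_prime for o in obs], dtype=float)
    y = np.array([o.nt for o in obs], dtype=float)
    n = x.size
    if n < 5:
        raise ValueError(f"LOOCV needs at least 5 observations, got {n}")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xi = _design_matrix(x[keep], form)
        try:
            beta = _ols(Xi, y[keep])
        except SingularFitError as exc:
            raise SingularFitError(f"leave-one-out fit singular at index {i}") from exc
        xi = _design_matrix(x[i : i + 1], form)
        preds[i] = float((xi @ beta)[0])
    return preds


def loocv(obs: list[PlotObservation], form: str = "quadratic") -> tuple[float, float]:
    """(r2_cv, rmse_cv): 1 - PRESS/SS_tot and sqrt(PRESS / n)."""
    y = np.array([o.nt for o in obs], dtype=float)
    preds = loocv_predictions(obs, form)
    press = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_cv = 1.0 - press / sst if sst > 0 else 1.0
    rmse_cv = math.sqrt(press / y.size)
    return r2_cv, rmse_cv


def fit_with_loocv(obs: list[PlotObservation], form: str = "quadratic",
                   stratum: str = UNCLASSIFIED) -> DensityModel:
    model = fit_density_model(obs, form, stratum)
    if len(obs) >= 5:
        model.r2_cv, model.rmse_cv = loocv(obs, form)
    return model


def calibrate_models(
    tables: dict[tuple[str, int, float], list[PlotObservation]],
    strata: tuple[str, ...] = DEFAULT_STRATA,
    forms: tuple[str, ...] = MODEL_FORMS,
) -> tuple[list[GridSearchCell], dict[str, GridSearchCell | None], dict[str, dict[str, DensityModel]]]:
    """Full calibration: grid search, then per-stratum models at the best cell."""
    cells, best = grid_search(tables, strata)
    models: dict[str, dict[str, DensityModel]] = {}
    for stratum, cell in best.items():
        if cell is None:
            continue
        obs = _stratum_obs(tables[(cell.band, cell.window_size, cell.ndvi_threshold)], stratum)
        models[stratum] = {
            form: fit_with_loocv(obs, form, stratum) for form in forms
        }
    return cells, best, models


def models_to_json(models: dict[str, dict[str, DensityModel]],
                   best: dict[str, GridSearchCell | None]) -> str:
    payload = {
        "best_combination": {
            stratum: (
                None
                if cell is None
                else {
                    "band": cell.band,
                    "window": cell.window_size,
                    "threshold": cell.ndvi_threshold,
                    "r": cell.r,
                    "p": cell.p,
                    "significant": cell.significant,
                    "n": cell.n,
                }
            )
            for stratum, cell in best.items()
        },
        "models": {
            stratum: {form: m.to_dict() for form, m in by_form.items()}
            for stratum, by_form in models.items()
        },
    }
    return json.dumps(payload, indent=2)
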