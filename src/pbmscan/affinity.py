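"""Regression of PBM-mapping scores against measured binding.

Two models validate the scorer:

* linear — fraction bound F against the score x: F = a·x + b, ordinary least
  squares, with non-binding probes plotted but excluded from the fit;
* nonlinear — dissociation constant against the score via the occupancy
  relation F = a·x + b and Kd = [ligand](1 − F)/F, giving
  Kd = z(1 − (a·x + b))/(a·x + b) with the ligand concentration z free.

Both are exposed as sklearn-style estimators (fit/predict, fitted attributes
with trailing underscores) and as plain functions returning result records.
The window-size sweep and the method comparison harness rank scorers by r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError
from .io import BindingMeasurement, EScoreTable
from .kmers import build_dense_array
from .scanner import ScanConfig, score_probe

__all__ = [
    "LinearFit",
    "KdFit",
    "FractionBoundRegression",
    "KdRegression",
    "fit_score_vs_fraction_bound",
    "fit_kd",
    "window_size_sweep",
    "compare_methods",
    "occupancy_to_kd",
    "kd_to_occupancy",
]


def occupancy_to_kd(fraction_bound, z: float):
    """Kd = [ligand]·(1 − F)/F with [ligand] = z."""
    f = np.asarray(fraction_bound, dtype=np.float64)
    return z * (1.0 - f) / f


def kd_to_occupancy(kd, z: float):
    """Inverse of :func:`occupancy_to_kd`: F = z/(Kd + z)."""
    kd = np.asarray(kd, dtype=np.float64)
    return z / (kd + z)


@dataclass
class LinearFit:
    """OLS result for score vs fraction bound."""

    a: float  # slope
    b: float  # intercept
    r_squared: float
    n: int
    excluded: tuple[str, ...] = ()

    def predict(self, x):
        return self.a * np.asarray(x, dtype=np.float64) + self.b


@dataclass
class KdFit:
    """Nonlinear fit of Kd = z(1 − (a·x + b))/(a·x + b)."""

    a: float
    b: float
    z: float
    r_squared: float
    residuals: np.ndarray
    converged: bool
    boundary: bool  # occupancy a·x+b left (0, 1] over the data range
    r_squared_occupancy: float = float("nan")

    def predict(self, x):
        occ = self.a * np.asarray(x, dtype=np.float64) + self.b
        return self.z * (1.0 - occ) / occ


class FractionBoundRegression(RegressorMixin, BaseEstimator):
    """sklearn-style OLS of fraction bound on a binding-site score.

    Fitted attributes: ``a_`` (slope), ``b_`` (intercept), ``r_squared_``,
    ``n_``, ``excluded_``. Probes named in ``fit(..., exclude=...)`` (e.g.
    probes with no detectable binding) are carried in ``excluded_`` for
    plotting but do not enter the fit.
    """

    def fit(self, X, y, names: Sequence[str] | None = None,
            exclude: Iterable[str] = ()) -> "FractionBoundRegression":
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if x.shape != y.shape:
            raise FitError("score and fraction-bound arrays differ in length")
        if ((y < 0) | (y > 1)).any():
            raise FitError("fraction_bound values must lie in [0, 1]")
        exclude = set(exclude)
        if exclude and names is None:
            raise FitError("exclusions given but no probe names")
        keep = np.ones(len(x), dtype=bool)
        excluded: list[str] = []
        if names is not None:
            for i, nm in enumerate(names):
                if nm in exclude:
                    keep[i] = False
                    excluded.append(nm)
        x_fit, y_fit = x[keep], y[keep]
        if len(x_fit) < 3:
            raise FitError(f"need >= 3 non-excluded points, got {len(x_fit)}")
        if np.ptp(x_fit) == 0:
            raise FitError("degenerate fit: zero variance in scores")
        res = stats.linregress(x_fit, y_fit)
        self.a_ = float(res.slope)
        self.b_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_ = int(len(x_fit))
        self.excluded_ = tuple(excluded)
        return self

    def predict(self, X):
        return self.a_ * np.asarray(X, dtype=np.float64).reshape(-1) + self.b_

    def result_(self) -> LinearFit:
        return LinearFit(self.a_, self.b_, self.r_squared_, self.n_, self.excluded_)


class KdRegression(RegressorMixin, BaseEstimator):
    """sklearn-style nonlinear regression of Kd on a binding-site score.

    Model: Kd = z(1 − (a·x + b))/(a·x + b), least squares on the Kd scale with
    multi-start initialisation over a log-spaced grid of the free ligand scale
    z (``n_starts`` starts). Fitted attributes: ``a_``, ``b_``, ``z_``,
    ``r_squared_`` (Kd scale), ``r_squared_occupancy_``, ``converged_``,
    ``boundary_`` (set when the fitted occupancy leaves (0, 1] over the data).
    """

    def __init__(self, n_starts: int = 16, max_nfev: int = 2000):
        self.n_starts = n_starts
        self.max_nfev = max_nfev

    def fit(self, X, y, init: tuple[float, float, float] | None = None) -> "KdRegression":
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        kd = np.asarray(y, dtype=np.float64).reshape(-1)
        if x.shape != kd.shape:
            raise FitError("score and Kd arrays differ in length")
        if len(x) < 4:
            raise FitError(f"need >= 4 points for the Kd model, got {len(x)}")
        if (kd <= 0).any():
            raise FitError("Kd values must be positive")
        if np.ptp(x) == 0:
            raise FitError("degenerate fit: zero variance in scores")

        def residuals(theta: np.ndarray) -> np.ndarray:
            a, b, z = theta
            occ = a * x + b
            occ = np.clip(occ, 1e-12, None)
            return z * (1.0 - occ) / occ - kd

        starts: list[np.ndarray] = []
        if init is not None:
            starts.append(np.asarray(init, dtype=np.float64))
        z_grid = np.geomspace(max(kd.min(), 1e-12) / 10.0, kd.max() * 10.0,
                              max(self.n_starts, 1))
        for z0 in z_grid:
            # implied occupancy under z0 pins a linear init for (a, b)
            occ0 = z0 / (kd + z0)
            A = np.vstack([x, np.ones_like(x)]).T
            ab, *_ = np.linalg.lstsq(A, occ0, rcond=None)
            starts.append(np.array([ab[0], ab[1], z0]))

        best = None
        for theta0 in starts:
            theta0 = np.array(theta0, dtype=np.float64)
            theta0[2] = max(theta0[2], 1e-9)
            try:
                sol = optimize.least_squares(
                    residuals, theta0,
                    bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                    max_nfev=self.max_nfev,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("Kd regression failed from every start")

        a, b, z = (float(v) for v in best.x)
        occ = a * x + b
        resid = residuals(best.x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((kd - kd.mean()) ** 2))
        self.a_, self.b_, self.z_ = a, b, z
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        occ_obs = kd_to_occupancy(kd, z)
        ss_res_o = float(np.sum((occ - occ_obs) ** 2))
        ss_tot_o = float(np.sum((occ_obs - occ_obs.mean()) ** 2))
        self.r_squared_occupancy_ = 1.0 - ss_res_o / ss_tot_o if ss_tot_o > 0 else float("nan")
        self.residuals_ = resid
        self.converged_ = bool(best.status > 0)
        self.boundary_ = bool((occ <= 0).any() or (occ > 1 + 1e-9).any())
        return self

    def predict(self, X):
        occ = self.a_ * np.asarray(X, dtype=np.float64).reshape(-1) + self.b_
        occ = np.clip(occ, 1e-12, None)
        return self.z_ * (1.0 - occ) / occ

    def result_(self) -> KdFit:
        return KdFit(self.a_, self.b_, self.z_, self.r_squared_, self.residuals_,
                     self.converged_, self.boundary_, self.r_squared_occupancy_)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_score_vs_fraction_bound(scores, fraction_bound, names=None, exclude=()) -> LinearFit:
    """OLS of fraction bound on score; ``exclude`` names non-binders kept out
    of the fit (they remain listed in the result for plotting)."""
    est = FractionBoundRegression().fit(scores, fraction_bound, names=names, exclude=exclude)
    return est.result_()


def fit_kd(scores, kd, init=None, n_starts: int = 16) -> KdFit:
    """Multi-start nonlinear least squares of Kd = z(1−(a·x+b))/(a·x+b)."""
    est = KdRegression(n_starts=n_starts).fit(scores, kd, init=init)
    return est.result_()


def _probe_scores(probes: Sequence[BindingMeasurement], array, window: int) -> np.ndarray:
    cfg = ScanConfig(window_w=window, threshold=0.37)
    out = []
    for p in probes:
        ps = score_probe(p.sequence, array, cfg)
        if window == 1:
            out.append(ps.max_escore)
        else:
            out.append(np.nan if ps.pbm_mapping_score is None else ps.pbm_mapping_score)
    return np.array(out)


def window_size_sweep(
    probes: Sequence[BindingMeasurement],
    table: EScoreTable,
    window_list: Sequence[int] = (1, 3, 5, 6, 7, 8),
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Fit fraction bound against the moving-average score for each window size.

    Window size 1 is the single best-octamer E-score. Returns one row per
    window with the fit (or the error that prevented it); the best row —
    argmax r² — carries ``best == True``. Fit failures do not abort the sweep.
    """
    array = build_dense_array(table)
    names = [p.name for p in probes]
    fb = np.array([p.fraction_bound for p in probes], dtype=np.float64)
    if np.isnan(fb).any():
        raise FitError("window sweep needs fraction_bound for every probe")
    rows = []
    for w in window_list:
        x = _probe_scores(probes, array, int(w))
        try:
            if np.isnan(x).any():
                raise FitError(f"window {w}: some probes too short to score")
            fit = fit_score_vs_fraction_bound(x, fb, names=names, exclude=exclude)
            rows.append({"window": int(w), "a": fit.a, "b": fit.b,
                         "r_squared": fit.r_squared, "n": fit.n, "error": None})
        except FitError as exc:
            rows.append({"window": int(w), "a": np.nan, "b": np.nan,
                         "r_squared": np.nan, "n": 0, "error": str(exc)})
    df = pd.DataFrame(rows)
    df["best"] = False
    if df["r_squared"].notna().any():
        df.loc[df["r_squared"].idxmax(), "best"] = True
    return df


def compare_methods(
    probes: Sequence[BindingMeasurement],
    scorers: dict[str, Callable[[str], float]],
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Rank named scoring functions by r² against fraction bound.

    Each scorer maps a probe sequence to a scalar score. Scorer failures are
    recorded in the ``error`` column, not raised. Rows are sorted by
    descending r² with rank 1 the best; deterministic ties keep dict order.
    """
    if len(scorers) < 2:
        raise FitError("compare_methods needs at least two scorers")
    names = [p.name for p in probes]
    fb = np.array([p.fraction_bound for p in probes], dtype=np.float64)
    rows = []
    for label, fn in scorers.items():
        try:
            x = np.array([float(fn(p.sequence)) for p in probes])
            fit = fit_score_vs_fraction_bound(x, fb, names=names, exclude=exclude)
            rows.append({"method": label, "a": fit.a, "b": fit.b,
                         "r_squared": fit.r_squared, "n": fit.n, "error": None})
        except Exception as exc:  # scorer failure is data, not fatal
            rows.append({"method": label, "a": np.nan, "b": np.nan,
                         "r_squared": np.nan, "n": 0, "error": str(exc)})
    df = pd.DataFrame(rows)
    order = (-df["r_squared"].fillna(-np.inf)).argsort(kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
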