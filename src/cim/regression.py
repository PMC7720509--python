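"""City-level relationship between cycle-network length and cycling mode share.

Fits a local-linear kernel regression (Gaussian kernel, leave-one-out
cross-validated bandwidth) of cycling mode share (%) on network length in
km per 100,000 population, and derives the average marginal effect and
predicted mode-share change for a network-expansion scenario. Built as a
scikit-learn-compatible estimator so it composes with sklearn tooling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CityTableError",
    "ExtrapolationWarning",
    "read_city_table",
    "LocalLinearShareCurve",
    "fit_share_curve",
    "average_marginal_effect",
    "predict_share_change",
]

REQUIRED_COLUMNS = ("city", "country", "population", "network_km",
                    "mode_share_pct")

#: Header aliases accepted when reading external city tables.
DEFAULT_ALIASES = {
    "city": ("city", "City", "city_name"),
    "country": ("country", "Country"),
    "population": ("population", "Population", "pop", "population_size"),
    "network_km": ("network_km", "cycle_network_km", "network_length_km",
                   "length_km", "cycling_network_km"),
    "mode_share_pct": ("mode_share_pct", "mode_share", "cycling_share",
                       "share_pct", "modal_share"),
}


class CityTableError(ValueError):
    """A city table failed validation; message carries per-row diagnostics."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the observed network-length support."""


def read_city_table(path, aliases: dict | None = None) -> pd.DataFrame:
    """Read and validate a city-level CSV of mode share and network length.

    Returns a DataFrame with the canonical columns plus the derived
    predictor ``network_km_per_100k`` = network_km / (population/100,000).
    """
    df = pd.read_csv(path)
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)
    rename = {}
    for canonical, names in alias_map.items():
        for name in names:
            if name in df.columns:
                rename[name] = canonical
                break
    df = df.rename(columns=rename)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise CityTableError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise CityTableError("no records in city table")

    problems = []
    for col in ("population", "network_km", "mode_share_pct"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[numeric.isna()]:
            problems.append(f"row {idx}: non-numeric {col} "
                            f"({df.loc[idx, col]!r})")
        df[col] = numeric
    dupes = df["city"].astype(str)[df["city"].astype(str).duplicated()]
    for idx, name in dupes.items():
        problems.append(f"row {idx}: duplicate city name {name!r}")
    if problems:
        raise CityTableError("; ".join(problems))
    bad_share = df.index[(df.mode_share_pct < 0) | (df.mode_share_pct > 100)]
    if len(bad_share):
        raise CityTableError(
            f"mode share outside [0, 100] in rows {list(bad_share)}")
    if (df.network_km < 0).any():
        raise CityTableError("negative network length")
    small = df.index[df.population < 100_000]
    if len(small):
        warnings.warn(f"{len(small)} cities below 100,000 population",
                      stacklevel=2)
    df["network_km_per_100k"] = df.network_km / (df.population / 100_000.0)
    return df.reset_index(drop=True)


def _local_linear(x_train: np.ndarray, y_train: np.ndarray, x0: np.ndarray,
                  h: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Closed-form local-linear fit at evaluation points x0."""
    d = x_train[None, :] - x0[:, None]
    w = np.exp(-0.5 * (d / h) ** 2)
    if weights is not None:
        w = w * weights
    s0 = w.sum(axis=1)
    s1 = (w * d).sum(axis=1)
    s2 = (w * d * d).sum(axis=1)
    t0 = (w * y_train).sum(axis=1)
    t1 = (w * d * y_train).sum(axis=1)
    denom = s0 * s2 - s1 ** 2
    # fall back to a local constant where the local design is singular
    scale = np.maximum(s0 * s2, 1.0) * 1e-12
    singular = denom <= scale
    out = np.empty(len(x0))
    ok = ~singular
    out[ok] = (s2[ok] * t0[ok] - s1[ok] * t1[ok]) / denom[ok]
    if singular.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            out[singular] = np.where(s0[singular] > 0,
                                     t0[singular] / s0[singular], np.nan)
    return out


def _loo_score(h: float, x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out squared prediction error of the local-linear fit."""
    n = len(x)
    d = x[None, :] - x[:, None]
    w = np.exp(-0.5 * (d / h) ** 2)
    np.fill_diagonal(w, 0.0)
    s0 = w.sum(axis=1)
    s1 = (w * d).sum(axis=1)
    s2 = (w * d * d).sum(axis=1)
    t0 = (w * y).sum(axis=1)
    t1 = (w * d * y).sum(axis=1)
    denom = s0 * s2 - s1 ** 2
    scale = np.maximum(s0 * s2, 1.0) * 1e-12
    bad = (denom <= scale) | (s0 <= 1e-300)
    if bad.all():
        return np.inf
    yhat = np.where(bad, np.where(s0 > 0, t0 / np.maximum(s0, 1e-300), 0.0),
                    (s2 * t0 - s1 * t1) / np.where(denom > 0, denom, 1.0))
    resid = y - yhat
    # penalize bandwidths too narrow to cover every left-out point
    if bad.any():
        return float(np.mean(resid ** 2) + 1e3 * bad.mean() * np.var(y))
    return float(np.mean(resid ** 2))


class LocalLinearShareCurve(RegressorMixin, BaseEstimator):
    """Local-linear kernel regression of mode share on network length.

    Parameters
    ----------
    bandwidth : float, optional
        Gaussian kernel bandwidth in km-per-100k units. When None it is
        chosen by leave-one-out cross-validation on the training data.
    clip : tuple of float
        Range to which predictions are clipped (shares live in [0, 100]).

    Attributes
    ----------
    bandwidth_ : float
        Bandwidth used by the fitted evaluator.
    n_obs_ : int
        Number of training observations.
    residual_sd_ : float
        Standard deviation of in-sample residuals.
    """

    def __init__(self, bandwidth: float | None = None,
                 clip: tuple[float, float] = (0.0, 100.0)):
        self.bandwidth = bandwidth
        self.clip = clip

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("LocalLinearShareCurve expects a single predictor")
        y = np.asarray(y, dtype=float)
        x = X[:, 0]
        if len(x) != len(y) or len(x) < 3:
            raise ValueError("need at least 3 paired observations")
        span = x.max() - x.min()
        if span <= 0:
            raise ValueError("degenerate predictor: all values equal")
        if self.bandwidth is not None:
            if self.bandwidth <= 0:
                raise ValueError("bandwidth must be positive")
            bw = float(self.bandwidth)
        else:
            bw = self._cross_validate_bandwidth(x, y, span)
        self.x_train_ = x
        self.y_train_ = y
        self.bandwidth_ = bw
        self.n_obs_ = len(x)
        resid = y - self._raw_predict(x)
        self.residual_sd_ = float(np.std(resid, ddof=1))
        return self

    @staticmethod
    def _cross_validate_bandwidth(x: np.ndarray, y: np.ndarray,
                                  span: float) -> float:
        lo = np.log10(max(span / 200.0, 1e-6))
        hi = np.log10(span * 3.0)
        grid = np.logspace(lo, hi, 40)
        scores = np.array([_loo_score(h, x, y) for h in grid])
        best = int(np.argmin(scores))
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(lambda lh: _loo_score(10 ** lh, x, y),
                              bounds=(np.log10(a), np.log10(b)),
                              method="bounded",
                              options={"xatol": 1e-3})
        h_ref = 10 ** res.x
        return float(h_ref if _loo_score(h_ref, x, y) <= scores[best]
                     else grid[best])

    def _raw_predict(self, x0: np.ndarray) -> np.ndarray:
        return _local_linear(self.x_train_, self.y_train_,
                             np.asarray(x0, dtype=float), self.bandwidth_)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = self._raw_predict(X[:, 0])
        return np.clip(out, *self.clip)

    @property
    def support_(self) -> tuple[float, float]:
        return float(self.x_train_.min()), float(self.x_train_.max())


def fit_share_curve(cities: pd.DataFrame,
                    bandwidth: float | None = None) -> LocalLinearShareCurve:
    """Fit the share-vs-length curve on a validated city table."""
    if len(cities) < 10:
        raise ValueError("need at least 10 city records")
    est = LocalLinearShareCurve(bandwidth=bandwidth)
    return est.fit(cities[["network_km_per_100k"]].to_numpy(),
                   cities["mode_share_pct"].to_numpy())


def average_marginal_effect(fit: LocalLinearShareCurve,
                            cities: pd.DataFrame | np.ndarray | None = None,
                            step_fraction: float = 0.05) -> float:
    """Mean local derivative of the fitted curve over the observations.

    Units: mode-share percentage points per km of network per 100,000
    population. Central finite difference with step = ``step_fraction`` of
    the bandwidth, evaluated at each training point (or at the supplied
    locations).
    """
    if cities is None:
        x = fit.x_train_
    elif isinstance(cities, pd.DataFrame):
        x = cities["network_km_per_100k"].to_numpy(dtype=float)
    else:
        x = np.asarray(cities, dtype=float).ravel()
    s = step_fraction * fit.bandwidth_
    deriv = (fit._raw_predict(x + s) - fit._raw_predict(x - s)) / (2 * s)
    return float(deriv.mean())


def predict_share_change(fit: LocalLinearShareCurve, population: float,
                         km_from: float, km_to: float) -> float:
    """Predicted change in mode share (percentage points) when the network
    grows from ``km_from`` to ``km_to`` in a city of ``population``.

    Evaluation points outside the observed support trigger an
    :class:`ExtrapolationWarning` and are moved to the nearest boundary.
    """
    per100k = 100_000.0 / population
    x = np.array([km_from * per100k, km_to * per100k])
    lo, hi = fit.support_
    if (x < lo).any() or (x > hi).any():
        warnings.warn(
            "evaluation outside observed network-length support; "
            "using nearest boundary value", ExtrapolationWarning,
            stacklevel=2)
        x = np.clip(x, lo, hi)
    y = fit.predict(x[:, None])
    return float(y[1] - y[0])
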