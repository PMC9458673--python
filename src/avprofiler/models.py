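"""Prediction models for A-V profile coefficients.

Two families:

* ``RidgeAVPredictor`` — penalised linear regression y = x'beta + eps on
  z-scored features with an unpenalised intercept.  The penalty is chosen
  by chronological (expanding-window) cross-validation over a log grid
  when not supplied, because the rows are a time series per player and
  shuffled folds would leak future form into the past.

* Forecasters — uni-modal baselines that see only the ordered coefficient
  series of past games: naive (last value), drift (last value plus mean
  step), the theta family (trend line plus an exponentially smoothed
  theta-scaled residual), an FFT harmonic extrapolator, and an averaged
  ensemble.  All share a minimal fit(series)/predict(horizon) surface so
  other families (Prophet-like, recurrent nets, vector models) can be
  plugged in without touching the evaluation harness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.model_selection import TimeSeriesSplit

__all__ = [
    "RidgeAVPredictor",
    "fit_ridge",
    "predict_ridge",
    "run_control_task",
    "ForecasterBase",
    "NaiveForecaster",
    "DriftForecaster",
    "ThetaForecaster",
    "FourThetaForecaster",
    "FFTForecaster",
    "EnsembleForecaster",
    "make_forecaster",
    "ensemble_average",
]

DEFAULT_ALPHA_GRID = np.logspace(-3, 3, 7)


class RidgeAVPredictor(BaseEstimator, RegressorMixin):
    """Ridge regression on standardised features with chronological CV.

    Features are z-scored with training statistics; the intercept is fit
    on the centred target and left unpenalised, so the coefficients solve
    (Z'Z + alpha I) beta = Z'y in standardised space.  Constant features
    are dropped with a warning.  Rows must be in chronological order when
    ``alpha`` is selected by cross-validation.

    Parameters
    ----------
    alpha : float or None
        Penalty; None selects from ``alpha_grid`` by expanding-window CV
        (``cv`` splits, falling back to fewer splits for short inputs).

    Fitted attributes: ``coef_`` (standardised space), ``intercept_``,
    ``alpha_``, ``feature_means_``, ``feature_stds_``, ``feature_names_in_``.
    """

    def __init__(self, alpha: float | None = None, cv: int = 5, alpha_grid=None):
        self.alpha = alpha
        self.cv = cv
        self.alpha_grid = alpha_grid

    def _check_X(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        return X, [f"x{i}" for i in range(X.shape[1])]

    def fit(self, X, y) -> "RidgeAVPredictor":
        X, names = self._check_X(X)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        if n < 2 or d < 1:
            raise ValueError("need at least 2 rows and 1 feature")
        stds = X.std(axis=0)
        keep = stds > 0
        if not keep.all():
            dropped = [nm for nm, k in zip(names, keep) if not k]
            warnings.warn(f"dropping constant features: {dropped}")
        self.feature_names_in_ = [nm for nm, k in zip(names, keep) if k]
        self._keep = keep
        Xk = X[:, keep]
        self.feature_means_ = Xk.mean(axis=0)
        self.feature_stds_ = Xk.std(axis=0)
        Z = (Xk - self.feature_means_) / self.feature_stds_

        if self.alpha is not None:
            self.alpha_ = float(self.alpha)
        else:
            self.alpha_ = self._select_alpha(Z, y)
        model = Ridge(alpha=self.alpha_, fit_intercept=True)
        model.fit(Z, y)
        self.coef_ = model.coef_
        self.intercept_ = float(model.intercept_)
        return self

    def _select_alpha(self, Z: np.ndarray, y: np.ndarray) -> float:
        grid = DEFAULT_ALPHA_GRID if self.alpha_grid is None else np.asarray(self.alpha_grid)
        n = Z.shape[0]
        n_splits = min(self.cv, n - 1)
        if n_splits < 2:
            return float(grid[len(grid) // 2])
        splitter = TimeSeriesSplit(n_splits=n_splits)
        errs = np.zeros(len(grid))
        for tr, va in splitter.split(Z):
            mu, sd = Z[tr].mean(axis=0), Z[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Ztr, Zva = (Z[tr] - mu) / sd, (Z[va] - mu) / sd
            for i, a in enumerate(grid):
                m = Ridge(alpha=a, fit_intercept=True).fit(Ztr, y[tr])
                errs[i] += np.mean((m.predict(Zva) - y[va]) ** 2)
        return float(grid[int(np.argmin(errs))])

    def predict(self, X) -> np.ndarray:
        X, names = self._check_X(X)
        if isinstance(X, np.ndarray) and X.shape[1] == self._keep.size:
            X = X[:, self._keep]
        elif X.shape[1] != len(self.feature_names_in_):
            raise ValueError("feature set does not match the fitted model")
        Z = (X - self.feature_means_) / self.feature_stds_
        return Z @ self.coef_ + self.intercept_


def fit_ridge(X, y, alpha: float | None = None, cv: int = 5) -> RidgeAVPredictor:
    """Functional wrapper over :class:`RidgeAVPredictor`."""
    return RidgeAVPredictor(alpha=alpha, cv=cv).fit(X, y)


def predict_ridge(fit: RidgeAVPredictor, X_new) -> np.ndarray:
    return fit.predict(X_new)


def _chronological_split(dates: np.ndarray, ratio: float = 0.8) -> np.ndarray:
    """Boolean test mask: the final (1-ratio) fraction of rows by date."""
    order = np.argsort(np.argsort(dates, kind="stable"), kind="stable")
    n = dates.size
    n_train = int(np.floor(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    return order >= n_train


def run_control_task(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    scope: str = "G",
    split_ratio: float = 0.8,
    select_k: int = 10,
    min_games: int = 5,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Predict a game's coefficients from that same game's summary features.

    This is the predictability ceiling: the predictors describe the very
    session whose profile is the target.  Per scope the rows are split
    chronologically (``split_ratio`` train), the top ``select_k`` features
    are chosen by F-test on the training rows, and a ridge model per
    target is scored on the held-out games.  Units (players for scope
    ``I``) with fewer than ``min_games`` games are excluded.

    Returns row-level predictions: player_id, game_id, target, y_true,
    y_pred.
    """
    from .features import FTestSelector  # local to avoid cycle

    merged = summaries.merge(
        profiles.rename(columns={"session_id": "session_id"}),
        on=["player_id", "session_id"],
        suffixes=("", "_prof"),
    )
    merged = merged[merged["valid"]].copy()
    skip = {
        "player_id", "session_id", "date", "kind", "slope", "intercept",
        "r2", "n_bins", "valid", "date_prof",
    }
    feat_cols = [c for c in summaries.columns if c not in skip]
    units = (
        [(pid, g) for pid, g in merged.groupby("player_id", sort=True)]
        if scope == "I"
        else [("G", merged)]
    )
    out = []
    for unit, df in units:
        df = df.sort_values(["date", "player_id", "session_id"], kind="stable")
        if len(df) < max(min_games, 3):
            continue
        test = _chronological_split(df["date"].to_numpy(), split_ratio)
        for target in ("slope", "intercept"):
            y = df[target].to_numpy(dtype=float)
            sel = FTestSelector(k=select_k).fit(df.loc[~test, feat_cols], y[~test])
            Xtr = sel.transform(df.loc[~test, feat_cols])
            Xte = sel.transform(df.loc[test, feat_cols])
            model = RidgeAVPredictor(alpha=alpha).fit(Xtr, y[~test])
            pred = model.predict(Xte)
            sub = df.loc[test]
            out.append(
                pd.DataFrame(
                    {
                        "player_id": sub["player_id"].to_numpy(),
                        "game_id": sub["session_id"].to_numpy(),
                        "target": target,
                        "y_true": y[test],
                        "y_pred": pred,
                    }
                )
            )
    if not out:
        raise ValueError("no unit had enough games for the control task")
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# forecasting family


def _ses_level(x: np.ndarray, alpha: float) -> float:
    """Final level of simple exponential smoothing initialised at x[0]."""
    # L_i = alpha x_i + (1-alpha) L_{i-1} via an IIR filter
    lev = lfilter([alpha], [1.0, -(1.0 - alpha)], x[1:], zi=[(1.0 - alpha) * x[0]])[0]
    return float(lev[-1]) if x.size > 1 else float(x[0])


def _ses_sse(x: np.ndarray, alpha: float) -> float:
    """One-step-ahead SSE of SES with smoothing ``alpha``."""
    if x.size < 2:
        return 0.0
    lev = lfilter([alpha], [1.0, -(1.0 - alpha)], x[1:], zi=[(1.0 - alpha) * x[0]])[0]
    preds = np.concatenate([[x[0]], lev[:-1]])
    return float(np.sum((x[1:] - preds) ** 2))


def _best_ses_alpha(x: np.ndarray, grid=None) -> float:
    grid = np.arange(0.01, 1.0, 0.01) if grid is None else grid
    sses = [_ses_sse(x, a) for a in grid]
    return float(grid[int(np.argmin(sses))])


class ForecasterBase(BaseEstimator):
    """fit(series) / predict(horizon) interface shared by all families."""

    min_length = 3

    def _check(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        if y.size < self.min_length:
            raise ValueError(
                f"{type(self).__name__} needs at least {self.min_length} "
                f"observations, got {y.size}"
            )
        return y

    def fit(self, y) -> "ForecasterBase":
        raise NotImplementedError

    def predict(self, horizon: int) -> np.ndarray:
        raise NotImplementedError


class NaiveForecaster(ForecasterBase):
    """Repeat the last observed value."""

    min_length = 3

    def fit(self, y):
        y = self._check(y)
        self.last_ = float(y[-1])
        return self

    def predict(self, horizon: int) -> np.ndarray:
        return np.full(horizon, self.last_)


class DriftForecaster(ForecasterBase):
    """Last value plus the mean first difference per step."""

    min_length = 3

    def fit(self, y):
        y = self._check(y)
        self.last_ = float(y[-1])
        self.drift_ = float(np.mean(np.diff(y)))
        return self

    def predict(self, horizon: int) -> np.ndarray:
        return self.last_ + self.drift_ * np.arange(1, horizon + 1)


def _ols_trend(y: np.ndarray) -> tuple[float, float]:
    """Intercept and slope of the OLS line through (0..n-1, y)."""
    n = y.size
    t = np.arange(n, dtype=float)
    slope = float(np.polyfit(t, y, 1)[0]) if n > 1 else 0.0
    intercept = float(y.mean() - slope * (n - 1) / 2.0)
    return intercept, slope


def theta_line(y: np.ndarray, theta: float) -> np.ndarray:
    """Theta line Z(theta) = theta * y - (theta - 1) * Z(0).

    Z(0) is the OLS trend line; Z(1) is the series itself and
    (Z(0) + Z(2)) / 2 reconstructs the series exactly.
    """
    y = np.asarray(y, dtype=float)
    intercept, slope = _ols_trend(y)
    trend = intercept + slope * np.arange(y.size)
    return theta * y - (theta - 1.0) * trend


class ThetaForecaster(ForecasterBase):
    """Theta-method forecast (trend-exact variant).

    The series is decomposed into its OLS trend line Z(0) and the
    theta-line Z(theta) = theta * y - (theta - 1) * Z(0), i.e. the trend
    plus a theta-scaled residual — (Z(0) + Z(2)) / 2 reconstructs the
    series exactly.  The forecast averages the two branches: the trend is
    extrapolated exactly and simple exponential smoothing (alpha chosen by
    one-step SSE over a 0.01..0.99 grid) flat-extrapolates the theta-scaled
    residual.  Extrapolating the trend exactly, rather than letting SES
    carry the lagged trend level, makes the forecast continue a perfectly
    linear series without error.
    """

    min_length = 8

    def __init__(self, theta: float = 2.0):
        self.theta = theta

    def fit(self, y):
        y = self._check(y)
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        self.intercept_, self.slope_ = _ols_trend(y)
        resid = y - (self.intercept_ + self.slope_ * np.arange(y.size))
        scaled = self.theta * resid
        if np.allclose(scaled, scaled[0]):
            self.ses_level_ = float(scaled[0])
            self.ses_alpha_ = 0.5
        else:
            self.ses_alpha_ = _best_ses_alpha(scaled)
            self.ses_level_ = _ses_level(scaled, self.ses_alpha_)
        self.n_ = y.size
        return self

    def predict(self, horizon: int) -> np.ndarray:
        t = self.n_ + np.arange(horizon, dtype=float)
        trend = self.intercept_ + self.slope_ * t
        return trend + 0.5 * self.ses_level_


class FourThetaForecaster(ForecasterBase):
    """Theta forecast with the theta coefficient tuned on a validation tail.

    Candidates default to {1, 2, 3, 4}; the last ~20% of the series (at
    least 2 points) serves as the validation tail and the candidate with
    the lowest squared error is refit on the full series.
    """

    min_length = 8

    def __init__(self, candidates: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)):
        self.candidates = candidates

    def fit(self, y):
        y = self._check(y)
        n_val = max(2, int(round(0.2 * y.size)))
        head, tail = y[:-n_val], y[-n_val:]
        best, best_err = self.candidates[0], np.inf
        for th in self.candidates:
            try:
                f = ThetaForecaster(theta=th).fit(head)
            except ValueError:
                continue
            err = float(np.sum((f.predict(n_val) - tail) ** 2))
            if err < best_err:
                best, best_err = th, err
        self.theta_ = best
        self._model = ThetaForecaster(theta=best).fit(y)
        return self

    def predict(self, horizon: int) -> np.ndarray:
        return self._model.predict(horizon)


class FFTForecaster(ForecasterBase):
    """Trend plus top-K Fourier harmonics, extrapolated beyond the sample.

    The K largest-magnitude positive frequencies are picked from the
    spectrum of the OLS-detrended series; trend and retained harmonics are
    then refit *jointly* by least squares before extrapolation.  The joint
    refit matters: on a pure integer-cycle sinusoid a plain OLS detrend
    fits a spurious tilt (slope -6/(pi k n)) whose extrapolation dominates
    the forecast error, while the joint fit recovers a flat trend and the
    exact harmonic, so the continuation is analytic.
    """

    min_length = 8

    def __init__(self, top_k: int = 3):
        self.top_k = top_k

    def _basis(self, t: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(t), t]
        for k in self.keep_:
            w = 2.0 * np.pi * k / self.n_
            cols.append(np.cos(w * t))
            if not (self.n_ % 2 == 0 and k == self.n_ // 2):
                cols.append(np.sin(w * t))
        return np.column_stack(cols)

    def fit(self, y):
        y = self._check(y)
        self.n_ = y.size
        intercept, slope = _ols_trend(y)
        resid = y - (intercept + slope * np.arange(self.n_))
        mags = np.abs(np.fft.rfft(resid))
        mags[0] = 0.0  # residual mean belongs to the trend
        k = min(self.top_k, mags.size - 1)
        self.keep_ = np.sort(np.argsort(mags)[::-1][:k])
        t = np.arange(self.n_, dtype=float)
        self.coef_, *_ = np.linalg.lstsq(self._basis(t), y, rcond=None)
        return self

    def predict(self, horizon: int) -> np.ndarray:
        t = self.n_ + np.arange(horizon, dtype=float)
        return self._basis(t) @ self.coef_


class EnsembleForecaster(ForecasterBase):
    """Average of member forecasts, optionally inverse-validation-MAPE weighted.

    With ``weighting='uniform'`` members are averaged equally; with
    ``'inverse_mape'`` each member is weighted by the inverse of its MAPE
    on a validation tail of the training series (weights normalised to 1).
    """

    min_length = 3

    def __init__(self, members: list | None = None, weighting: str = "uniform"):
        self.members = members
        self.weighting = weighting

    def fit(self, y):
        y = np.asarray(y, dtype=float).ravel()
        members = self.members or [
            ThetaForecaster(),
            FourThetaForecaster(),
            FFTForecaster(),
        ]
        if len(members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        self.fitted_ = [m.fit(y) for m in members]
        if self.weighting == "uniform":
            self.weights_ = np.full(len(members), 1.0 / len(members))
        elif self.weighting == "inverse_mape":
            n_val = max(2, int(round(0.2 * y.size)))
            head, tail = y[:-n_val], y[-n_val:]
            inv = []
            for m in members:
                try:
                    pred = type(m)(**m.get_params()).fit(head).predict(n_val)
                    mape = np.mean(np.abs((tail - pred) / tail))
                    inv.append(1.0 / max(mape, 1e-12))
                except (ValueError, ZeroDivisionError):
                    inv.append(0.0)
            inv = np.asarray(inv)
            self.weights_ = (
                inv / inv.sum() if inv.sum() > 0 else np.full(len(members), 1 / len(members))
            )
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        return self

    def predict(self, horizon: int) -> np.ndarray:
        preds = np.stack([m.predict(horizon) for m in self.fitted_])
        return self.weights_ @ preds


def ensemble_average(
    forecasts: list[np.ndarray], weights: np.ndarray | None = None
) -> np.ndarray:
    """Combine equal-horizon forecasts into one (unweighted mean by default)."""
    if len(forecasts) < 2:
        raise ValueError("need at least 2 forecasts")
    arrs = [np.asarray(f, dtype=float) for f in forecasts]
    h = arrs[0].size
    if any(a.size != h for a in arrs):
        raise ValueError("forecast horizons differ")
    stack = np.stack(arrs)
    if weights is None:
        return stack.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    return (w / w.sum()) @ stack


_FAMILIES = {
    "naive": NaiveForecaster,
    "drift": DriftForecaster,
    "theta": ThetaForecaster,
    "fourtheta": FourThetaForecaster,
    "fft": FFTForecaster,
    "ensemble": EnsembleForecaster,
}


def make_forecaster(family: str, **kwargs) -> ForecasterBase:
    """Forecaster factory; the registry doubles as the plug-in point for
    additional families."""
    try:
        return _FAMILIES[family](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; available: {sorted(_FAMILIES)}"
        ) from None
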