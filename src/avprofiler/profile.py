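"""Acceleration-velocity (A-V) profile extraction from 10 Hz velocity traces.

An athlete's in-situ A-V profile summarises the linear decline of maximal
horizontal acceleration with running velocity.  It is estimated from a raw
GNSS velocity signal in four steps: backward-difference acceleration,
first-order Butterworth low-pass filtering (1 Hz cut-off), retention of the
maximal acceleration per 0.1 m/s velocity bin, and an ordinary least-squares
line fitted to the bin maxima at velocities above 3 m/s.  The fitted
intercept (m/s^2) approximates the theoretical maximal acceleration at rest
and the slope (1/s) its decline per unit velocity; the x-intercept
approximates maximal velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FilterSpec",
    "AVProfile",
    "ProfileParams",
    "compute_acceleration",
    "lowpass_filter",
    "bin_max_acceleration",
    "fit_profile",
    "extract_profile",
    "AVProfileExtractor",
]


@dataclass(frozen=True)
class FilterSpec:
    """First-order Butterworth low-pass filter settings.

    ``zero-phase`` runs the filter forward and backward (squared magnitude
    response, no lag between acceleration and velocity); ``causal`` is a
    single forward pass with the usual first-order -3 dB point at the
    cut-off.
    """

    order: int = 1
    cutoff_hz: float = 1.0
    mode: str = "zero-phase"  # "zero-phase" | "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass
class AVProfile:
    """Fitted A-V profile coefficients with fit diagnostics.

    ``valid`` is False when fewer than ``min_bins`` velocity bins above
    ``v_min_fit`` were populated; coefficient fields are then NaN.  A
    physiologically implausible fit (slope >= 0 or intercept <= 0) keeps
    ``valid`` True but sets ``plausible`` False.
    """

    player_id: str
    session_id: str
    slope: float
    intercept: float
    r_squared: float
    n_bins_used: int
    v_min_fit: float = 3.0
    bin_width: float = 0.1
    valid: bool = True

    @property
    def plausible(self) -> bool:
        return bool(self.valid and self.slope < 0 and self.intercept > 0)

    @property
    def v_max_theoretical(self) -> float:
        """x-intercept of the fitted line, an estimate of maximal velocity."""
        if not self.valid or self.slope == 0:
            return float("nan")
        return -self.intercept / self.slope


@dataclass(frozen=True)
class ProfileParams:
    """End-to-end extraction settings (defaults follow the standard recipe)."""

    sampling_rate: float = 10.0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    bin_width: float = 0.1
    v_min_fit: float = 3.0
    min_bins: int = 10


def compute_acceleration(
    v: np.ndarray, omega: float, t: np.ndarray | None = None
) -> np.ndarray:
    """Backward-difference acceleration in m/s^2.

    a_i = (v_i - v_{i-1}) * omega for i = 1..n-1; output length len(v) - 1.
    The raw velocity difference per sample is scaled by the sampling rate so
    the result carries physical units.  If ``t`` is given, sampling
    uniformity is checked first.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("v must be a 1-d array with at least 2 samples")
    if omega <= 0:
        raise ValueError("sampling rate must be positive")
    if t is not None:
        t = np.asarray(t, dtype=float)
        if t.shape != v.shape:
            raise ValueError("t and v must have equal length")
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - 1.0 / omega) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"non-uniform sampling at index {int(bad[0]) + 1}: "
                f"step {dt[bad[0]]:.6g} s, expected {1.0 / omega:.6g} s"
            )
    return np.diff(v) * omega


def lowpass_filter(
    a: np.ndarray, omega: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Low-pass filter a series with a first-order Butterworth design."""
    spec = spec or FilterSpec()
    a = np.asarray(a, dtype=float)
    nyquist = omega / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist "
            f"frequency {nyquist} Hz"
        )
    b, a_coef = signal.butter(spec.order, spec.cutoff_hz / nyquist)
    if spec.mode == "zero-phase":
        return signal.filtfilt(b, a_coef, a)
    return signal.lfilter(b, a_coef, a)


def bin_max_acceleration(
    v: np.ndarray, a_filtered: np.ndarray, bin_width: float = 0.1
) -> pd.DataFrame:
    """Maximal acceleration per velocity bin.

    Bins are left-closed half-open [k*w, (k+1)*w); empty bins are omitted.
    Returns a frame with ``bin_center``, ``a_max`` and the per-bin sample
    ``count`` for diagnostics, sorted by bin center.
    """
    v = np.asarray(v, dtype=float)
    a_filtered = np.asarray(a_filtered, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != a_filtered.shape:
        raise ValueError("v and a_filtered must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor(v / bin_width).astype(np.int64)
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    uniq, starts, counts = np.unique(
        idx_sorted, return_index=True, return_counts=True
    )
    a_max = np.maximum.reduceat(a_filtered[order], starts)
    return pd.DataFrame(
        {
            "bin_center": (uniq + 0.5) * bin_width,
            "a_max": a_max,
            "count": counts,
        }
    )


def fit_profile(
    binned: pd.DataFrame,
    v_min: float = 3.0,
    min_bins: int = 10,
    player_id: str = "",
    session_id: str = "",
    bin_width: float = 0.1,
) -> AVProfile:
    """OLS line a = intercept + slope * v through bin maxima above ``v_min``.

    "Above" is strict: only bins whose center exceeds ``v_min`` enter the
    fit.  With fewer than ``min_bins`` such bins the profile is returned
    flagged invalid with NaN coefficients.
    """
    keep = binned["bin_center"].to_numpy() > v_min
    n_used = int(keep.sum())
    if n_used < min_bins:
        return AVProfile(
            player_id=player_id,
            session_id=session_id,
            slope=float("nan"),
            intercept=float("nan"),
            r_squared=float("nan"),
            n_bins_used=n_used,
            v_min_fit=v_min,
            bin_width=bin_width,
            valid=False,
        )
    x = binned.loc[keep, "bin_center"].to_numpy()
    y = binned.loc[keep, "a_max"].to_numpy()
    if np.allclose(y, y[0]):
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return AVProfile(
        player_id=player_id,
        session_id=session_id,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_bins_used=n_used,
        v_min_fit=v_min,
        bin_width=bin_width,
        valid=True,
    )


def extract_profile(trace, params: ProfileParams | None = None) -> AVProfile:
    """Full extraction pipeline on one session trace.

    The acceleration sample a_i (difference v_{i-1} -> v_i) is paired with
    the endpoint velocity v_i; at 10 Hz and 0.1 m/s bins the midpoint vs
    endpoint distinction is negligible.
    """
    params = params or ProfileParams()
    omega = getattr(trace, "sampling_rate", params.sampling_rate)
    v = np.asarray(trace.v, dtype=float)
    t = getattr(trace, "t", None)
    a = compute_acceleration(v, omega, t=t)
    a_f = lowpass_filter(a, omega, params.filter_spec)
    binned = bin_max_acceleration(v[1:], a_f, params.bin_width)
    return fit_profile(
        binned,
        v_min=params.v_min_fit,
        min_bins=params.min_bins,
        player_id=getattr(trace, "player_id", ""),
        session_id=getattr(trace, "session_id", ""),
        bin_width=params.bin_width,
    )


class AVProfileExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping session traces to a table of A-V coefficients.

    Stateless (``fit`` only validates parameters); ``transform`` accepts an
    iterable of traces and returns one row per trace with the fitted slope,
    intercept and diagnostics.  Invalid profiles (too few populated bins)
    are kept as rows with NaN coefficients and ``valid`` False so callers
    can filter explicitly.
    """

    def __init__(
        self,
        sampling_rate: float = 10.0,
        cutoff_hz: float = 1.0,
        filter_mode: str = "zero-phase",
        bin_width: float = 0.1,
        v_min_fit: float = 3.0,
        min_bins: int = 10,
    ):
        self.sampling_rate = sampling_rate
        self.cutoff_hz = cutoff_hz
        self.filter_mode = filter_mode
        self.bin_width = bin_width
        self.v_min_fit = v_min_fit
        self.min_bins = min_bins

    def _params(self) -> ProfileParams:
        return ProfileParams(
            sampling_rate=self.sampling_rate,
            filter_spec=FilterSpec(cutoff_hz=self.cutoff_hz, mode=self.filter_mode),
            bin_width=self.bin_width,
            v_min_fit=self.v_min_fit,
            min_bins=self.min_bins,
        )

    def fit(self, X: Iterable | None = None, y=None) -> "AVProfileExtractor":
        self._params()  # validates
        self.n_features_in_ = 0
        return self

    def transform(self, X: Iterable) -> pd.DataFrame:
        params = self._params()
        rows = []
        for trace in X:
            p = extract_profile(trace, params)
            rows.append(
                {
                    "player_id": p.player_id,
                    "session_id": p.session_id,
                    "date": getattr(trace, "date", None),
                    "slope": p.slope,
                    "intercept": p.intercept,
                    "r2": p.r_squared,
                    "n_bins": p.n_bins_used,
                    "valid": p.valid,
                }
            )
        return pd.DataFrame(rows)
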