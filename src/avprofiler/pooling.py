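"""Window pooling of session features into per-game predictor vectors.

Each target game is predicted from the last L sessions (games or
trainings) preceding it.  The window's feature rows are pooled either by
the arithmetic mean or by softmax exponential-decay weights

    w_j = exp(-beta * t_j) / sum_k exp(-beta * t_k),

where t_j is the number of calendar days between session j and the target
game and beta sets the decay rate — beta = 0 recovers the mean, large beta
concentrates all weight on the most recent session.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "mean_pool",
    "softmax_weights",
    "exponential_pool",
    "build_design_matrix",
]

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("player_id", "game_id", "date")


def mean_pool(window_features: np.ndarray) -> np.ndarray:
    """Column-wise arithmetic mean of an L x d feature window."""
    X = np.asarray(window_features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.size == 0:
        raise ValueError("empty window")
    return X.mean(axis=0)


def softmax_weights(t: np.ndarray, beta: float) -> np.ndarray:
    """Softmax exponential-decay weights over days-before-game ``t``.

    Non-negative, sum to one, and non-increasing in t for beta > 0.  The
    minimum of beta*t is subtracted before exponentiation for numerical
    stability.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty time vector")
    if np.any(t < 0):
        raise ValueError("days-before-game must be non-negative")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = -beta * t
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def exponential_pool(
    window_features: np.ndarray, t: np.ndarray, beta: float
) -> np.ndarray:
    """Softmax-weighted column sums; beta = 0 reproduces ``mean_pool`` exactly."""
    X = np.asarray(window_features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    t = np.asarray(t, dtype=float)
    if X.shape[0] != t.size:
        raise ValueError(
            f"window has {X.shape[0]} rows but t has {t.size} entries"
        )
    if beta == 0:
        # identical summation order as mean_pool: sum then scale
        return X.sum(axis=0) / X.shape[0]
    w = softmax_weights(t, beta)
    return w @ X


def build_design_matrix(
    schedule: pd.DataFrame | None,
    features: pd.DataFrame,
    profiles: pd.DataFrame,
    L: int = 5,
    method: str = "mean",
    beta: float = 0.3,
    feature_columns: list[str] | None = None,
    strict_window: bool = False,
) -> pd.DataFrame:
    """One pooled predictor row per (player, game), aligned to its targets.

    ``features`` holds one row per (player, session) with feature columns;
    ``profiles`` one row per (player, game) with ``slope``/``intercept``
    targets.  For each game the last ``L`` sessions strictly preceding it
    (by date, within player) are pooled; ``t`` is the vector of calendar-day
    gaps.  Games with no preceding session are excluded and logged; with
    ``strict_window`` games with fewer than L predecessors are dropped too.

    Returns a frame with index columns ``player_id, game_id, date``, the
    pooled feature columns, targets ``y_slope``/``y_intercept`` and the
    realised ``window_len``.
    """
    if method not in ("mean", "exponential"):
        raise ValueError(f"unknown pooling method {method!r}")
    if schedule is not None and not {"date", "kind"}.issubset(features.columns):
        features = features.merge(
            schedule[["session_id", "date", "kind"]], on="session_id", how="left"
        )
    if feature_columns is None:
        skip = {"player_id", "session_id", "date", "kind"}
        feature_columns = [c for c in features.columns if c not in skip]

    prof = profiles.set_index(["player_id", "session_id"])
    rows = []
    n_dropped = 0
    for player_id, feats in features.groupby("player_id", sort=True):
        feats = feats.sort_values("date", kind="stable")
        dates = pd.to_datetime(feats["date"]).to_numpy()
        F = feats[feature_columns].to_numpy(dtype=float)
        sess_ids = feats["session_id"].to_numpy()
        is_game = (feats["kind"] == "game").to_numpy()
        for i in np.nonzero(is_game)[0]:
            gid = sess_ids[i]
            if (player_id, gid) not in prof.index:
                continue
            lo = max(0, i - L)
            if i == 0 or (strict_window and i - lo < L):
                n_dropped += 1
                logger.info("game %s/%s excluded: no usable window", player_id, gid)
                continue
            t_days = (dates[i] - dates[lo:i]) / np.timedelta64(1, "D")
            if method == "mean":
                x = mean_pool(F[lo:i])
            else:
                x = exponential_pool(F[lo:i], t_days, beta)
            target = prof.loc[(player_id, gid)]
            rows.append(
                {
                    "player_id": player_id,
                    "game_id": gid,
                    "date": feats["date"].iloc[i],
                    **dict(zip(feature_columns, x)),
                    "window_len": i - lo,
                    "y_slope": target["slope"],
                    "y_intercept": target["intercept"],
                }
            )
    if n_dropped:
        logger.info("%d games excluded for lack of preceding sessions", n_dropped)
    return pd.DataFrame(rows)
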