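"""Experiment harness: run every prediction task on one chronological
split, score with MAPE and compare tasks with paired bootstrap contrasts.

The design mirrors a model-comparison study: a *control* task (predicting
a game's A-V coefficients from that same game's summary features — the
predictability ceiling), a games-only forecasting ensemble, and ridge
regressions on windows of past sessions (commercial summaries or
signal-derived features, mean or exponential pooling, fitted per player or
over the group).  Every task scores the identical set of (player, game)
test keys — the final 20% of each player's games by date, never shuffled —
so mean errors are directly comparable.  Classical repeated-measures
ANOVA machinery is replaced by a seeded paired bootstrap over players,
which plays the same decision role with fewer assumptions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FTestSelector, extract_features
from .models import EnsembleForecaster, RidgeAVPredictor
from .pooling import build_design_matrix
from .profile import (
    ProfileParams,
    bin_max_acceleration,
    compute_acceleration,
    fit_profile,
    lowpass_filter,
)
from .synthetic import summarise_session

__all__ = [
    "mape",
    "rescale_targets",
    "RescaleMap",
    "paired_bootstrap_compare",
    "run_experiment",
    "ExperimentResult",
    "DEFAULT_TASKS",
]

logger = logging.getLogger(__name__)

TARGETS = ("slope", "intercept")


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error as a fraction: mean(|t - p| / |t|)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    zeros = np.nonzero(y_true == 0)[0]
    if zeros.size:
        raise ValueError(f"zero ground truth at rows {zeros[:5].tolist()}: MAPE undefined")
    return float(np.mean(np.abs((y_true - y_pred) / y_true)))


@dataclass(frozen=True)
class RescaleMap:
    """Affine map fitted on training rows, reapplied to test rows."""

    scale: float
    offset: float

    def apply(self, x) -> np.ndarray:
        return self.scale * np.asarray(x, dtype=float) + self.offset


def rescale_targets(
    slope_series, intercept_series, train_mask=None
) -> tuple[np.ndarray, RescaleMap]:
    """Map the slope series affinely onto the intercept series' range.

    Slope and intercept live on very different scales, so cross-target
    error comparisons use the slope linearly re-scaled to the intercept's
    range (train min -> min, train max -> max).  Returns the mapped series
    and the fitted map.
    """
    s = np.asarray(slope_series, dtype=float)
    b = np.asarray(intercept_series, dtype=float)
    tr = np.ones(s.size, dtype=bool) if train_mask is None else np.asarray(train_mask)
    s_tr, b_tr = s[tr], b[tr]
    if np.unique(s_tr).size < 2 or np.unique(b_tr).size < 2:
        raise ValueError("degenerate range: need >= 2 distinct training values")
    scale = (b_tr.max() - b_tr.min()) / (s_tr.max() - s_tr.min())
    offset = b_tr.min() - scale * s_tr.min()
    m = RescaleMap(scale=scale, offset=offset)
    return m.apply(s), m


def _per_player_mape(rows: pd.DataFrame) -> pd.Series:
    return rows.groupby("player_id", sort=True).apply(
        lambda g: mape(g["y_true"], g["y_pred"]), include_groups=False
    )


def summarise_mape(rows: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Mean MAPE per (task, target): per-player means averaged (default)
    or pooled over all rows."""
    recs = []
    for (task, target), g in rows.groupby(["task", "target"], sort=True):
        value = (
            mape(g["y_true"], g["y_pred"]) if pooled else float(_per_player_mape(g).mean())
        )
        recs.append({"task": task, "target": target, "mape": value, "n_rows": len(g)})
    return pd.DataFrame(recs)


def paired_bootstrap_compare(
    result_a: pd.DataFrame,
    result_b: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    label_a: str = "a",
    label_b: str = "b",
) -> dict:
    """Paired bootstrap contrast of two tasks' per-player MAPEs.

    Players are resampled with replacement; each replicate records the
    difference of mean per-player MAPE (a minus b).  Reports the point
    estimate, percentile 95% CI and a two-sided bootstrap p-value.
    """
    pa = _per_player_mape(result_a)
    pb = _per_player_mape(result_b)
    players = pa.index.intersection(pb.index)
    if len(players) < 5:
        raise ValueError(
            f"need >= 5 shared players for a paired bootstrap, got {len(players)}"
        )
    da = pa.loc[players].to_numpy()
    db = pb.loc[players].to_numpy()
    diff = da - db
    point = float(diff.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(players), size=(B, len(players)))
    reps = diff[idx].mean(axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    # two-sided p: how often the resampled difference crosses zero
    frac = float(np.mean(reps <= 0) if point > 0 else np.mean(reps >= 0))
    p = min(1.0, 2.0 * max(frac, 1.0 / B))
    return {
        "task_a": label_a,
        "task_b": label_b,
        "mean_diff": point,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_boot": p,
        "n_players": int(len(players)),
    }


# ---------------------------------------------------------------------------
# full experiment


def process_season(
    dataset,
    with_summaries: bool = True,
    with_raw_features: bool = True,
    with_profiles: bool = True,
    profile_params: ProfileParams | None = None,
) -> dict[str, pd.DataFrame | None]:
    """Stream every trace once, computing all requested per-session tables.

    Regenerating a 90-minute trace costs as much as summarising it, so the
    summary, the signal-feature vector and (for games) the A-V profile are
    all computed in a single pass over the season; the filtered
    acceleration is shared between the summary and the profile fit.  Fills
    ``dataset.summaries`` as a side effect when summaries are requested
    and missing.
    """
    params = profile_params or ProfileParams()
    need_summaries = with_summaries and dataset.summaries is None
    summary_rows, feature_rows, profile_rows = [], [], []
    games_only = not (need_summaries or with_raw_features)
    for tr in dataset.iter_traces(kind="game" if games_only else None):
        meta = {
            "player_id": tr.player_id,
            "session_id": tr.session_id,
            "date": tr.date,
            "kind": tr.kind,
        }
        a_f = None
        if need_summaries or (with_profiles and tr.kind == "game"):
            a_f = lowpass_filter(
                compute_acceleration(tr.v, tr.sampling_rate),
                tr.sampling_rate,
                params.filter_spec,
            )
        if need_summaries:
            summary_rows.append({**meta, **summarise_session(tr, a_filtered=a_f)})
        if with_raw_features:
            feature_rows.append({**meta, **extract_features(tr)})
        if with_profiles and tr.kind == "game":
            binned = bin_max_acceleration(tr.v[1:], a_f, params.bin_width)
            p = fit_profile(
                binned,
                v_min=params.v_min_fit,
                min_bins=params.min_bins,
                player_id=tr.player_id,
                session_id=tr.session_id,
                bin_width=params.bin_width,
            )
            profile_rows.append(
                {
                    **meta,
                    "slope": p.slope,
                    "intercept": p.intercept,
                    "r2": p.r_squared,
                    "n_bins": p.n_bins_used,
                    "valid": p.valid,
                }
            )
    if need_summaries:
        dataset.summaries = pd.DataFrame(summary_rows)
    return {
        "summaries": dataset.summaries if with_summaries else None,
        "raw_features": pd.DataFrame(feature_rows) if with_raw_features else None,
        "profiles": pd.DataFrame(profile_rows) if with_profiles else None,
    }


DEFAULT_TASKS = (
    "control",
    "forecast",
    "ridge-mean-commercial-I",
    "ridge-exp-commercial-I",
    "ridge-mean-commercial-G",
    "ridge-exp-commercial-G",
    "ridge-mean-raw-G",
    "ridge-exp-raw-G",
)


@dataclass
class ExperimentResult:
    rows: pd.DataFrame  # player_id, game_id, task, target, y_true, y_pred
    ranking: pd.DataFrame  # task, target, mape (sorted ascending)
    contrasts: pd.DataFrame  # bootstrap contrasts vs the forecast reference
    config: dict = field(default_factory=dict)
    profiles: pd.DataFrame | None = None  # extracted per-game A-V profiles

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "mape_rows.csv", index=False)
        self.ranking.to_csv(out / "ranking.csv", index=False)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        (out / "run_config.json").write_text(json.dumps(self.config, indent=1))
        self._plot(out)

    def _plot(self, out: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for target in self.rows["target"].unique():
            sub = self.rows[self.rows["target"] == target]
            tasks = sorted(sub["task"].unique())
            data = [
                np.abs(
                    (g["y_true"] - g["y_pred"]) / g["y_true"]
                ).to_numpy()
                for t in tasks
                for g in [sub[sub["task"] == t]]
            ]
            fig, ax = plt.subplots(figsize=(1.2 * len(tasks) + 2, 4))
            ax.boxplot(data, tick_labels=tasks, showfliers=False)
            ax.set_ylabel("absolute percentage error")
            ax.set_title(f"per-game APE by task — {target}")
            ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            fig.savefig(out / f"mape_distribution_{target}.png", dpi=120)
            plt.close(fig)


def _eligible_players(profiles: pd.DataFrame, min_games: int) -> list[str]:
    counts = profiles[profiles["valid"]].groupby("player_id").size()
    return sorted(counts[counts >= min_games].index)


def _test_keys(profiles: pd.DataFrame, players: list[str], ratio: float) -> pd.DataFrame:
    """Final (1-ratio) of each player's valid games by date."""
    keys = []
    for pid in players:
        sub = profiles[(profiles["player_id"] == pid) & profiles["valid"]].sort_values(
            "date", kind="stable"
        )
        n_train = min(max(int(np.floor(ratio * len(sub))), 1), len(sub) - 1)
        keys.append(sub.iloc[n_train:][["player_id", "session_id"]])
    out = pd.concat(keys, ignore_index=True)
    return out.rename(columns={"session_id": "game_id"})


def _ridge_task_rows(
    design: pd.DataFrame,
    test_keys: pd.DataFrame,
    scope: str,
    select_k: int,
    task: str,
) -> pd.DataFrame:
    """Fit/score one pooled-window ridge task on the common split."""
    test_set = set(map(tuple, test_keys[["player_id", "game_id"]].to_numpy()))
    design = design.copy()
    design["is_test"] = [
        (p, g) in test_set for p, g in zip(design["player_id"], design["game_id"])
    ]
    feat_cols = [
        c
        for c in design.columns
        if c
        not in {
            "player_id", "game_id", "date", "window_len", "y_slope",
            "y_intercept", "is_test",
        }
    ]
    units = (
        design.groupby("player_id", sort=True)
        if scope == "I"
        else [("G", design)]
    )
    out = []
    for _, df in units:
        df = df.sort_values(["date", "player_id", "game_id"], kind="stable")
        tr, te = df[~df["is_test"]], df[df["is_test"]]
        if len(tr) < 3 or len(te) == 0:
            continue
        for target in TARGETS:
            y_tr = tr[f"y_{target}"].to_numpy(dtype=float)
            sel = FTestSelector(k=select_k).fit(tr[feat_cols], y_tr)
            model = RidgeAVPredictor().fit(sel.transform(tr[feat_cols]), y_tr)
            pred = model.predict(sel.transform(te[feat_cols]))
            out.append(
                pd.DataFrame(
                    {
                        "player_id": te["player_id"].to_numpy(),
                        "game_id": te["game_id"].to_numpy(),
                        "task": task,
                        "target": target,
                        "y_true": te[f"y_{target}"].to_numpy(dtype=float),
                        "y_pred": pred,
                    }
                )
            )
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def _forecast_rows(
    profiles: pd.DataFrame, test_keys: pd.DataFrame, min_train: int = 8
) -> pd.DataFrame:
    """Games-only uni-modal ensemble forecast of each player's test games.

    ``min_train`` is the eligibility threshold on the training-series
    length; raise it to 40 to mirror the stricter filter used for
    data-hungry multivariate forecasters.
    """
    out = []
    for pid, keys in test_keys.groupby("player_id", sort=True):
        sub = profiles[(profiles["player_id"] == pid) & profiles["valid"]].sort_values(
            "date", kind="stable"
        )
        test_ids = set(keys["game_id"])
        is_test = sub["session_id"].isin(test_ids).to_numpy()
        if is_test.sum() == 0 or (~is_test).sum() < min_train:
            continue
        h = int(is_test.sum())
        for target in TARGETS:
            series = sub.loc[~is_test, target].to_numpy(dtype=float)
            pred = EnsembleForecaster().fit(series).predict(h)
            te = sub[is_test]
            out.append(
                pd.DataFrame(
                    {
                        "player_id": pid,
                        "game_id": te["session_id"].to_numpy(),
                        "task": "forecast",
                        "target": target,
                        "y_true": te[target].to_numpy(dtype=float),
                        "y_pred": pred,
                    }
                )
            )
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def _control_rows(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    test_keys: pd.DataFrame,
    select_k: int,
) -> pd.DataFrame:
    """Control task on the common split: same-game features -> coefficients."""
    merged = summaries.merge(
        profiles[["player_id", "session_id", "slope", "intercept", "valid"]],
        on=["player_id", "session_id"],
    )
    merged = merged[merged["valid"]].copy()
    test_set = set(map(tuple, test_keys[["player_id", "game_id"]].to_numpy()))
    merged["is_test"] = [
        (p, s) in test_set
        for p, s in zip(merged["player_id"], merged["session_id"])
    ]
    feat_cols = [
        c
        for c in summaries.columns
        if c not in {"player_id", "session_id", "date", "kind"}
    ]
    merged = merged.sort_values(["date", "player_id", "session_id"], kind="stable")
    tr, te = merged[~merged["is_test"]], merged[merged["is_test"]]
    out = []
    for target in TARGETS:
        y_tr = tr[target].to_numpy(dtype=float)
        sel = FTestSelector(k=select_k).fit(tr[feat_cols], y_tr)
        model = RidgeAVPredictor().fit(sel.transform(tr[feat_cols]), y_tr)
        pred = model.predict(sel.transform(te[feat_cols]))
        out.append(
            pd.DataFrame(
                {
                    "player_id": te["player_id"].to_numpy(),
                    "game_id": te["session_id"].to_numpy(),
                    "task": "control",
                    "target": target,
                    "y_true": te[target].to_numpy(dtype=float),
                    "y_pred": pred,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def run_experiment(
    dataset,
    tasks: tuple[str, ...] = DEFAULT_TASKS,
    split_ratio: float = 0.8,
    L: int = 5,
    beta: float = 0.3,
    select_k: int = 10,
    min_games: int = 10,
    forecast_min_train: int = 8,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run every task on the same chronological split of a season dataset.

    ``dataset`` is a :class:`~avprofiler.synthetic.SeasonDataset` (or any
    object with the same ``summaries`` / ``iter_traces`` surface).  Game
    profiles are extracted once; players with at least ``min_games`` valid
    game profiles define the common test keys (final 20% of their games).
    Task failures are recorded and the run continues.
    """
    need_raw = any(t.startswith("ridge-") and "-raw-" in t for t in tasks)
    tables = process_season(
        dataset, with_summaries=True, with_raw_features=need_raw, with_profiles=True
    )
    summaries = tables["summaries"]
    profiles = tables["profiles"]
    raw_features = tables["raw_features"]

    players = _eligible_players(profiles, min_games)
    if not players:
        raise ValueError(f"no player has >= {min_games} valid game profiles")
    test_keys = _test_keys(profiles, players, split_ratio)
    profiles_elig = profiles[profiles["player_id"].isin(players)]
    summaries_elig = summaries[summaries["player_id"].isin(players)]

    all_rows: list[pd.DataFrame] = []
    failures: dict[str, str] = {}
    designs: dict[tuple[str, str, float], pd.DataFrame] = {}

    def design_for(source: str, method: str) -> pd.DataFrame:
        feats = summaries_elig if source == "commercial" else raw_features[
            raw_features["player_id"].isin(players)
        ]
        key = (source, method, beta)
        if key not in designs:
            designs[key] = build_design_matrix(
                dataset.schedule,
                feats,
                profiles_elig,
                L=L,
                method=method,
                beta=beta,
            )
        return designs[key]

    for task in tasks:
        try:
            if task == "control":
                rows = _control_rows(summaries_elig, profiles_elig, test_keys, select_k)
            elif task == "forecast":
                rows = _forecast_rows(profiles_elig, test_keys, forecast_min_train)
            elif task.startswith("ridge-"):
                _, method, source, scope = task.split("-")
                method = {"mean": "mean", "exp": "exponential"}[method]
                source = {"commercial": "commercial", "raw": "raw"}[source]
                rows = _ridge_task_rows(
                    design_for(source, method), test_keys, scope, select_k, task
                )
            else:
                raise ValueError(f"unknown task {task!r}")
            if rows.empty:
                raise ValueError("task produced no scored rows")
            all_rows.append(rows)
        except Exception as exc:  # record and continue
            logger.warning("task %s failed: %s", task, exc)
            failures[task] = str(exc)

    rows = pd.concat(all_rows, ignore_index=True)
    ranking = summarise_mape(rows).sort_values(
        ["target", "mape"], kind="stable"
    ).reset_index(drop=True)

    contrasts = []
    ref = rows[rows["task"] == "forecast"]
    for target in TARGETS:
        ref_t = ref[ref["target"] == target]
        if ref_t.empty:
            continue
        for task in sorted(rows["task"].unique()):
            if task == "forecast":
                continue
            sub = rows[(rows["task"] == task) & (rows["target"] == target)]
            if sub.empty:
                continue
            try:
                c = paired_bootstrap_compare(
                    sub, ref_t, seed=seed, label_a=task, label_b="forecast"
                )
                c["target"] = target
                contrasts.append(c)
            except ValueError as exc:
                failures[f"contrast:{task}:{target}"] = str(exc)
    contrasts = pd.DataFrame(contrasts)

    result = ExperimentResult(
        rows=rows,
        ranking=ranking,
        contrasts=contrasts,
        profiles=profiles,
        config={
            "tasks": list(tasks),
            "failures": failures,
            "split_ratio": split_ratio,
            "L": L,
            "beta": beta,
            "select_k": select_k,
            "min_games": min_games,
            "seed": seed,
            "n_players_eligible": len(players),
            "n_test_keys": int(len(test_keys)),
        },
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
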