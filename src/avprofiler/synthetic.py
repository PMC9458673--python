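"""Synthetic GNSS season generator with known ground-truth A-V envelopes.

Real club tracking data are proprietary, so this module fabricates seasons
of 10 Hz velocity traces from a known maximal-effort envelope

    a_max(v) = A0 * (1 - v / V0),

i.e. maximal acceleration declines linearly from ``A0`` (m/s^2) at rest to
zero at maximal velocity ``V0`` (m/s).  Sessions are intermittent: jogging,
submaximal efforts, deceleration ramps and a guaranteed set of maximal
bouts whose samples sit exactly on the envelope before noise, so the
extraction pipeline has a recoverable ground truth.  Athlete capacities
take a small multiplicative random-walk step each week, emulating
season-scale drift, and additive Gaussian noise emulates GNSS speed error.

Everything is deterministic given the season seed: each (player, session)
trace draws from its own child random stream, so traces can be regenerated
lazily instead of held in memory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .profile import FilterSpec, compute_acceleration, lowpass_filter

__all__ = [
    "GroundTruthProfile",
    "SessionTrace",
    "SeasonConfig",
    "SeasonDataset",
    "SUMMARY_FEATURES",
    "simulate_bout",
    "simulate_session",
    "summarise_session",
    "simulate_season",
    "draw_player_profiles",
]

SEASON_START = _date(2019, 7, 1)
# weekday offsets of up to four sessions in a week (Mon, Tue, Thu, Sat, ...)
_WEEK_OFFSETS = (0, 1, 3, 5, 2, 4, 6)


@dataclass(frozen=True)
class GroundTruthProfile:
    """True maximal-acceleration envelope of a simulated athlete."""

    athlete_id: str
    A0: float = 4.72  # maximal theoretical acceleration at v=0, m/s^2
    V0: float = 8.86  # maximal velocity, m/s
    drift_sd: float = 0.01  # weekly fractional random-walk sd on A0 and V0

    def __post_init__(self) -> None:
        if self.A0 <= 0 or self.V0 <= 0:
            raise ValueError("A0 and V0 must be positive")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be non-negative")

    @property
    def intercept_true(self) -> float:
        return self.A0

    @property
    def slope_true(self) -> float:
        return -self.A0 / self.V0

    def envelope(self, v: np.ndarray) -> np.ndarray:
        """Maximal acceleration available at velocity v (clipped at 0)."""
        return np.maximum(self.A0 * (1.0 - np.asarray(v, dtype=float) / self.V0), 0.0)


@dataclass
class SessionTrace:
    """One session's uniformly sampled velocity signal plus metadata."""

    player_id: str
    session_id: str
    date: _date
    kind: str  # "game" | "training"
    sampling_rate: float
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")
        if self.v.size and self.v.min() < 0:
            raise ValueError("velocities must be non-negative")
        if self.t.size > 1:
            step = 1.0 / self.sampling_rate
            if np.abs(np.diff(self.t) - step).max() > 1e-9:
                raise ValueError("time stamps must be uniform")

    @property
    def duration_s(self) -> float:
        return self.t[-1] - self.t[0] + 1.0 / self.sampling_rate if self.t.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "velocity_mps": self.v})


@dataclass(frozen=True)
class SeasonConfig:
    """Season layout and noise settings.

    Defaults emulate a 1.5-season elite-football data set: 42 players, 74
    games and 196 training sessions at roughly four sessions a week, 90 min
    games and 60 min trainings, with every player attending every session.
    ``bout_mix`` gives the (maximal, submaximal) bout proportions.
    """

    n_players: int = 42
    n_games: int = 74
    n_trainings: int = 196
    sessions_per_week: int = 4
    noise_sd: float = 0.1  # additive Gaussian velocity noise, m/s
    seed: int = 0
    bout_mix: tuple[float, float] = (0.25, 0.75)
    game_duration_s: float = 5400.0
    training_duration_s: float = 3600.0
    acute_sd: float = 0.05  # per-session fractional day-form variation

    def __post_init__(self) -> None:
        if min(self.n_players, self.n_games, self.n_trainings) <= 0:
            raise ValueError("player and session counts must be positive")
        if not 1 <= self.sessions_per_week <= len(_WEEK_OFFSETS):
            raise ValueError("sessions_per_week must be in 1..7")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(sum(self.bout_mix) - 1.0) > 1e-9 or min(self.bout_mix) < 0:
            raise ValueError("bout_mix proportions must be non-negative and sum to 1")
        if self.game_duration_s <= 0 or self.training_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.acute_sd < 0:
            raise ValueError("acute_sd must be non-negative")


def simulate_bout(
    profile: GroundTruthProfile,
    effort: float,
    v_start: float,
    v_target: float,
    omega: float = 10.0,
    max_duration_s: float = 20.0,
) -> np.ndarray:
    """Accelerative bout by first-order Euler integration of the envelope ODE.

    dv/dt = effort * A0 * (1 - v/V0), stepped at 1/omega until v reaches
    ``v_target`` (or the duration cap).  The implicit (backward) Euler step
    is used so that every per-sample difference satisfies

        (v_{n+1} - v_n) * omega == effort * A0 * (1 - v_{n+1}/V0)

    exactly — the envelope identity holds at the sample's own velocity,
    which is the convention the backward-difference extraction pairs with.
    The recursion is affine and evaluated in closed form; the returned
    samples start at ``v_start``.
    """
    if not 0 < effort <= 1:
        raise ValueError("effort must be in (0, 1]")
    if v_target > profile.V0:
        raise ValueError(
            f"v_target {v_target} m/s exceeds the athlete's V0 {profile.V0} m/s"
        )
    if not 0 <= v_start < v_target:
        raise ValueError("require 0 <= v_start < v_target")
    b = 1.0 / (1.0 + effort * profile.A0 / (omega * profile.V0))
    gap0 = profile.V0 - v_start
    gap_target = profile.V0 - v_target
    n_cap = int(round(max_duration_s * omega))
    if gap_target <= 0:
        n = n_cap
    else:
        n = int(np.ceil(np.log(gap_target / gap0) / np.log(b)))
        n = min(max(n, 1), n_cap)
    return profile.V0 - gap0 * b ** np.arange(n + 1)


def _decel_ramp(v_from: float, v_to: float, omega: float, rate: float = 3.0) -> np.ndarray:
    """Constant-deceleration ramp from v_from down to v_to (exclusive ends)."""
    step = rate / omega
    if v_from - v_to <= step:
        return np.empty(0)
    return np.arange(v_from - step, v_to, -step)


def simulate_session(
    profile: GroundTruthProfile,
    kind: str,
    duration_s: float,
    config: SeasonConfig,
    rng: np.random.Generator,
    player_id: str = "",
    session_id: str = "",
    date: _date = SEASON_START,
    omega: float = 10.0,
) -> SessionTrace:
    """Assemble one intermittent session and add velocity noise.

    The session interleaves jogging, submaximal accelerate-hold-decelerate
    efforts and a set of maximal bouts whose target velocities are
    stratified from ~0.55*V0 up to 0.97*V0 (starts drawn below 2.5 m/s), so
    every velocity bin from the fit threshold up toward V0 receives
    envelope-touching samples.  Gaussian noise (sd ``config.noise_sd``) is
    added to the whole trace and clipped at zero.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_total = int(round(duration_s * omega))

    # plan the guaranteed maximal bouts: stratified targets reaching toward V0
    n_max = max(8, int(round(duration_s / 450.0)))
    fracs = np.linspace(0.55, 0.97, n_max) + rng.uniform(-0.02, 0.02, n_max)
    targets = np.clip(fracs, 0.3, 0.975) * profile.V0
    rng.shuffle(targets)
    # worst-case sample need per maximal bout (start at rest) + ramp/jog slack
    b_step = 1.0 / (1.0 + profile.A0 / (omega * profile.V0))
    worst = [
        int(np.ceil(np.log((profile.V0 - t) / profile.V0) / np.log(b_step))) + 80
        for t in targets
    ]
    if sum(worst) > n_total:
        raise ValueError(
            f"duration {duration_s} s too short for {n_max} maximal bouts "
            f"(needs roughly {sum(worst) / omega:.0f} s)"
        )

    p_max = config.bout_mix[0]
    segments: list[np.ndarray] = []
    budget = n_total
    k = 0  # next maximal bout index
    cv = 0.3  # current velocity; every segment starts where the last ended

    def push(seg: np.ndarray) -> None:
        nonlocal budget, cv
        seg = seg[:budget]
        if seg.size:
            segments.append(seg)
            budget -= seg.size
            cv = seg[-1]

    push(np.full(min(int(rng.uniform(50, 200)), budget), cv))
    while budget > 0:
        force_max = k < n_max and budget < sum(worst[k:]) + 600
        if k < n_max and (force_max or rng.uniform() < p_max):
            push(simulate_bout(profile, 1.0, cv, targets[k], omega))
            k += 1
        else:
            v_t = max(rng.uniform(2.0, 5.5), cv + 0.5)
            push(simulate_bout(profile, rng.uniform(0.3, 0.7), cv,
                               min(v_t, 0.95 * profile.V0), omega))
            push(np.full(int(rng.uniform(20, 80)), cv))  # hold at reached speed
        jog_v = rng.uniform(0.2, 1.8)
        push(_decel_ramp(cv, jog_v, omega))
        push(np.full(int(rng.uniform(50, 200)), min(cv, jog_v)))
    v = np.concatenate(segments)[:n_total]
    if v.size < n_total:  # pad with steady jog if assembly undershot
        v = np.concatenate([v, np.full(n_total - v.size, float(v[-1]))])
    if config.noise_sd > 0:
        v = v + rng.normal(0.0, config.noise_sd, n_total)
        v = np.clip(v, 0.0, None)
    t = np.arange(n_total) / omega
    return SessionTrace(
        player_id=player_id or profile.athlete_id,
        session_id=session_id,
        date=date,
        kind=kind,
        sampling_rate=omega,
        t=t,
        v=v,
    )


#: zone edges for distance-per-speed-zone features, m/s
SPEED_ZONE_EDGES = (0.0, 2.0, 4.0, 5.5, 7.0)

SUMMARY_FEATURES = (
    "total_distance_m",
    "dist_zone1_m",
    "dist_zone2_m",
    "dist_zone3_m",
    "dist_zone4_m",
    "dist_zone5_m",
    "accel_count_2",
    "accel_count_3",
    "decel_count_2",
    "decel_count_3",
    "max_speed_mps",
    "mean_moving_speed_mps",
    "sprint_count",
    "peak_filtered_accel_mps2",
    "duration_s",
)


def _episode_count(mask: np.ndarray) -> int:
    """Number of contiguous True episodes (one count per threshold crossing)."""
    if mask.size == 0:
        return 0
    return int(mask[0]) + int(np.count_nonzero(mask[1:] & ~mask[:-1]))


def summarise_session(
    trace: SessionTrace,
    zone_edges: tuple[float, ...] = SPEED_ZONE_EDGES,
    filter_spec: FilterSpec | None = None,
    moving_threshold: float = 0.5,
    sprint_threshold: float = 7.0,
    a_filtered: np.ndarray | None = None,
) -> dict[str, float]:
    """Commercial-style per-session summary features.

    Distance integrates v*T; acceleration/deceleration counts are
    threshold-crossing episodes of the Butterworth-filtered acceleration
    (one count per contiguous supra-threshold stretch); sprint count is the
    number of entries above ``sprint_threshold``.  ``a_filtered`` lets
    callers that already filtered the acceleration avoid recomputing it.
    """
    v = trace.v
    T = 1.0 / trace.sampling_rate
    dist = v * T
    total = float(dist.sum())
    edges = np.asarray(zone_edges + (np.inf,))
    zone_idx = np.searchsorted(edges, v, side="right") - 1
    zones = np.bincount(zone_idx, weights=dist, minlength=len(zone_edges))

    a_f = (
        a_filtered
        if a_filtered is not None
        else lowpass_filter(
            compute_acceleration(v, trace.sampling_rate), trace.sampling_rate, filter_spec
        )
    )
    moving = v > moving_threshold
    out = {
        "total_distance_m": total,
        "dist_zone1_m": float(zones[0]),
        "dist_zone2_m": float(zones[1]),
        "dist_zone3_m": float(zones[2]),
        "dist_zone4_m": float(zones[3]),
        "dist_zone5_m": float(zones[4]),
        "accel_count_2": _episode_count(a_f > 2.0),
        "accel_count_3": _episode_count(a_f > 3.0),
        "decel_count_2": _episode_count(a_f < -2.0),
        "decel_count_3": _episode_count(a_f < -3.0),
        "max_speed_mps": float(v.max()),
        "mean_moving_speed_mps": float(v[moving].mean()) if moving.any() else 0.0,
        "sprint_count": _episode_count(v > sprint_threshold),
        "peak_filtered_accel_mps2": float(a_f.max()),
        "duration_s": float(v.size * T),
    }
    return out


def draw_player_profiles(
    n_players: int, rng: np.random.Generator, drift_sd: float = 0.01
) -> list[GroundTruthProfile]:
    """Draw a squad of athlete envelopes around the typical elite profile.

    Intercepts are N(4.72, 0.35) m/s^2 and slopes N(-0.533, 0.05) 1/s
    (truncated to a physiological range); V0 follows as -A0/slope.
    """
    profiles = []
    for i in range(n_players):
        a0 = float(np.clip(rng.normal(4.72, 0.35), 3.5, 6.0))
        slope = float(np.clip(rng.normal(-0.533, 0.05), -0.70, -0.40))
        profiles.append(
            GroundTruthProfile(
                athlete_id=f"P{i:02d}", A0=a0, V0=-a0 / slope, drift_sd=drift_sd
            )
        )
    return profiles


def build_schedule(config: SeasonConfig) -> pd.DataFrame:
    """Team calendar: one row per session with id, date, kind and week.

    Games are spread evenly over the weeks and placed on the last slots of
    a week; the first slot of every week is a training, so every game is
    preceded by at least one training session.
    """
    S = config.n_games + config.n_trainings
    spw = config.sessions_per_week
    n_weeks = int(np.ceil(S / spw))
    game_cum = np.round(np.arange(1, n_weeks + 1) * config.n_games / n_weeks).astype(int)
    games_per_week = np.diff(np.concatenate([[0], game_cum]))
    rows = []
    sid = 0
    remaining = S
    for w in range(n_weeks):
        count = min(spw, remaining)
        remaining -= count
        g = min(games_per_week[w], max(count - 1, 0))
        kinds = ["training"] * (count - g) + ["game"] * g
        offsets = sorted(_WEEK_OFFSETS[:count])
        for slot, kind in enumerate(kinds):
            rows.append(
                {
                    "session_id": f"S{sid:03d}",
                    "date": SEASON_START + timedelta(days=7 * w + offsets[slot]),
                    "kind": kind,
                    "week": w,
                }
            )
            sid += 1
    df = pd.DataFrame(rows)
    # rounding may leave a surplus/deficit of games; fix from the tail
    diff = int((df["kind"] == "game").sum()) - config.n_games
    if diff:
        kinds = df["kind"].to_numpy().copy()
        flip_from, flip_to = ("game", "training") if diff > 0 else ("training", "game")
        idx = np.nonzero(kinds == flip_from)[0][::-1][: abs(diff)]
        kinds[idx] = flip_to
        df["kind"] = kinds
    return df


@dataclass
class SeasonDataset:
    """A simulated season: schedule, summaries, ground truth, lazy traces.

    Traces are regenerated on demand from per-(player, session) child
    random streams, so repeated access is byte-identical and the full
    season never needs to sit in memory.  Ground truth lives in ``truth``
    and is written to a separate file by :meth:`write`; model code paths
    only ever see ``schedule``, ``summaries`` and traces.
    """

    config: SeasonConfig
    players: list[GroundTruthProfile]
    schedule: pd.DataFrame
    truth: pd.DataFrame
    summaries: pd.DataFrame | None = None

    def _session_profile(self, player_idx: int, session_idx: int) -> GroundTruthProfile:
        row = self.truth.iloc[player_idx * len(self.schedule) + session_idx]
        base = self.players[player_idx]
        return dataclasses.replace(
            base, A0=row["intercept_true"], V0=-row["intercept_true"] / row["slope_true"]
        )

    def trace(self, player_id: str, session_id: str) -> SessionTrace:
        """Regenerate one session trace deterministically."""
        p_idx = next(i for i, p in enumerate(self.players) if p.athlete_id == player_id)
        s_idx = int(self.schedule.index[self.schedule["session_id"] == session_id][0])
        return self._make_trace(p_idx, s_idx)

    def _make_trace(self, p_idx: int, s_idx: int) -> SessionTrace:
        row = self.schedule.iloc[s_idx]
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1, p_idx, s_idx)))
        duration = (
            cfg.game_duration_s if row["kind"] == "game" else cfg.training_duration_s
        )
        return simulate_session(
            self._session_profile(p_idx, s_idx),
            kind=row["kind"],
            duration_s=duration,
            config=cfg,
            rng=rng,
            player_id=self.players[p_idx].athlete_id,
            session_id=row["session_id"],
            date=row["date"],
        )

    def iter_traces(self, kind: str | None = None) -> Iterator[SessionTrace]:
        """Yield every (player, session) trace, optionally one kind only."""
        for p_idx in range(len(self.players)):
            for s_idx in range(len(self.schedule)):
                if kind is None or self.schedule.iloc[s_idx]["kind"] == kind:
                    yield self._make_trace(p_idx, s_idx)

    def write(self, out_dir: str | Path, with_traces: bool = False) -> None:
        """Write schedule/summaries as JSON, ground truth separately.

        Ground truth goes to ``<out>/ground_truth/`` — a directory model
        code never reads — while traces (optional, large) are CSV files
        ``<player>_<date>_<kind>_<id>.csv`` under ``<out>/traces/``.
        """
        out = Path(out_dir)
        (out / "ground_truth").mkdir(parents=True, exist_ok=True)
        sched = self.schedule.copy()
        sched["date"] = sched["date"].astype(str)
        (out / "schedule.json").write_text(sched.to_json(orient="records", indent=1))
        if self.summaries is not None:
            summ = self.summaries.copy()
            summ["date"] = summ["date"].astype(str)
            (out / "summaries.json").write_text(summ.to_json(orient="records", indent=1))
        truth = self.truth.copy()
        truth["date"] = truth["date"].astype(str)
        (out / "ground_truth" / "truth.json").write_text(
            truth.to_json(orient="records", indent=1)
        )
        (out / "ground_truth" / "players.json").write_text(
            json.dumps([dataclasses.asdict(p) for p in self.players], indent=1)
        )
        if with_traces:
            tdir = out / "traces"
            tdir.mkdir(exist_ok=True)
            for tr in self.iter_traces():
                name = f"{tr.player_id}_{tr.date}_{tr.kind}_{tr.session_id}.csv"
                tr.to_frame().to_csv(tdir / name, index=False)


def simulate_season(
    config: SeasonConfig | None = None,
    profiles: list[GroundTruthProfile] | None = None,
    with_summaries: bool = True,
) -> SeasonDataset:
    """Simulate a full season for a squad of players.

    Before each calendar week every player's A0 and V0 take independent
    multiplicative random-walk steps of sd ``drift_sd``; on top of the
    walk, each session realises an acute day-form factor of sd
    ``acute_sd`` on both capacities (athletes fluctuate game to game, not
    only week to week — this is what makes same-day features genuinely
    more informative than history).  The realised per-session true
    coefficients are stored for recovery tests.  With ``with_summaries``
    the commercial-style summary of every (player, session) trace is
    computed in one streaming pass.
    """
    config = config or SeasonConfig()
    if profiles is None:
        prof_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
        profiles = draw_player_profiles(config.n_players, prof_rng)
    if not profiles:
        raise ValueError("need at least one player")
    schedule = build_schedule(config)
    n_weeks = int(schedule["week"].max()) + 1

    truth_rows = []
    for p_idx, prof in enumerate(profiles):
        drift_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2, p_idx)))
        steps_a = 1.0 + drift_rng.normal(0.0, prof.drift_sd, n_weeks)
        steps_v = 1.0 + drift_rng.normal(0.0, prof.drift_sd, n_weeks)
        if prof.drift_sd == 0:
            steps_a = np.ones(n_weeks)
            steps_v = np.ones(n_weeks)
        fa = np.cumprod(steps_a)
        fv = np.cumprod(steps_v)
        weeks = schedule["week"].to_numpy()
        n_sess = len(schedule)
        acute_a = 1.0 + drift_rng.normal(0.0, config.acute_sd, n_sess)
        acute_v = 1.0 + drift_rng.normal(0.0, config.acute_sd, n_sess)
        if config.acute_sd == 0:
            acute_a = np.ones(n_sess)
            acute_v = np.ones(n_sess)
        a0_w = prof.A0 * fa[weeks] * acute_a
        v0_w = prof.V0 * fv[weeks] * acute_v
        for s_idx in range(len(schedule)):
            row = schedule.iloc[s_idx]
            truth_rows.append(
                {
                    "player_id": prof.athlete_id,
                    "session_id": row["session_id"],
                    "date": row["date"],
                    "kind": row["kind"],
                    "intercept_true": a0_w[s_idx],
                    "slope_true": -a0_w[s_idx] / v0_w[s_idx],
                }
            )
    truth = pd.DataFrame(truth_rows)
    ds = SeasonDataset(config=config, players=list(profiles), schedule=schedule, truth=truth)
    if with_summaries:
        rows = []
        for tr in ds.iter_traces():
            rec = {
                "player_id": tr.player_id,
                "session_id": tr.session_id,
                "date": tr.date,
                "kind": tr.kind,
            }
            rec.update(summarise_session(tr))
            rows.append(rec)
        ds.summaries = pd.DataFrame(rows)
    return ds
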