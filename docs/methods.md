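# Methods

This note records the models, the numerical choices and the open design
decisions behind `avprofiler`, and what the synthetic benchmark does and
does not establish about real tracking data.

## A-V profile extraction

The in-situ A-V profile assumes that over a long enough session an
athlete repeatedly touches their maximal-effort envelope
`a_max(v) = Y^b + Y^a v`. The estimator:

1. **Acceleration.** Backward difference of the velocity signal scaled
   to physical units, `a_i = (v_i − v_{i−1})·ω` with `ω = 10` Hz. The
   raw per-sample difference alone would carry units of m/s per sample;
   scaling by `ω` is what makes intercepts of ~4.7 m/s² comparable with
   published values.
2. **Filtering.** First-order Butterworth low-pass, 1 Hz cut-off,
   applied to the acceleration signal only. Default is zero-phase
   (forward–backward, squared magnitude response, no lag between
   acceleration and the velocity it is paired with); a causal
   single-pass mode is available (`FilterSpec(mode="causal")`), whose
   gain at the cut-off is the textbook 1/√2 instead of 1/2.
3. **Binning.** Each acceleration sample is paired with its endpoint
   velocity `v_i` and assigned to left-closed bins of width 0.1 m/s;
   the maximum per bin is retained, with the per-bin sample count kept
   as a diagnostic.
4. **Fit.** OLS line through the bin maxima with centre strictly above
   3 m/s. A fit needs at least 10 populated bins (configurable);
   otherwise the profile is flagged invalid rather than dropped
   silently. Slope ≥ 0 or intercept ≤ 0 marks a profile implausible but
   still reported.

Conventions the method does not pin down, fixed here: bin centres (not
means) represent bins in the regression; "above 3 m/s" is strict; the
endpoint velocity (not the midpoint) is paired with each difference.

## The synthetic season generator

Real club data are proprietary, so the benchmark world is simulated with
a known truth. Each athlete has an envelope `a(v) = A0 (1 − v/V0)`
(population draws `A0 ~ N(4.72, 0.35)` m/s², slope `~ N(−0.533, 0.05)`
1/s truncated to a physiological range, `V0 = −A0/slope`). Sessions are
intermittent: jogging (0.2–1.8 m/s), submaximal accelerate–hold–
decelerate efforts (effort 30–70 %, targets 2–5.5 m/s), constant
−3 m/s² deceleration ramps, and per session at least eight maximal
bouts whose stratified targets span 0.55–0.97·V0, so every velocity bin
in the fit range receives envelope-touching samples. Velocity is
continuous across segments — discontinuities would put filtered
impulse artefacts into the bin maxima.

**Integration.** Bouts integrate `dv/dt = effort·A0(1 − v/V0)` with an
implicit first-order Euler step evaluated in closed form, so that every
per-sample difference satisfies
`(v_{n+1} − v_n)·ω = effort·A0(1 − v_{n+1}/V0)` exactly — the identity
is stated at the *sample's own* velocity because that is the pairing
the backward-difference extractor measures. With the explicit step the
identity holds at the step-start velocity instead, and the mismatch
(plus bin-edge max-picking) lifts recovered intercepts by a
deterministic ~6 %.

**Variation.** Three scales, all multiplicative on `A0` and `V0`:
a weekly random walk (`drift_sd`, default 1 % — season-scale form
drift), an acute per-session day-form factor (`acute_sd`, default 5 % —
game-to-game fluctuation; this is what makes same-day features
genuinely more informative than history, and without it the control
task has no structural advantage), and additive i.i.d. Gaussian
velocity noise (`noise_sd`, default 0.1 m/s, clipped at zero) emulating
GNSS speed error. The realised per-session coefficients are stored
separately from anything model code reads.

**Defaults** emulate an elite-football season and a half: 42 players,
74 games (90 min) and 196 trainings (60 min) at four sessions a week,
full squad participation, games placed after at least one training in
the week. A full default season generates, with summaries, in under
two minutes on one CPU; traces are regenerated lazily from per-session
child random streams rather than held in memory, so repeated access is
byte-identical.

**Known deviations of the world from real data.** Noise is white,
whereas Doppler-derived GNSS speed error is autocorrelated; efforts are
piecewise-stationary rather than tactically structured; decelerations
are a constant ramp; no positional information, signal dropouts or
satellite-geometry effects are modelled. Passing the benchmark
therefore shows the *pipeline* is correct and calibrated under
controlled conditions, not that real data meet its assumptions.

**Summary features.** The vendor-style per-session record (15 scalars:
total and per-zone distances, debounced acceleration/deceleration
counts at ±2 and ±3 m/s², max speed, mean moving speed above 0.5 m/s,
sprint entries above 7 m/s, peak filtered acceleration, duration)
deliberately includes peak filtered acceleration and max speed so that
same-day features identify the realised envelope — the control task's
low error is achievable by construction, as it evidently was in the
real study. One measured caveat: the session-wide peak of the filtered
acceleration under-shoots the envelope at its own velocity by a stable
≈5.9 %, because the peak sits just after a maximal-bout onset where
the two-sided kernel still mixes pre-bout zeros with an acceleration
decaying at `τ = V0/A0 ≈ 1.9 s`.

## Pooling

Predictors for a target game pool the last `L = 5` sessions preceding
it (games or trainings), by arithmetic mean or by softmax
exponential-decay weights `w_j = e^{−β t_j} / Σ_k e^{−β t_k}`. `t` is
measured in calendar days (session frequencies are heterogeneous, so
index-based decay would conflate a congested week with a sparse one).
`β` is a tunable decay scale with default 0.3 /day; `β = 0` reproduces
the mean exactly (identical summation order), large `β` concentrates
all weight on the most recent session. The minimum of `β t` is
subtracted before exponentiation. Windows shorter than `L` are kept by
default (dropping them would discard early-season games); a strict
mode drops them.

## Signal features and selection

27 closed-form features per velocity signal: 18 time-domain (moments,
quantiles, energy, mean crossings, streaks, autocorrelations at lags
1/10/50) and 9 frequency-domain from the one-sided DFT (spectral
centroid and variance, total energy, four band-energy fractions over
[0, 0.1), [0.1, 0.5), [0.5, 1.0) and [1.0, Nyquist] Hz, dominant
non-DC peak amplitude and frequency). The spectral normalisation is
pinned by Parseval's identity (`spectral_energy == Σx²`), and the four
band fractions partition the axis so they sum to one. The DFT is taken
on the raw, unwindowed signal with no detrending.

Stationarity is checked with the plain (unaugmented) Dickey-Fuller
test with constant — the first difference regressed on the lagged
level, the t-ratio compared to the tabulated 5 % critical value.

Selection keeps the ten features with the smallest univariate
regression p-values, `F = r²(n−2)/(1−r²)` with `p` from `F(1, n−2)`;
ties break by descending F then feature name so reports are
deterministic. Selection is always computed on training rows only, to
keep the chronological holdout honest.

## Models

**Ridge.** Features are z-scored with training statistics; the
intercept is fitted on the centred target and unpenalised; coefficients
solve `(ZᵀZ + λI)β = Zᵀy`. When `λ` is not supplied it is chosen from
the grid `10^{−3..3}` by expanding-window (chronological) 5-fold
cross-validation — never shuffled folds, since rows are a time series
per player. Constant features are dropped with a warning. Group-scope
(G) models pool all players' rows without player-wise centring;
individual scope (I) fits per player.

**Forecasters** see only the ordered game-by-game coefficient series:
naive (last value), drift (last value plus mean step), the theta
family, an FFT harmonic extrapolator, and an averaged ensemble
(default members: theta, four-theta, FFT; equal weights, optional
inverse-validation-MAPE weights). Minimum series lengths are 3
(naive/drift) and 8 (theta/FFT); a stricter ≥ 40-observation
eligibility filter, as used for data-hungry multivariate forecasters,
is available as a parameter. Other model families plug in through the
same `fit(series)` / `predict(horizon)` surface.

*Theta (trend-exact variant).* The series decomposes into its OLS
trend line Z(0) and theta-lines `Z(θ) = θ·y − (θ−1)·Z(0)`;
`(Z(0) + Z(2))/2` reconstructs the series exactly. The forecast
averages the Z(0) branch with the Z(θ) branch, where the trend is
extrapolated exactly and simple exponential smoothing (α on a
0.01–0.99 grid by one-step SSE) flat-extrapolates the θ-scaled
detrended component. Flat SES extrapolation of the *full* theta line —
the textbook formulation — lags a trending series by `(1−α)/α` steps
and cannot continue even a perfectly linear series; extrapolating the
trend exactly removes that lag while leaving the stochastic component
to SES. Four-theta tunes `θ ∈ {1, 2, 3, 4}` on a validation tail
(last 20 %, at least two points) and refits on the full series.

*FFT.* The top-K (default 3) magnitude frequencies are selected from
the spectrum of the OLS-detrended series, then trend and retained
harmonics are refitted jointly by least squares and extrapolated. The
joint refit matters: a plain OLS detrend of an integer-cycle sinusoid
fits a spurious slope of `−6/(πkn)` whose extrapolation dominates the
error budget.

## Evaluation

MAPE is reported as a fraction, `mean(|y − ŷ| / |y|)`; zero truths are
an error, not a silent skip. Summaries average per-player MAPEs across
players (a pooled-rows option exists). Cross-target comparisons use the
slope series affinely mapped onto the intercept's training range, with
the map reapplied to test rows.

The test split is the final 20 % of each eligible player's games by
date (players need ≥ 10 valid game profiles), and **every task scores
exactly the same (player, game) keys** — the comparability contract
that makes the ranking table meaningful. Classical repeated-measures
ANOVA with post-hoc adjustment is deliberately replaced by a seeded
paired bootstrap over players (2000 replicates, percentile CIs,
two-sided p): it plays the same decision role with fewer distributional
assumptions and is exactly reproducible.

Problem sizes used by the shipped checks: recovery uses 50 simulated
90-minute sessions per noise condition; calibration and the
model-comparison ordering use full default seasons (42 players, 270
team sessions; ~630 scored test keys per task) — one season per seed,
three to five seeds, chosen as the smallest replication that keeps the
stochastic checks stable.

## Known limitations

- The generator's envelope is exactly linear; curvature or
  velocity-dependent noise in real athletes' envelopes is not
  modelled, so extraction bias under misspecification is untested.
- The acute-form and drift magnitudes are plausibility choices, not
  fitted to data; conclusions about the *relative* ordering of tasks
  are robust to them, absolute MAPEs are not.
- Only uni-modal forecasting is built in; vector (multi-modal)
  forecasting of slope and intercept jointly is out of scope and
  available only through the plug-in interface.
- The bootstrap treats players as exchangeable units and ignores
  within-player autocorrelation of errors across test games.
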