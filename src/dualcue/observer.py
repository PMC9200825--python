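"""Synthetic observers for both tasks.

The covert observer answers a 2AFC orientation judgement with
probability given by a cumulative-Gaussian psychometric function whose
location shifts multiplicatively by trial type (attention lowers the
threshold on validly cued trials and raises it on invalid ones).

The gaze observer emits raw 1-kHz position traces: Gaussian fixation
noise plus saccades with an error-function position profile, i.e. a
Gaussian velocity profile obeying a linear main sequence
(peak velocity = slope x amplitude).  Trial-type-dependent latencies,
direction errors, and cue-driven anticipatory saccades (optionally
followed by a corrective movement) reproduce the statistical structure
the oculomotor analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

__all__ = [
    "ObserverParams",
    "GazeSimParams",
    "GazeTrace",
    "psychometric_p",
    "simulate_covert",
    "simulate_gaze_trial",
    "simulate_gaze_session",
    "write_responses",
    "write_traces",
    "read_trace",
]


def psychometric_p(
    contrast, mu: float, sigma: float, guess: float = 0.5, lapse: float = 0.0
):
    """P(correct) = guess + (1 - guess - lapse) * Phi((c - mu) / sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    contrast = np.asarray(contrast, dtype=float)
    p = guess + (1.0 - guess - lapse) * ndtr((contrast - mu) / sigma)
    return float(p) if p.ndim == 0 else p


@dataclass
class ObserverParams:
    """Psychometric parameters of the simulated covert observer.

    ``effect_valid`` / ``effect_invalid`` are fractional shifts of the
    neutral location mu (e.g. -0.05 lowers the threshold by 5% on valid
    trials).  Defaults match the magnitude of the reported group
    effects (valid about -5%, invalid about +10%, baseline threshold
    near 0.045 contrast).
    """

    mu_neutral: float = 0.045
    sigma: float = 0.012
    guess: float = 0.5
    lapse: float = 0.0
    effect_valid: float = -0.05
    effect_invalid: float = 0.10
    rt_mean_ms: float = 600.0
    rt_sd_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.guess + self.lapse < 1:
            raise ValueError("guess + lapse must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for eff in (self.effect_valid, self.effect_invalid):
            if self.mu_neutral * (1 + eff) <= 0:
                raise ValueError("effects must keep mu positive")

    def mu_for(self, trial_type: str) -> float:
        eff = {"neutral": 0.0, "valid": self.effect_valid,
               "invalid": self.effect_invalid}[trial_type]
        return self.mu_neutral * (1.0 + eff)


def simulate_covert(schedule, params: ObserverParams) -> pd.DataFrame:
    """Bernoulli 2AFC responses for every trial of a covert schedule."""
    df = schedule.trials if hasattr(schedule, "trials") else schedule
    if (df["task"] != "covert").any():
        raise ValueError("simulate_covert requires a covert schedule")
    rng = np.random.default_rng(params.seed)
    mu = df["trial_type"].map(params.mu_for).to_numpy(dtype=float)
    p = params.guess + (1 - params.guess - params.lapse) * ndtr(
        (df["contrast"].to_numpy(dtype=float) - mu) / params.sigma
    )
    correct = rng.random(len(df)) < p
    rt = rng.normal(params.rt_mean_ms, params.rt_sd_ms, len(df)).clip(150)
    return pd.DataFrame(
        {"trial_id": df["trial_id"].to_numpy(), "correct": correct.astype(int),
         "rt_ms": rt}
    )


@dataclass
class GazeSimParams:
    """Kinematic and statistical parameters of the simulated gaze observer.

    Latencies (ms re target onset) are truncated Gaussians on (80, 500);
    the neutral mean shifts fractionally by trial type.  ``p_error`` and
    ``p_anticipatory`` map trial type to the probability of a direction
    error and of a cue-driven anticipatory saccade.  The main sequence
    is linear: peak velocity (deg/s) = main_sequence_slope x amplitude.
    Onset of a programmed saccade is defined as the instant its velocity
    profile crosses ``onset_speed_deg_s``.
    """

    sample_rate: float = 1000.0
    latency_mean_neutral: float = 165.0
    latency_sd: float = 25.0
    effect_valid: float = -0.04
    effect_invalid: float = 0.05
    p_error: dict = field(default_factory=lambda: {
        "neutral": 0.025, "valid": 0.007, "invalid": 0.055})
    p_anticipatory: dict = field(default_factory=lambda: {
        "neutral": 0.04, "valid": 0.08, "invalid": 0.08})
    p_anticipatory_to_salient: float = 0.8
    amplitude_deg: float = 5.0
    noise_sd_deg: float = 0.05
    main_sequence_slope: float = 55.0  # 1/s
    onset_speed_deg_s: float = 30.0
    latency_window_ms: tuple = (80.0, 500.0)
    trace_end_ms: float = 700.0
    latency_distribution: str = "truncnorm"  # or "exgauss"
    exgauss_tau_ms: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate < 250:
            raise ValueError("sample_rate must be >= 250 Hz")
        if self.amplitude_deg <= 0:
            raise ValueError("amplitude_deg must be positive")
        for d in (self.p_error, self.p_anticipatory):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.p_anticipatory_to_salient <= 1:
            raise ValueError("p_anticipatory_to_salient must lie in [0, 1]")

    @property
    def profile_sigma_ms(self) -> float:
        # Gaussian velocity profile width implied by the linear main
        # sequence: displacement A = Vp * sigma * sqrt(2*pi) with
        # Vp = slope * A, so sigma = 1 / (slope * sqrt(2*pi)).
        return 1000.0 / (self.main_sequence_slope * np.sqrt(2 * np.pi))

    def latency_mean(self, trial_type: str) -> float:
        eff = {"neutral": 0.0, "valid": self.effect_valid,
               "invalid": self.effect_invalid}[trial_type]
        return self.latency_mean_neutral * (1.0 + eff)


@dataclass
class GazeTrace:
    """Raw sampled eye position; time in ms relative to target onset."""

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    target_onset_ms: float
    target_side: str
    salient_side: str
    meta: dict = field(default_factory=dict)

    @property
    def sample_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.t_ms)))


def _saccade_profile(t_ms: np.ndarray, onset_ms: float, displacement: float,
                     params: GazeSimParams) -> tuple[np.ndarray, float]:
    """Error-function position step whose velocity crosses the onset speed
    at ``onset_ms``.  Returns (positions, end_ms of the movement)."""
    sigma = params.profile_sigma_ms
    vp = params.main_sequence_slope * abs(displacement)
    v0 = min(params.onset_speed_deg_s, 0.9 * vp)
    delta = sigma * np.sqrt(2.0 * np.log(vp / v0))  # onset -> peak lead time
    center = onset_ms + delta
    return displacement * ndtr((t_ms - center) / sigma), center + 4.0 * sigma


def _draw_latency(trial_type: str, params: GazeSimParams,
                  rng: np.random.Generator) -> float:
    lo, hi = params.latency_window_ms
    mean = params.latency_mean(trial_type)
    if params.latency_distribution == "exgauss":
        for _ in range(1000):
            v = rng.normal(mean - params.exgauss_tau_ms, params.latency_sd) \
                + rng.exponential(params.exgauss_tau_ms)
            if lo < v < hi:
                return v
        return float(np.clip(v, lo + 1, hi - 1))
    a = (lo - mean) / params.latency_sd
    b = (hi - mean) / params.latency_sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=params.latency_sd,
                               random_state=rng))


def simulate_gaze_trial(trial, params: GazeSimParams,
                        rng: np.random.Generator | None = None) -> GazeTrace:
    """One raw gaze trace for a gaze-task trial.

    With probability ``p_anticipatory`` the trace contains an early
    small saccade (amplitude 1-2.5 deg, onset uniform in (-70, 80) ms re
    target onset, directed to the salient side with probability
    ``p_anticipatory_to_salient``) followed by a corrective saccade that
    reaches the target; otherwise a single regular saccade of
    ``amplitude_deg`` toward the target, flipped with ``p_error``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    get = trial.get if hasattr(trial, "get") else lambda k: getattr(trial, k)
    if get("task") != "gaze":
        raise ValueError("simulate_gaze_trial requires a gaze trial")
    target_side = get("target_side")
    salient_side = get("salient_side")
    trial_type = get("trial_type")
    soa = float(get("soa_ms"))
    dt = 1000.0 / params.sample_rate
    t = np.arange(-soa, params.trace_end_ms + dt / 2, dt)
    x = rng.normal(0.0, params.noise_sd_deg, t.size)
    y = rng.normal(0.0, params.noise_sd_deg, t.size)
    target_x = params.amplitude_deg if target_side == "right" else -params.amplitude_deg
    sides = {"left": -1.0, "right": 1.0}
    meta: dict = {"trial_id": get("trial_id"), "has_anticipatory": False,
                  "erroneous": False}

    antic_end = -np.inf
    landing = 0.0
    if rng.random() < params.p_anticipatory.get(trial_type, 0.0):
        amp = rng.uniform(1.0, 2.5)
        onset = rng.uniform(-70.0, 80.0)
        if salient_side in sides:
            toward = salient_side if rng.random() < params.p_anticipatory_to_salient \
                else ("left" if salient_side == "right" else "right")
        else:
            toward = "left" if rng.random() < 0.5 else "right"
        disp = sides[toward] * amp
        prof, antic_end = _saccade_profile(t, onset, disp, params)
        x = x + prof
        landing = disp
        meta.update(has_anticipatory=True, anticipatory_onset_ms=onset,
                    anticipatory_direction=toward, anticipatory_amplitude_deg=amp)

    reg_onset = _draw_latency(trial_type, params, rng)
    if meta["has_anticipatory"]:
        # corrective saccade: continue or reverse to reach the target,
        # leaving a margin so the two movements never merge in detection
        reg_onset = max(reg_onset, antic_end + 40.0)
        disp = target_x - landing
        reg_dir = "right" if disp > 0 else "left"
    else:
        erroneous = rng.random() < params.p_error.get(trial_type, 0.0)
        meta["erroneous"] = bool(erroneous)
        disp = -target_x if erroneous else target_x
        reg_dir = "right" if disp > 0 else "left"
    prof, _ = _saccade_profile(t, reg_onset, disp, params)
    x = x + prof
    meta.update(regular_onset_ms=float(reg_onset), regular_direction=reg_dir,
                regular_amplitude_deg=abs(disp))
    return GazeTrace(t, x, y, 0.0, target_side, str(salient_side), meta)


def simulate_gaze_session(schedule, params: GazeSimParams) -> list[GazeTrace]:
    """Seed-deterministic traces for every trial of a gaze schedule."""
    df = schedule.trials if hasattr(schedule, "trials") else schedule
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(len(df))
    return [
        simulate_gaze_trial(row, params, np.random.default_rng(ss))
        for (_, row), ss in zip(df.iterrows(), streams)
    ]


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def write_traces(traces: list[GazeTrace], out_dir: str | Path,
                 params: GazeSimParams | None = None) -> Path:
    """Per-trial CSVs (t_ms, x_deg, y_deg) plus a JSON manifest."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for tr in traces:
        fname = f"trace_{int(tr.meta['trial_id']):05d}.csv"
        pd.DataFrame({"t_ms": tr.t_ms, "x_deg": tr.x_deg, "y_deg": tr.y_deg}
                     ).to_csv(out / fname, index=False, float_format="%.5f")
        files.append(fname)
    manifest = {"files": files}
    if params is not None:
        manifest["params"] = {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in asdict(params).items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def read_trace(path: str | Path, target_side: str = "right",
               salient_side: str = "none") -> GazeTrace:
    df = pd.read_csv(path)
    return GazeTrace(df["t_ms"].to_numpy(), df["x_deg"].to_numpy(),
                     df["y_deg"].to_numpy(), 0.0, target_side, salient_side)
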