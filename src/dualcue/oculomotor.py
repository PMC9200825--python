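"""Saccade detection and classification for the gaze-orienting task.

Raw gaze traces are low-pass filtered (zero-phase second-order
Butterworth, 30 Hz cutoff), numerically differentiated, and searched
for saccades with a conjoint velocity-acceleration threshold: an event
begins at the first sample where speed and acceleration magnitude both
exceed their thresholds and extends while speed stays above a fraction
of the velocity threshold.

Detected events are classified by latency relative to target onset:

* regular saccade — the first event with latency in (80, 500) ms and
  amplitude > 2 deg (40% of the 5-deg target eccentricity); labelled
  correct if directed to the target, erroneous otherwise.
* anticipatory saccade — latency in (-70, 80) ms and amplitude >= 1 deg,
  presumed cue-driven.
* trials without any detected saccade are aberrant and excluded.

Summaries report mean correct-saccade latencies (with percentage change
relative to the same condition's neutral baseline), direction-error and
anticipatory percentages over the total number of saccades per cell,
and the preferential direction of anticipatory saccades in non-neutral
trials (weighted across participants by their anticipatory counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .observer import GazeTrace
from .psychometrics import relative_change

__all__ = [
    "SaccadeEvent",
    "TrialClassification",
    "lowpass_filter",
    "differentiate",
    "detect_saccades",
    "classify_trial",
    "classification_table",
    "summarize_gaze",
    "check_fixation",
    "analyze_session",
    "REGULAR_LATENCY_WINDOW_MS",
    "REGULAR_MIN_AMPLITUDE_DEG",
    "ANTICIPATORY_LATENCY_WINDOW_MS",
    "ANTICIPATORY_MIN_AMPLITUDE_DEG",
]

# classification windows; latency bounds are open intervals
REGULAR_LATENCY_WINDOW_MS = (80.0, 500.0)
REGULAR_MIN_AMPLITUDE_DEG = 2.0  # 40% of the 5-deg cue/target eccentricity
ANTICIPATORY_LATENCY_WINDOW_MS = (-70.0, 80.0)
ANTICIPATORY_MIN_AMPLITUDE_DEG = 1.0


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    direction: str

    @property
    def latency_ms(self) -> float:
        return self.onset_ms

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass
class TrialClassification:
    trial_id: int
    events: list
    regular: SaccadeEvent | None
    regular_label: str  # correct | erroneous | none
    anticipatory: list
    aberrant: bool
    n_unclassified: int = 0


def _check_uniform(t_ms: np.ndarray) -> float:
    dt = np.diff(t_ms)
    if dt.size == 0:
        raise ValueError("trace too short")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise ValueError("timestamps jitter beyond 1% of the sample interval")
    return med


def lowpass_filter(trace: GazeTrace, cutoff_hz: float = 30.0,
                   order: int = 2) -> GazeTrace:
    """Zero-phase (forward-backward) Butterworth low-pass, DC gain 1.

    Edge effects are handled by odd-reflection padding three filter
    characteristic times (3 / cutoff) long, which preserves linear
    trends at the trace boundaries.
    """
    dt_ms = _check_uniform(trace.t_ms)
    if trace.t_ms.size < 20:
        raise ValueError("need at least 20 samples to filter")
    fs = 1000.0 / dt_ms
    b, a = butter(order, cutoff_hz, fs=fs)
    padlen = min(int(3 * fs / cutoff_hz), trace.t_ms.size - 1)
    x = filtfilt(b, a, trace.x_deg, padtype="odd", padlen=padlen)
    y = filtfilt(b, a, trace.y_deg, padtype="odd", padlen=padlen)
    return GazeTrace(trace.t_ms, x, y, trace.target_onset_ms,
                     trace.target_side, trace.salient_side, dict(trace.meta))


def differentiate(t_ms: np.ndarray, pos_deg: np.ndarray) -> np.ndarray:
    """Velocity in deg/s: central differences interior, one-sided at ends."""
    if pos_deg.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(pos_deg, t_ms / 1000.0)


def detect_saccades(
    trace: GazeTrace,
    v_thresh_deg_s: float = 30.0,
    a_thresh_deg_s2: float = 2000.0,
    min_dur_ms: float = 8.0,
    merge_gap_ms: float = 20.0,
    offset_fraction: float = 1.0 / 3.0,
    amplitude_margin_ms: float = 5.0,
) -> list[SaccadeEvent]:
    """Conjoint velocity-acceleration threshold saccade detection.

    An event starts at the first sample where speed > ``v_thresh`` AND
    acceleration magnitude > ``a_thresh``, and extends while speed stays
    above ``offset_fraction * v_thresh``.  Events closer than
    ``merge_gap_ms`` are merged; events shorter than ``min_dur_ms`` are
    discarded.  Amplitude is the net horizontal displacement magnitude
    across the event, read ``amplitude_margin_ms`` outside the
    thresholded interval so the sub-threshold tails of the velocity
    profile are not clipped; direction is its sign.
    """
    t = trace.t_ms
    dt_ms = _check_uniform(t)
    vx = differentiate(t, trace.x_deg)
    vy = differentiate(t, trace.y_deg)
    speed = np.hypot(vx, vy)
    ax = differentiate(t, vx)
    ay = differentiate(t, vy)
    amag = np.hypot(ax, ay)

    above = speed > offset_fraction * v_thresh_deg_s
    conj = (speed > v_thresh_deg_s) & (amag > a_thresh_deg_s2)
    # contiguous above-offset regions that contain a conjoint-threshold sample
    regions = []
    idx = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
    for s, e in zip(idx[::2], idx[1::2]):  # half-open [s, e)
        hits = np.flatnonzero(conj[s:e])
        if hits.size:
            regions.append((s + int(hits[0]), e - 1))  # onset at conjoint hit
    # merge events separated by less than merge_gap_ms
    merged: list[list[int]] = []
    for s, e in regions:
        if merged and (t[s] - t[merged[-1][1]]) < merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    margin = int(round(amplitude_margin_ms / dt_ms))
    for s, e in merged:
        if t[e] - t[s] < min_dur_ms:
            continue
        s_amp = max(s - margin, 0)
        e_amp = min(e + margin, t.size - 1)
        disp = trace.x_deg[e_amp] - trace.x_deg[s_amp]
        events.append(SaccadeEvent(
            onset_ms=float(t[s]),
            offset_ms=float(t[e]),
            amplitude_deg=float(abs(disp)),
            peak_velocity_deg_s=float(speed[s:e + 1].max()),
            direction="right" if disp > 0 else "left",
        ))
    return events


def _in_open(x: float, window: tuple) -> bool:
    return window[0] < x < window[1]


def classify_trial(events: list, trial) -> TrialClassification:
    """Partition detected events into regular / anticipatory / unclassified.

    The regular saccade is the FIRST event inside the regular latency
    window with sufficient amplitude; window boundaries are open, so an
    event exactly at a boundary is unclassified.
    """
    get = trial.get if hasattr(trial, "get") else lambda k: getattr(trial, k)
    events = sorted(events, key=lambda ev: ev.onset_ms)
    regular = None
    anticipatory = []
    n_other = 0
    for ev in events:
        if (regular is None
                and _in_open(ev.latency_ms, REGULAR_LATENCY_WINDOW_MS)
                and ev.amplitude_deg > REGULAR_MIN_AMPLITUDE_DEG):
            regular = ev
        elif (_in_open(ev.latency_ms, ANTICIPATORY_LATENCY_WINDOW_MS)
                and ev.amplitude_deg >= ANTICIPATORY_MIN_AMPLITUDE_DEG):
            anticipatory.append(ev)
        else:
            n_other += 1
    if regular is None:
        label = "none"
    elif regular.direction == get("target_side"):
        label = "correct"
    else:
        label = "erroneous"
    return TrialClassification(
        trial_id=int(get("trial_id")), events=events, regular=regular,
        regular_label=label, anticipatory=anticipatory,
        aberrant=len(events) == 0, n_unclassified=n_other,
    )


def classification_table(classifications: list) -> pd.DataFrame:
    """Flatten per-trial classifications to one row per trial."""
    rows = []
    for c in classifications:
        rows.append({
            "trial_id": c.trial_id,
            "n_events": len(c.events),
            "aberrant": c.aberrant,
            "regular_label": c.regular_label,
            "regular_latency_ms": c.regular.latency_ms if c.regular else np.nan,
            "regular_direction": c.regular.direction if c.regular else "",
            "regular_amplitude_deg": c.regular.amplitude_deg if c.regular else np.nan,
            "n_anticipatory": len(c.anticipatory),
            "n_anticipatory_left": sum(ev.direction == "left" for ev in c.anticipatory),
            "n_anticipatory_right": sum(ev.direction == "right" for ev in c.anticipatory),
            "n_unclassified": c.n_unclassified,
        })
    return pd.DataFrame(rows)


def _cell_stats(sub: pd.DataFrame, denominator: str) -> dict:
    reg = sub[sub["regular_label"] != "none"]
    correct = reg[reg["regular_label"] == "correct"]
    n_err = int((reg["regular_label"] == "erroneous").sum())
    n_antic = int(sub["n_anticipatory"].sum())
    total = len(reg) + (n_antic if denominator == "all_saccades" else 0)
    nonneutral = sub[sub["trial_type"] != "neutral"]
    n_antic_nn = int(nonneutral["n_anticipatory"].sum())
    to_salient = int(
        np.where(nonneutral["salient_side"] == "left",
                 nonneutral["n_anticipatory_left"],
                 nonneutral["n_anticipatory_right"]).sum()
    ) if len(nonneutral) else 0
    return {
        "n_trials": len(sub),
        "n_aberrant": int(sub["aberrant"].sum()),
        "n_regular": len(reg),
        "n_correct": len(correct),
        "n_erroneous": n_err,
        "n_anticipatory": n_antic,
        "n_saccades": total,
        "mean_latency_ms": correct["regular_latency_ms"].mean(),
        "sem_latency_ms": correct["regular_latency_ms"].sem(),
        "pct_direction_errors": 100.0 * n_err / total if total else np.nan,
        "pct_anticipatory": 100.0 * n_antic / total if total else np.nan,
        "n_anticipatory_nonneutral": n_antic_nn,
        "n_anticipatory_to_salient": to_salient,
    }


def summarize_gaze(
    classifications: list | pd.DataFrame,
    schedule,
    denominator: str = "all_saccades",
) -> pd.DataFrame:
    """Per-cell latency, direction-error, and anticipatory summaries.

    With multiple participants, latency and percentage measures are
    averaged subject-wise (mean +/- SEM across participants) while
    anticipatory direction preference uses weighted averages with the
    per-participant anticipatory counts as weights.
    """
    if denominator not in ("all_saccades", "regular_only"):
        raise ValueError("denominator must be 'all_saccades' or 'regular_only'")
    cls = (classification_table(classifications)
           if not isinstance(classifications, pd.DataFrame) else classifications)
    sched = schedule.trials if hasattr(schedule, "trials") else schedule
    df = cls.merge(sched, on="trial_id", how="left", validate="m:1",
                   suffixes=("", "_sched"))
    if df["trial_type"].isna().any():
        raise ValueError("classifications reference trials absent from the schedule")
    has_part = "participant" in df.columns
    units = df["participant"].unique() if has_part else [0]
    per_rows = []
    for unit in units:
        sub_u = df[df["participant"] == unit] if has_part else df
        base_lat = {}
        stats = {}
        for (cond, vb, tt), cell in sub_u.groupby(
            ["condition", "validity_block", "trial_type"], observed=True
        ):
            stats[(cond, vb, tt)] = _cell_stats(cell, denominator)
        for (cond, vb, tt), st in stats.items():
            base = stats.get((cond, vb, "neutral"), {}).get("mean_latency_ms", np.nan)
            lat = st["mean_latency_ms"]
            st = dict(st)
            st["latency_change_pct"] = (
                relative_change(lat, base)
                if tt != "neutral" and np.isfinite(lat) and np.isfinite(base) and base > 0
                else (0.0 if tt == "neutral" and np.isfinite(lat) else np.nan)
            )
            st.update(participant=unit, condition=cond, validity_block=vb,
                      trial_type=tt)
            per_rows.append(st)
    per = pd.DataFrame(per_rows)
    if not has_part:
        out = per.drop(columns="participant")
        out["pct_anticipatory_to_salient"] = np.where(
            out["n_anticipatory_nonneutral"] > 0,
            100.0 * out["n_anticipatory_to_salient"]
            / out["n_anticipatory_nonneutral"], np.nan)
        return out

    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g["n_anticipatory_nonneutral"].to_numpy(dtype=float)
        pref = (100.0 * g["n_anticipatory_to_salient"].sum() / w.sum()
                if w.sum() > 0 else np.nan)
        return pd.Series({
            "n_participants": len(g),
            "n_trials": g["n_trials"].sum(),
            "n_saccades": g["n_saccades"].sum(),
            "mean_latency_ms": g["mean_latency_ms"].mean(),
            "sem_latency_ms": g["mean_latency_ms"].sem(),
            "latency_change_pct": g["latency_change_pct"].mean(),
            "latency_change_sem": g["latency_change_pct"].sem(),
            "pct_direction_errors": g["pct_direction_errors"].mean(),
            "pct_anticipatory": g["pct_anticipatory"].mean(),
            "pct_anticipatory_to_salient": pref,
        })

    out = per.groupby(
        ["condition", "validity_block", "trial_type"], observed=True
    ).apply(_agg, include_groups=False).reset_index()
    out.attrs["per_participant"] = per
    return out


def check_fixation(trace: GazeTrace, fixation_radius_deg: float = 2.0,
                   fixation_point: tuple = (0.0, 0.0)) -> bool:
    """True iff gaze ever moves strictly further than the radius from fixation."""
    d = np.hypot(trace.x_deg - fixation_point[0], trace.y_deg - fixation_point[1])
    return bool(np.any(d > fixation_radius_deg))


def analyze_session(
    traces: list, schedule, v_thresh_deg_s: float = 30.0,
    a_thresh_deg_s2: float = 2000.0, cutoff_hz: float = 30.0,
) -> tuple[list, pd.DataFrame]:
    """Filter, detect, and classify every trace of a gaze session."""
    sched = schedule.trials if hasattr(schedule, "trials") else schedule
    by_id = {int(r.trial_id): r for r in sched.itertuples()}
    classifications = []
    for tr in traces:
        trial = by_id[int(tr.meta["trial_id"])]
        filt = lowpass_filter(tr, cutoff_hz=cutoff_hz)
        events = detect_saccades(filt, v_thresh_deg_s, a_thresh_deg_s2)
        classifications.append(classify_trial(events, trial))
    return classifications, classification_table(classifications)
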