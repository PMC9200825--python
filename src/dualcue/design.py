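"""Trial schedules for the dual-cue spatial-cueing (Posner-type) tasks.

Two tasks share the same cue geometry (two bilateral cues at 5 deg of
eccentricity, 150 ms SOA) and the same validity manipulation:

* covert task — orientation discrimination of a tilted Gabor at eight
  contrasts (constant stimuli).  Per session and condition: 112 neutral
  trials and 250 non-neutral trials, split 125 valid / 125 invalid in
  the 50%-validity session or 200 / 50 in the 80%-validity session.
  Two sessions x two conditions = 1448 trials per participant.
* gaze task — saccade to a peripheral target.  Per session and
  condition: 100 neutral and 250 non-neutral trials; 1400 in total.

Cue validity is the percentage of non-neutral trials whose salient cue
is on the target side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "SessionSchedule",
    "build_covert_schedule",
    "build_gaze_schedule",
    "build_covert_sessions",
    "build_gaze_sessions",
    "validity_of",
    "default_contrasts",
    "write_schedule",
    "read_schedule",
]

SOA_MS = 150.0
CUE_ECCENTRICITY_DEG = 5.0
CUE_DURATION_MS = 25.0  # not printed in the design; configurable metadata
TILTS_DEG = (-20.0, 20.0)

CONDITIONS = ("experimental", "control")
TRIAL_TYPES = ("neutral", "valid", "invalid")

COVERT_NEUTRAL_PER_SESSION_CONDITION = 112   # 224 per condition over 2 sessions
GAZE_NEUTRAL_PER_SESSION_CONDITION = 100
NONNEUTRAL_PER_SESSION_CONDITION = 250
VALIDITY_SPLITS = {50: (125, 125), 80: (200, 50)}  # (valid, invalid)

TRIAL_COLUMNS = [
    "trial_id", "task", "condition", "trial_type", "validity_block",
    "salient_side", "target_side", "contrast", "tilt_deg",
    "soa_ms", "cue_eccentricity_deg",
]


def default_contrasts(lo: float = 0.01, hi: float = 0.09, n: int = 8) -> np.ndarray:
    """Eight log-spaced Gabor contrasts spanning the tested range."""
    return np.geomspace(lo, hi, n)


@dataclass
class SessionSchedule:
    """One session's trial-by-trial design (seeded, reproducible)."""

    task: str
    validity_block: int
    seed: int
    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def counts(self) -> pd.DataFrame:
        return (
            self.trials.groupby(["condition", "trial_type"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )


def _balanced_pairs(n: int, values: tuple, rng: np.random.Generator) -> np.ndarray:
    """n draws from ``values`` with counts differing by at most 1."""
    k = len(values)
    reps = np.repeat(np.arange(k), n // k)
    extra = rng.choice(k, size=n % k, replace=False)
    idx = np.concatenate([reps, extra]).astype(int)
    rng.shuffle(idx)
    return np.asarray(values, dtype=object)[idx]


def _contrast_counts(n: int, n_levels: int, rng: np.random.Generator) -> np.ndarray:
    counts = np.full(n_levels, n // n_levels)
    counts[rng.choice(n_levels, size=n % n_levels, replace=False)] += 1
    return counts


def _cell_rows(
    task: str,
    condition: str,
    trial_type: str,
    validity_block: int,
    n: int,
    contrasts: np.ndarray | None,
    rng: np.random.Generator,
) -> list[dict]:
    rows: list[dict] = []
    if contrasts is None:
        groups = [(np.nan, n)]
    else:
        counts = _contrast_counts(n, len(contrasts), rng)
        groups = list(zip(contrasts, counts))
    for contrast, m in groups:
        m = int(m)
        sides = _balanced_pairs(m, ("left", "right"), rng)
        tilts = (
            _balanced_pairs(m, TILTS_DEG, rng)
            if task == "covert"
            else np.full(m, np.nan, dtype=object)
        )
        for side, tilt in zip(sides, tilts):
            if trial_type == "neutral":
                salient = "none"
            elif trial_type == "valid":
                salient = side
            else:
                salient = "left" if side == "right" else "right"
            rows.append(
                {
                    "task": task,
                    "condition": condition,
                    "trial_type": trial_type,
                    "validity_block": validity_block,
                    "salient_side": salient,
                    "target_side": side,
                    "contrast": contrast,
                    "tilt_deg": tilt,
                    "soa_ms": SOA_MS,
                    "cue_eccentricity_deg": CUE_ECCENTRICITY_DEG,
                }
            )
    return rows


def _build_session(
    task: str,
    validity_block: int,
    n_neutral: int,
    contrasts: np.ndarray | None,
    seed: int,
) -> SessionSchedule:
    if validity_block not in VALIDITY_SPLITS:
        raise ValueError("validity_block must be 50 or 80")
    rng = np.random.default_rng(seed)
    n_valid, n_invalid = VALIDITY_SPLITS[validity_block]
    rows: list[dict] = []
    for condition in CONDITIONS:
        for trial_type, n in (
            ("neutral", n_neutral),
            ("valid", n_valid),
            ("invalid", n_invalid),
        ):
            rows.extend(
                _cell_rows(task, condition, trial_type, validity_block, n,
                           contrasts, rng)
            )
    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_id", np.arange(len(df)))
    meta = {
        "task": task,
        "validity_block": validity_block,
        "seed": seed,
        "soa_ms": SOA_MS,
        "cue_eccentricity_deg": CUE_ECCENTRICITY_DEG,
        "cue_duration_ms": CUE_DURATION_MS,
    }
    if contrasts is not None:
        meta["contrasts"] = list(map(float, contrasts))
    return SessionSchedule(task, validity_block, seed, df, meta)


def build_covert_schedule(
    validity_block: int,
    contrasts: np.ndarray | list | None = None,
    seed: int = 0,
) -> SessionSchedule:
    """One covert-task session (both conditions, one validity block)."""
    if contrasts is None:
        contrasts = default_contrasts()
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.size != 8:
        raise ValueError("exactly 8 contrast levels are required")
    if np.any(np.diff(contrasts) <= 0):
        raise ValueError("contrasts must be strictly increasing")
    if np.any((contrasts <= 0) | (contrasts >= 1)):
        raise ValueError("contrasts must lie in (0, 1)")
    return _build_session(
        "covert", validity_block, COVERT_NEUTRAL_PER_SESSION_CONDITION,
        contrasts, seed,
    )


def build_gaze_schedule(validity_block: int, seed: int = 0) -> SessionSchedule:
    """One gaze-task session (both conditions, one validity block)."""
    return _build_session(
        "gaze", validity_block, GAZE_NEUTRAL_PER_SESSION_CONDITION, None, seed
    )


def _both_sessions(builder, seed: int, **kwargs) -> pd.DataFrame:
    frames = []
    for i, block in enumerate((50, 80)):
        sched = builder(block, seed=seed + i, **kwargs)
        df = sched.trials.copy()
        df.insert(1, "session", i + 1)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["trial_id"] = np.arange(len(out))
    return out


def build_covert_sessions(seed: int = 0, contrasts=None) -> pd.DataFrame:
    """Both covert sessions (50% and 80% validity); 1448 trials."""
    return _both_sessions(build_covert_schedule, seed, contrasts=contrasts)


def build_gaze_sessions(seed: int = 0) -> pd.DataFrame:
    """Both gaze sessions (50% and 80% validity); 1400 trials."""
    return _both_sessions(build_gaze_schedule, seed)


def validity_of(schedule: SessionSchedule | pd.DataFrame) -> float:
    """Percentage of non-neutral trials with the salient cue on the target side."""
    df = schedule.trials if isinstance(schedule, SessionSchedule) else schedule
    nn = df[df["trial_type"] != "neutral"]
    if len(nn) == 0:
        raise ValueError("schedule has no non-neutral trials")
    return 100.0 * (nn["trial_type"] == "valid").sum() / len(nn)


def write_schedule(schedule: SessionSchedule, path: str | Path) -> None:
    """CSV of trials plus a JSON sidecar with seed, counts, and config."""
    path = Path(path)
    schedule.trials.to_csv(path, index=False)
    sidecar = dict(schedule.meta)
    sidecar["counts"] = {
        f"{r.condition}/{r.trial_type}": int(r.n)
        for r in schedule.counts.itertuples()
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_schedule(path: str | Path) -> SessionSchedule:
    path = Path(path)
    trials = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SessionSchedule(
        task=meta.get("task", trials["task"].iloc[0]),
        validity_block=int(meta.get("validity_block",
                                    trials["validity_block"].iloc[0])),
        seed=int(meta.get("seed", -1)),
        trials=trials,
        meta=meta,
    )
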