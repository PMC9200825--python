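"""Maximum-likelihood psychometric fits and contrast thresholds.

Percent-correct data from the covert 2AFC task are fitted with a
cumulative-Gaussian psychometric function

    Psi(c) = guess + (1 - guess - lapse) * Phi((c - mu) / sigma)

by maximising the binomial log-likelihood over (mu, sigma) on linear
contrast.  The contrast threshold is the level yielding a criterion
proportion correct (default 0.80); cueing effects are expressed as the
percentage change of valid/invalid thresholds relative to the neutral
baseline of the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .observer import psychometric_p

__all__ = [
    "PsychFit",
    "fit_psychometric",
    "threshold_at",
    "relative_change",
    "covert_summary",
    "plot_psychometric_cell",
]

_EPS = 1e-10


@dataclass(frozen=True)
class PsychFit:
    mu: float
    sigma: float
    guess: float
    lapse: float
    loglik: float
    converged: bool
    n_trials: int
    message: str = ""

    def predict(self, contrast):
        return psychometric_p(contrast, self.mu, self.sigma, self.guess, self.lapse)


def _nll(params: np.ndarray, levels, k, n, guess, lapse) -> float:
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    psi = guess + (1 - guess - lapse) * ndtr((levels - mu) / sigma)
    psi = np.clip(psi, _EPS, 1 - _EPS)
    return -float(np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi)))


def fit_psychometric(
    levels,
    k_correct,
    n_total,
    guess: float = 0.5,
    lapse: float = 0.0,
) -> PsychFit:
    """Binomial MLE of (mu, sigma) with a coarse-grid multi-start.

    Returns ``converged=False`` (with the best-effort parameters) when
    the data are unidentifiable: performance at ceiling or at chance at
    every level, where the likelihood is flat in mu or sigma.
    """
    levels = np.asarray(levels, dtype=float)
    k = np.asarray(k_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if not (levels.shape == k.shape == n.shape):
        raise ValueError("levels, k_correct, n_total must have equal length")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct stimulus levels")
    if not np.all(np.isfinite(levels)):
        raise ValueError("levels must be finite")
    if np.any(k < 0) or np.any(k > n) or np.any(n <= 0):
        raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    if n.sum() < 20:
        raise ValueError("need at least 20 trials in total")

    prop = k / n
    span = levels.max() - levels.min()
    ceiling = 1 - guess - lapse
    # degenerate data: no information about mu (all ceiling / all chance)
    hi = prop > guess + 0.75 * ceiling
    lo = prop < guess + 0.25 * ceiling
    degenerate = hi.all() or lo.all()

    mu_grid = np.linspace(levels.min() - 0.25 * span, levels.max() + 0.25 * span, 7)
    sig_grid = np.log(np.geomspace(span / 40, 2 * span, 7))
    grid_m, grid_s = np.meshgrid(mu_grid, sig_grid)
    starts = np.column_stack([grid_m.ravel(), grid_s.ravel()])
    scores = np.array([_nll(s, levels, k, n, guess, lapse) for s in starts])
    best = None
    for s in starts[np.argsort(scores)[:3]]:
        res = minimize(_nll, s, args=(levels, k, n, guess, lapse),
                       method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    converged = bool(best.success) and not degenerate and sigma > 0
    msg = "degenerate: performance at ceiling or chance at all levels" \
        if degenerate else best.message
    return PsychFit(float(mu), sigma, guess, lapse, -float(best.fun),
                    converged, int(n.sum()), msg)


def threshold_at(fit: PsychFit, criterion: float = 0.80) -> float:
    """Contrast at which the fitted curve predicts ``criterion`` correct.

    threshold = mu + sigma * Phi^-1((criterion - guess)/(1 - guess - lapse))
    """
    if not fit.converged:
        raise ValueError("cannot take a threshold from a non-converged fit")
    attain_lo, attain_hi = fit.guess, 1 - fit.lapse
    if not attain_lo < criterion < attain_hi:
        raise ValueError(
            f"criterion {criterion} outside attainable range "
            f"({attain_lo}, {attain_hi})"
        )
    q = (criterion - fit.guess) / (1 - fit.guess - fit.lapse)
    return float(fit.mu + fit.sigma * ndtri(q))


def relative_change(value: float, baseline: float) -> float:
    """Percentage change of ``value`` relative to a positive baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (value - baseline) / baseline


def _fit_cell(cell: pd.DataFrame, guess: float, lapse: float) -> PsychFit:
    agg = cell.groupby("contrast")["correct"].agg(["sum", "count"])
    return fit_psychometric(agg.index.to_numpy(), agg["sum"].to_numpy(),
                            agg["count"].to_numpy(), guess, lapse)


def covert_summary(
    responses: pd.DataFrame,
    schedule,
    criterion: float = 0.80,
    guess: float = 0.5,
    lapse: float = 0.0,
    max_extrapolation: float = 3.0,
) -> pd.DataFrame:
    """Thresholds and baseline-relative changes per design cell.

    Cells are (condition x validity_block x trial_type); with a
    ``participant`` column present, fits are per participant per cell
    and the summary reports the mean threshold and the mean of
    per-participant relative changes (subject-wise averaging).
    Cells whose fitted threshold exceeds ``max_extrapolation`` times the
    largest tested contrast, or whose fit did not converge, are
    reported as missing.
    """
    sched = schedule.trials if hasattr(schedule, "trials") else schedule
    df = responses.merge(sched, on="trial_id", how="left", validate="m:1",
                         suffixes=("", "_sched"))
    if df["trial_type"].isna().any():
        orphans = responses.loc[df["trial_type"].isna(), "trial_id"].tolist()
        raise ValueError(f"responses reference unknown trials: {orphans[:10]}")
    has_part = "participant" in df.columns
    units = df["participant"].unique() if has_part else [0]
    rows = []
    for unit in units:
        sub = df[df["participant"] == unit] if has_part else df
        cmax = sub["contrast"].max()
        thr = {}
        for (cond, vb, tt), cell in sub.groupby(
            ["condition", "validity_block", "trial_type"], observed=True
        ):
            fit = _fit_cell(cell, guess, lapse)
            t = np.nan
            if fit.converged:
                t = threshold_at(fit, criterion)
                if t > max_extrapolation * cmax or t <= 0:
                    t = np.nan
            thr[(cond, vb, tt)] = (t, fit, len(cell))
        for (cond, vb, tt), (t, fit, n) in thr.items():
            base = thr.get((cond, vb, "neutral"), (np.nan,))[0]
            change = (
                relative_change(t, base)
                if tt != "neutral" and np.isfinite(t) and np.isfinite(base) and base > 0
                else (0.0 if tt == "neutral" and np.isfinite(t) else np.nan)
            )
            rows.append({
                "participant": unit, "condition": cond, "validity_block": vb,
                "trial_type": tt, "n_trials": n, "mu": fit.mu,
                "sigma": fit.sigma, "converged": fit.converged,
                "threshold": t, "relative_change_pct": change,
            })
    per = pd.DataFrame(rows)
    if not has_part:
        return per.drop(columns="participant")
    out = (
        per.groupby(["condition", "validity_block", "trial_type"], observed=True)
        .agg(n_participants=("participant", "nunique"),
             n_trials=("n_trials", "sum"),
             threshold=("threshold", "mean"),
             threshold_sem=("threshold", "sem"),
             relative_change_pct=("relative_change_pct", "mean"),
             relative_change_sem=("relative_change_pct", "sem"))
        .reset_index()
    )
    out.attrs["per_participant"] = per
    return out


def plot_psychometric_cell(levels, k_correct, n_total, fit: PsychFit,
                           criterion: float = 0.80, ax=None, label: str = ""):
    """Diagnostic plot: observed proportions, fitted curve, and threshold."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    levels = np.asarray(levels, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(levels, np.asarray(k_correct) / np.asarray(n_total), "o", label=label)
    grid = np.linspace(levels.min() * 0.8, levels.max() * 1.1, 200)
    ax.plot(grid, fit.predict(grid), "-")
    if fit.converged:
        thr = threshold_at(fit, criterion)
        ax.axvline(thr, ls="--", lw=0.8)
        ax.axhline(criterion, ls=":", lw=0.8)
    ax.set_xlabel("contrast")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.4, 1.02)
    return ax
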