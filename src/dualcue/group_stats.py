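"""Group-level statistics for within-subject factorial summaries.

* :func:`rm_factorial_anova` — repeated-measures factorial ANOVA via the
  classical sums-of-squares partition (each effect tested against its
  own effect-by-subject interaction); eta-squared is SS_effect/SS_total.
* :func:`paired_bonferroni` — paired t-tests with Bonferroni correction.
* :func:`friedman_conover` — Friedman rank test (suitable for
  binomially distributed error proportions) with Kendall's W and
  Conover post-hoc pairwise comparisons.
* :func:`two_proportion_z` — pooled-variance z test for two proportions,
  justified by large per-cell counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rm_factorial_anova",
    "paired_bonferroni",
    "friedman_conover",
    "two_proportion_z",
    "FriedmanResult",
]


def _ss_means(df: pd.DataFrame, dv: str, cols: list[str], n_obs: int) -> float:
    """sum over groups of (group total)^2 / group size; T(empty) = G^2/N."""
    if not cols:
        return float(df[dv].sum() ** 2 / n_obs)
    g = df.groupby(cols, observed=True)[dv]
    return float((g.sum() ** 2 / g.size()).sum())


def rm_factorial_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """Fully-crossed within-subject factorial ANOVA.

    Requires a complete balanced design (one observation per subject per
    cell); subjects with missing cells are dropped listwise.  Returns a
    table of (effect, SS, df1, df2, F, p, eta_squared) where each
    effect's error term is its interaction with subjects and
    eta_squared = SS_effect / SS_total (classical).
    """
    df = data[[subject, dv, *within]].dropna().copy()
    cells = df.groupby(within, observed=True).ngroups
    per_subj = df.groupby(subject, observed=True).size()
    complete = per_subj[per_subj == cells].index
    dropped = sorted(set(per_subj.index) - set(complete))
    df = df[df[subject].isin(complete)]
    n_subj = df[subject].nunique()
    if n_subj < 3:
        raise ValueError("need at least 3 participants with complete designs")
    counts = df.groupby([subject, *within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise ValueError(f"design not complete/balanced; offending cells: {bad}")

    n_obs = len(df)
    levels = {f: df[f].nunique() for f in within}
    grand_ss = float((df[dv] ** 2).sum())
    t_empty = _ss_means(df, dv, [], n_obs)
    ss_total = grand_ss - t_empty

    def t_of(cols: tuple) -> float:
        return _ss_means(df, dv, list(cols), n_obs)

    rows = []
    for r in range(1, len(within) + 1):
        for effect in itertools.combinations(within, r):
            ss_e = 0.0
            ss_err = 0.0
            for k in range(r + 1):
                for sub in itertools.combinations(effect, k):
                    sign = (-1) ** (r - k)
                    ss_e += sign * t_of(sub)
                    ss_err += sign * (t_of((*sub, subject)) - t_of(sub))
            df1 = int(np.prod([levels[f] - 1 for f in effect]))
            df2 = df1 * (n_subj - 1)
            ms_e, ms_err = ss_e / df1, ss_err / df2
            if ms_err <= 1e-300:
                f_stat, p = np.nan, np.nan
                note = "zero error variance"
            else:
                f_stat = ms_e / ms_err
                p = float(stats.f.sf(f_stat, df1, df2))
                note = ""
            rows.append({
                "effect": " * ".join(effect), "SS": ss_e, "SS_error": ss_err,
                "df1": df1, "df2": df2, "F": f_stat, "p": p,
                "eta_squared": ss_e / ss_total if ss_total > 0 else np.nan,
                "note": note,
            })
    out = pd.DataFrame(rows)
    out.attrs["SS_total"] = ss_total
    out.attrs["n_participants"] = n_subj
    out.attrs["dropped_participants"] = dropped
    # subject main effect completes the partition:
    out.attrs["SS_subject"] = t_of((subject,)) - t_empty
    return out


def paired_bonferroni(
    data: pd.DataFrame | dict,
    comparisons: list[tuple],
    dv: str | None = None,
    cell: str | None = None,
    subject: str = "participant",
) -> pd.DataFrame:
    """Paired t-tests with Bonferroni-corrected p values.

    ``data`` is either a mapping of cell name -> paired vector, or a
    long DataFrame with ``dv``, ``cell``, and ``subject`` columns.
    Zero-variance nonzero differences are flagged degenerate (infinite
    t); identical vectors give t = 0, p = 1.
    """
    if isinstance(data, pd.DataFrame):
        wide = data.pivot_table(index=subject, columns=cell, values=dv)
        vectors = {c: wide[c].to_numpy() for c in wide.columns}
    else:
        vectors = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        x, y = vectors[a], vectors[b]
        ok = np.isfinite(x) & np.isfinite(y)
        d = x[ok] - y[ok]
        n = d.size
        if n < 3:
            raise ValueError(f"comparison {a} vs {b}: fewer than 3 pairs")
        sd = d.std(ddof=1)
        degenerate = False
        if sd == 0:
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p, degenerate = np.inf * np.sign(d.mean()), 0.0, True
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), n - 1)
        rows.append({"pair": f"{a} vs {b}", "t": t, "df": n - 1,
                     "p_uncorrected": p, "p_corrected": min(1.0, p * m),
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    kendall_w: float
    posthoc: pd.DataFrame
    n_uninformative_rows: int


def friedman_conover(data: pd.DataFrame | np.ndarray,
                     bonferroni: bool = True) -> FriedmanResult:
    """Friedman rank test with Kendall's W and Conover post-hoc tests.

    ``data`` is participants x conditions.  Ties within a participant
    get midranks; all-tied rows carry no rank information and are
    counted in ``n_uninformative_rows``.  Kendall's W = chi2 / (n(k-1)).
    Conover's pairwise statistic compares column rank sums with the
    tie-corrected variance and df = (n-1)(k-1).
    """
    arr = np.asarray(data, dtype=float)
    names = (list(data.columns) if isinstance(data, pd.DataFrame)
             else [f"c{i}" for i in range(arr.shape[1])])
    n, k = arr.shape
    if n < 3 or k < 3:
        raise ValueError("need at least 3 participants and 3 conditions")
    chi2, p = stats.friedmanchisquare(*(arr[:, j] for j in range(k)))
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    uninformative = int(np.sum(np.ptp(arr, axis=1) == 0))
    w = float(chi2 / (n * (k - 1)))
    rank_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    b1 = float((rank_sums**2).sum() / n)
    dof = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (1.0 - chi2 / (n * (k - 1))) * (a1 - b1) / dof
    denom = np.sqrt(max(denom_sq, 0.0))
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        if denom == 0:
            t = np.inf * np.sign(rank_sums[i] - rank_sums[j]) \
                if rank_sums[i] != rank_sums[j] else 0.0
            pp = 0.0 if np.isinf(t) else 1.0
        else:
            t = (rank_sums[i] - rank_sums[j]) / denom
            pp = 2 * stats.t.sf(abs(t), dof)
        rows.append({"pair": f"{names[i]} vs {names[j]}", "t": t, "df": dof,
                     "p_uncorrected": pp,
                     "p_corrected": min(1.0, pp * m) if bonferroni else pp})
    return FriedmanResult(float(chi2), k - 1, float(p), w,
                          pd.DataFrame(rows), uninformative)


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pooled-variance z test for the difference of two proportions."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if min(n1, n2) < 30:
        warnings.warn("fewer than 30 observations per group; the normal "
                      "approximation may be poor", stacklevel=2)
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "larger":
        p = stats.norm.sf(z)
    elif alternative == "smaller":
        p = stats.norm.cdf(z)
    else:
        raise ValueError("alternative must be two-sided, larger, or smaller")
    return float(z), float(p)
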