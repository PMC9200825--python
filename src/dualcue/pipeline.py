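"""End-to-end orchestration of the synthetic dual-cue experiment.

features -> design -> simulate -> analyze -> stats -> report, driven by
a single serialisable :class:`RunConfig`.  Per-participant and per-stage
randomness derives from the root seed through a documented counter
scheme (``SeedSequence([seed, participant_index, stage_code])``), so a
cohort is reproducible from its config alone and can be extended with
more participants without disturbing existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design, features, group_stats, observer, oculomotor, psychometrics

__all__ = ["RunConfig", "run_end_to_end", "recovery_report", "simulate_cohort"]

_STAGE = {"covert": 1, "gaze": 2}


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 16
    observer: dict = field(default_factory=dict)
    gaze: dict = field(default_factory=dict)
    feature_model: dict = field(default_factory=lambda: {
        "n_images": 8, "image_size": 256, "N": 50, "W": 0.05,
        "patch_side": 3, "cell_px": 3})
    analysis: dict = field(default_factory=lambda: {
        "criterion": 0.8, "v_thresh_deg_s": 30.0, "a_thresh_deg_s2": 2000.0})
    tasks: tuple = ("covert", "gaze")
    out_dir: str = "dualcue_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["tasks"] = list(d["tasks"])
        Path(path).write_text(yaml.safe_dump(d))


def _participant_seed(root: int, participant: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([root, participant, _STAGE[stage]])


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _covert_participant(config: RunConfig, p_idx: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    ss = _participant_seed(config.seed, p_idx, "covert")
    sched = design.build_covert_sessions(seed=_seed_int(ss))
    params = observer.ObserverParams(**{**config.observer,
                                        "seed": _seed_int(ss.spawn(1)[0])})
    resp = observer.simulate_covert(sched, params)
    sched = sched.assign(participant=p_idx)
    resp = resp.assign(participant=p_idx)
    return sched, resp


def _gaze_participant(config: RunConfig, p_idx: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    ss = _participant_seed(config.seed, p_idx, "gaze")
    sched = design.build_gaze_sessions(seed=_seed_int(ss))
    params = observer.GazeSimParams(**{**config.gaze,
                                       "seed": _seed_int(ss.spawn(1)[0])})
    traces = observer.simulate_gaze_session(sched, params)
    _, cls = oculomotor.analyze_session(
        traces, sched,
        v_thresh_deg_s=config.analysis.get("v_thresh_deg_s", 30.0),
        a_thresh_deg_s2=config.analysis.get("a_thresh_deg_s2", 2000.0),
    )
    sched = sched.assign(participant=p_idx)
    cls = cls.assign(participant=p_idx)
    return sched, cls


def simulate_cohort(config: RunConfig) -> dict:
    """Simulate and analyze a whole cohort in memory."""
    out: dict = {}
    if "covert" in config.tasks:
        scheds, resps = zip(*(_covert_participant(config, i)
                              for i in range(config.n_participants)))
        sched = pd.concat(scheds, ignore_index=False)
        resp = pd.concat(resps, ignore_index=True)
        out["covert_schedule"] = sched
        out["covert_responses"] = resp
        out["covert_summary"] = psychometrics.covert_summary(
            _rekey(resp), _with_participant_join(sched),
            criterion=config.analysis.get("criterion", 0.8))
    if "gaze" in config.tasks:
        scheds, clss = zip(*(_gaze_participant(config, i)
                             for i in range(config.n_participants)))
        sched = pd.concat(scheds, ignore_index=False)
        cls = pd.concat(clss, ignore_index=True)
        out["gaze_schedule"] = sched
        out["gaze_classifications"] = cls
        out["gaze_summary"] = oculomotor.summarize_gaze(
            _rekey(cls), _with_participant_join(sched))
    return out


def _with_participant_join(sched: pd.DataFrame) -> pd.DataFrame:
    # trial_id is only unique within participant; build a unique key
    df = sched.copy()
    df["trial_id"] = df["participant"].astype(np.int64) * 10**6 + df["trial_id"]
    return df


def _rekey(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    t["trial_id"] = t["participant"].astype(np.int64) * 10**6 + t["trial_id"]
    return t


def _feature_stage(config: RunConfig, out: Path) -> dict:
    fm = config.feature_model
    imgs = features.synthetic_natural_images(
        fm.get("n_images", 8), fm.get("image_size", 256),
        seed=_seed_int(np.random.SeedSequence([config.seed, 0, 0])))
    binimgs = [features.binarize_image(im) for im in imgs]
    dist = features.estimate_patch_distribution(binimgs, fm.get("patch_side", 3))
    opt = features.select_optimal_features(dist, fm.get("N", 50), fm.get("W", 0.05))
    non = features.select_nonoptimal_features(dist, fm.get("N", 50))
    bal = features.check_luminance_balance(opt, non)
    dist.to_json(out / "patch_distribution.json")
    opt.to_json(out / "optimal_features.json")
    non.to_json(out / "nonoptimal_features.json")
    features.write_cue_set(opt, out / "cues_optimal", fm.get("cell_px", 3))
    features.write_cue_set(non, out / "cues_nonoptimal", fm.get("cell_px", 3))
    return {
        "n_optimal": len(opt), "n_nonoptimal": len(non),
        "optimal_entropy_bits": opt.achieved_entropy,
        "luminance_difference_cd_m2": bal.difference_cd_m2,
        "luminance_balanced": bool(bal.balanced),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_stats_stage(cohort: dict) -> dict:
    res: dict = {}
    cov = cohort.get("covert_summary")
    if cov is not None and "per_participant" in cov.attrs:
        per = cov.attrs["per_participant"]
        try:
            res["covert_anova"] = group_stats.rm_factorial_anova(
                per, "threshold", ["condition", "trial_type", "validity_block"])
        except ValueError as err:
            res["covert_anova_skipped"] = str(err)
    gz = cohort.get("gaze_summary")
    if gz is not None and "per_participant" in gz.attrs:
        per = gz.attrs["per_participant"]
        try:
            res["gaze_anova"] = group_stats.rm_factorial_anova(
                per, "mean_latency_ms",
                ["condition", "trial_type", "validity_block"])
            err_wide = per.pivot_table(index="participant",
                                       columns="trial_type",
                                       values="pct_direction_errors")
            res["errors_friedman"] = group_stats.friedman_conover(
                err_wide[["neutral", "valid", "invalid"]])
        except ValueError as err:
            res["gaze_anova_skipped"] = str(err)
        # anticipatory rate: neutral vs non-neutral, pooled over participants
        agg = per.groupby(per["trial_type"] == "neutral").agg(
            k=("n_anticipatory", "sum"), n=("n_saccades", "sum"))
        if set(agg.index) == {True, False} and (agg["n"] > 0).all():
            z, p = group_stats.two_proportion_z(
                int(agg.loc[False, "k"]), int(agg.loc[False, "n"]),
                int(agg.loc[True, "k"]), int(agg.loc[True, "n"]))
            res["anticipatory_two_proportion"] = {"z": z, "p": p}
    return res


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full synthetic experiment; returns a manifest of outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "n_participants": config.n_participants, "stages": {}}
    manifest["stages"]["features"] = _feature_stage(config, out)
    cohort = simulate_cohort(config)
    files = {}
    if "covert" in config.tasks:
        cohort["covert_schedule"].to_csv(out / "covert_schedule.csv", index=False)
        cohort["covert_responses"].to_csv(out / "covert_responses.csv", index=False)
        cohort["covert_summary"].to_csv(out / "covert_results.csv", index=False)
        files["covert_results"] = "covert_results.csv"
        manifest["stages"]["covert"] = {
            "n_trials": int(len(cohort["covert_schedule"])),
            "n_cells": int(len(cohort["covert_summary"])),
        }
    if "gaze" in config.tasks:
        cohort["gaze_schedule"].to_csv(out / "gaze_schedule.csv", index=False)
        cohort["gaze_classifications"].to_csv(out / "gaze_events.csv", index=False)
        cohort["gaze_summary"].to_csv(out / "gaze_results.csv", index=False)
        files["gaze_results"] = "gaze_results.csv"
        manifest["stages"]["gaze"] = {
            "n_trials": int(len(cohort["gaze_schedule"])),
            "n_cells": int(len(cohort["gaze_summary"])),
        }
    stats_res = _group_stats_stage(cohort)
    stats_txt = []
    for name, val in stats_res.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"stats_{name}.csv", index=False)
            files[name] = f"stats_{name}.csv"
        elif isinstance(val, group_stats.FriedmanResult):
            stats_txt.append(f"{name}: chi2={val.chi2:.3f} df={val.df} "
                             f"p={val.p:.4g} W={val.kendall_w:.3f}")
            val.posthoc.to_csv(out / f"stats_{name}_posthoc.csv", index=False)
        else:
            stats_txt.append(f"{name}: {val}")
    (out / "stats_report.txt").write_text("\n".join(stats_txt) + "\n")
    manifest["checksums"] = {k: _sha256(out / v) for k, v in files.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def recovery_report(config: RunConfig, n_replicates: int = 10) -> pd.DataFrame:
    """Replicate small cohorts and report recovery of the generating effects.

    Recovered quantities: covert effect_valid / effect_invalid (from
    mean relative threshold changes), gaze latency effects, direction
    error and anticipatory probabilities, and the anticipatory salient-
    side preference.  Reports true value, recovered mean, bias, RMSE.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    obs = observer.ObserverParams(**config.observer)
    gz = observer.GazeSimParams(**config.gaze)
    rec: dict[str, list] = {k: [] for k in (
        "covert_effect_valid", "covert_effect_invalid",
        "gaze_effect_valid", "gaze_effect_invalid",
        "p_error_invalid", "p_anticipatory_nonneutral",
        "p_anticipatory_to_salient")}
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + 1000 * (r + 1))
        cohort = simulate_cohort(cfg)
        if "covert_summary" in cohort:
            cs = cohort["covert_summary"]
            for tt, key in (("valid", "covert_effect_valid"),
                            ("invalid", "covert_effect_invalid")):
                v = cs.loc[cs["trial_type"] == tt, "relative_change_pct"].mean()
                rec[key].append(v / 100.0)
        if "gaze_summary" in cohort:
            gs = cohort["gaze_summary"]
            for tt, key in (("valid", "gaze_effect_valid"),
                            ("invalid", "gaze_effect_invalid")):
                v = gs.loc[gs["trial_type"] == tt, "latency_change_pct"].mean()
                rec[key].append(v / 100.0)
            per = gs.attrs.get("per_participant", gs)
            inv = per[per["trial_type"] == "invalid"]
            rec["p_error_invalid"].append(
                inv["n_erroneous"].sum() / max(inv["n_regular"].sum(), 1))
            nn = per[per["trial_type"] != "neutral"]
            rec["p_anticipatory_nonneutral"].append(
                nn["n_anticipatory"].sum() / max(nn["n_trials"].sum(), 1))
            n_sal = nn["n_anticipatory_to_salient"].sum()
            n_all = nn["n_anticipatory_nonneutral"].sum()
            if n_all > 0:
                rec["p_anticipatory_to_salient"].append(n_sal / n_all)
    truth = {
        "covert_effect_valid": obs.effect_valid,
        "covert_effect_invalid": obs.effect_invalid,
        "gaze_effect_valid": gz.effect_valid,
        "gaze_effect_invalid": gz.effect_invalid,
        "p_error_invalid": gz.p_error["invalid"],
        "p_anticipatory_nonneutral": gz.p_anticipatory["valid"],
        "p_anticipatory_to_salient": gz.p_anticipatory_to_salient,
    }
    rows = []
    for key, vals in rec.items():
        if not vals:
            continue
        vals = np.asarray(vals, dtype=float)
        rows.append({
            "parameter": key, "true": truth[key],
            "recovered_mean": vals.mean(),
            "bias": vals.mean() - truth[key],
            "rmse": float(np.sqrt(np.mean((vals - truth[key]) ** 2))),
            "n_replicates": vals.size,
        })
    return pd.DataFrame(rows)
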