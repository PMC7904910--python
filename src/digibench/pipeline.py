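"""End-to-end orchestration of the validation pipeline.

``run_pipeline`` executes the full chain — simulate (or load) → score →
outlier-adjust → agreement → reliability → learning detection → minimum
test time → criterion model → decline thresholds → group comparison —
writing every stage artifact plus a manifest (YAML) that echoes the
effective parameters and per-stage seeds, so any number in any report is
reproducible from the manifest and inputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from digibench import agreement as agr
from digibench import changepoint as cpt
from digibench import model as mdl
from digibench import reliability as rel
from digibench import scoring
from digibench import simulate as sim
from digibench import thresholds as thr

log = logging.getLogger("digibench")

#: conservative significance threshold applied uniformly
SIGNIFICANCE_LEVEL = 0.01

_STAGES = ("simulate", "score", "agreement", "reliability", "learning",
           "mintime", "model", "thresholds")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    seed: int = 0
    preset: str = "paper-like"        # or "custom" with input paths
    trials_path: str | None = None
    profiles_path: str | None = None
    cutoff_s: float = 75.0
    sitting_policy: str = "mean"      # {"trial1", "trial2", "mean"}
    ba_method: str = "mixed"          # {"simple", "mixed"}
    covariate_set: str = "taps"       # {"taps", "neurex", "none"}
    threshold_method: str = "iqr1.5"
    k_max: int = 4
    out_dir: str = "pipeline_out"
    n_hv: int = 39
    n_ms: int = 154
    n_longitudinal: int = 16
    n_sittings: int = 25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single global seed out to independent per-stage seeds."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {s: int(c.generate_state(1)[0] % (2 ** 31))
            for s, c in zip(_STAGES, children)}


def group_compare(x, y, alpha: float = 0.05) -> dict:
    """Two-group comparison by the Wilcoxon rank-sum test with a
    Hodges-Lehmann location-shift estimate and confidence interval.

    The test is exact for small samples without ties, asymptotic
    otherwise; the CI comes from the standard rank-based construction
    on the sorted pairwise differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m < 3 or n < 3:
        raise ValueError("group_compare needs >= 3 per group")
    method = ("exact" if m <= 25 and n <= 25
              and np.unique(np.concatenate([x, y])).size == m + n
              else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)

    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    z = stats.norm.ppf(1 - alpha / 2)
    c = m * n / 2 - z * np.sqrt(m * n * (m + n + 1) / 12.0)
    k = int(np.floor(c))
    k = max(k, 0)
    lo = float(diffs[k]) if k < diffs.size else float(diffs[0])
    hi = float(diffs[m * n - k - 1])
    return {
        "p_value": float(res.pvalue), "u_statistic": float(res.statistic),
        "median_x": float(np.median(x)), "median_y": float(np.median(y)),
        "hl_shift": hl, "ci_low": lo, "ci_high": hi,
        "n_x": m, "n_y": n, "method": method,
        "significant": bool(res.pvalue < SIGNIFICANCE_LEVEL),
    }


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, default=_json_default,
                               allow_nan=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the result dictionary and writes
    stage artifacts + ``manifest.yaml`` under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    results: dict = {}
    handler = logging.StreamHandler(sys.stderr)
    if not log.handlers:
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    def stage(name):
        log.info("stage=%s event=start", name)

    try:
        # ------------------------------------------------ simulate / load
        stage("simulate")
        if config.preset == "paper-like":
            profiles = sim.generate_cross_sectional(sim.CohortParams(
                n_hv=config.n_hv, n_ms=config.n_ms,
                seed=seeds["simulate"]))
            trials_long = sim.generate_longitudinal(sim.LearningCurveParams(
                n_subjects=config.n_longitudinal,
                n_sittings=config.n_sittings,
                seed=seeds["simulate"] + 1))
            stream_trials = sim.generate_stream_cohort(
                n_subjects=22, seed=seeds["simulate"] + 2)
        else:
            if not config.trials_path or not config.profiles_path:
                raise ValueError(
                    "custom preset needs trials_path and profiles_path")
            trials_long = scoring.read_trials(config.trials_path)
            profiles = scoring.read_profiles(config.profiles_path)
            stream_trials = None
        scoring.write_profiles(profiles, out / "profiles.csv")
        scoring.write_trials(trials_long, out / "trials.csv")

        # ------------------------------------------------ score
        stage("score")
        scores = scoring.sitting_scores(trials_long,
                                        policy=config.sitting_policy)
        pair = scoring.sitting_scores(trials_long, policy="trial1").merge(
            scoring.sitting_scores(trials_long, policy="trial2"),
            on=["subject_id", "cohort", "sitting"],
            suffixes=("_t1", "_t2"))
        pair = pair.rename(columns={"score_90s_t1": "trial1_score",
                                    "score_90s_t2": "trial2_score"})

        # ------------------------------------------------ agreement
        stage("agreement")
        ba_pairs = pair.rename(columns={"trial1_score": "x",
                                        "trial2_score": "y"})
        if config.ba_method == "mixed":
            trial_ba = agr.mixed_effects_bland_altman(ba_pairs)
        else:
            trial_ba = agr.bland_altman(ba_pairs["x"], ba_pairs["y"])
        adjusted = agr.adjust_outlier_trials(pair, trial_ba)
        adjusted["score_90s"] = adjusted[
            ["trial1_score", "trial2_score"]].mean(axis=1)
        log.info("stage=agreement event=outliers n=%d",
                 int(adjusted["outlier"].sum()))

        written_ba = agr.bland_altman(profiles["written_sdmt"],
                                      profiles["app_sdmt"])
        ccc_raw = agr.lin_ccc(profiles["written_sdmt"],
                              profiles["app_sdmt"])
        corrected = scoring.apply_bias_correction(
            profiles["app_sdmt"].to_numpy(), written_ba.bias)
        ccc_corrected = agr.lin_ccc(profiles["written_sdmt"], corrected)
        results["agreement"] = {
            "trial_ba": trial_ba, "written_ba": written_ba,
            "ccc_raw": ccc_raw, "ccc_corrected": ccc_corrected,
            "n_outlier_sittings": int(adjusted["outlier"].sum()),
        }
        _write_json(results["agreement"], out / "agreement.json")

        # ------------------------------------------------ learning
        stage("learning")
        learning = {}
        for sid, grp in adjusted.groupby("subject_id"):
            res = cpt.detect_learning_end(grp["sitting"], grp["score_90s"])
            learning[sid] = res
        n_found = sum(r.identified for r in learning.values())
        found_sittings = [r.sitting for r in learning.values()
                          if r.identified]
        results["learning"] = {
            "n_subjects": len(learning), "n_identified": n_found,
            "mean_end_sitting": (float(np.mean(found_sittings))
                                 if found_sittings else None),
            "per_subject": {s: {"identified": r.identified,
                                "sitting": r.sitting, "reason": r.reason}
                            for s, r in learning.items()},
        }
        _write_json(results["learning"], out / "learning.json")

        # ------------------------------------------------ reliability
        stage("reliability")
        icc_all = rel.icc_mixed(adjusted)
        post_rows = []
        for sid, grp in adjusted.groupby("subject_id"):
            res = learning[sid]
            cut = res.sitting if res.identified else None
            if cut is not None:
                post_rows.append(grp[grp["sitting"] > cut])
        post = (pd.concat(post_rows) if post_rows
                else adjusted.iloc[0:0])
        icc_post = rel.icc_mixed(post) if len(post) else None
        results["reliability"] = {"icc_all": icc_all, "icc_post": icc_post}
        _write_json(results["reliability"], out / "reliability.json")

        # ------------------------------------------------ minimum test time
        stage("mintime")
        if stream_trials is not None:
            mtt = cpt.minimum_test_time(stream_trials)
            spurt = cpt.speed_change(stream_trials)
            results["mintime"] = {
                "min_time_s": mtt.min_time_s,
                "breakpoints": list(mtt.fit.breakpoints),
                "rho_at_75s": float(mtt.curve.loc[
                    mtt.curve["cutoff_s"] == 75.0, "rho"].iloc[0]),
                "speed_change": spurt,
            }
            mtt.curve.to_csv(out / "mintime_curve.csv", index=False)
            _write_json(results["mintime"], out / "mintime.json")

        # ------------------------------------------------ criterion model
        stage("model")
        covs = {"taps": ("dh_taps", "age"),
                "neurex": ("neurex_dh_cerebellar", "neurex_upper_motor",
                           "neurex_vision", "neurex_eye_movements", "age"),
                "none": ()}[config.covariate_set]
        missing = [c for c in ("bpfr", "t2ll", *covs)
                   if c not in profiles.columns]
        if missing:
            raise ValueError(f"model stage: missing covariate column(s) "
                             f"{missing}")
        train, val = mdl.split_cohort(
            profiles, mdl.SplitSpec(seed=seeds["model"]))
        fit = mdl.fit_biomarker_model(train, covariates=covs,
                                      seed=seeds["model"])
        metrics = mdl.validate_model(fit, val)
        results["model"] = {"model": fit, "metrics": metrics}
        if {"dh_taps", "age"} <= set(fit.coefficients):
            adj = mdl.to_adjusted_biomarker(fit)
            results["model"]["adjusted_formula"] = adj
        _write_json(results["model"], out / "model.json")
        val_scatter = val[["subject_id", "app_sdmt"]].copy()
        val_scatter["predicted"] = fit.predict(val)
        val_scatter.to_csv(out / "validation_scatter.csv", index=False)

        # ------------------------------------------------ thresholds
        stage("thresholds")
        post_src = post if len(post) else adjusted
        k_reports = thr.k_average_thresholds(
            post_src, k_max=config.k_max, method=config.threshold_method)
        results["thresholds"] = {"per_k": k_reports}
        _write_json(results["thresholds"], out / "thresholds.json")

        # ------------------------------------------------ group comparison
        stage("group_compare")
        hv = profiles.loc[profiles["cohort"] == "HV", "app_sdmt"]
        ms = profiles.loc[profiles["cohort"] != "HV", "app_sdmt"]
        results["group_compare"] = group_compare(hv, ms)
        _write_json(results["group_compare"], out / "group_compare.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {"config": dataclasses.asdict(config),
                "stage_seeds": seeds,
                "significance_level": SIGNIFICANCE_LEVEL,
                "stages_completed": list(results)}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return results
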