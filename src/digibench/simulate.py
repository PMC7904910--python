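"""Seeded synthetic cohorts with the statistical structure the validation
analyses assume.

Three generators are provided:

``generate_cross_sectional``
    One row per subject with cohort label, demographics, MRI measures
    (brain parenchymal fraction, T2 lesion load), dominant-hand tap
    count, NeurEx subsystem scores and disability scales, all driven by
    a latent disease-severity variable so the cross-correlations have
    the clinically expected signs.  The app SDMT score is generated from
    the linear digital-biomarker structure
    ``app = 55.5*BPFr - 306.5*T2LL + 0.24*taps - 0.16*age - 5.9 + eps``
    and the written score is the app score plus a constant design bias
    (default +7.8 points) plus noise.  Tap-count means are solved per
    cohort so that group medians land on the configured targets
    (default 54 points for healthy volunteers, 34.8 for MS).

``generate_longitudinal``
    Per-subject learning curves with two trials per sitting: a
    piecewise-linear rise that plateaus at a configurable break sitting
    (default 8), a configurable fraction of never-plateau subjects with
    a continuously positive slope, a small trial-2 practice advantage
    (default 0.19 points), and Gaussian session/trial noise.

``generate_answer_stream`` / ``generate_stream_cohort``
    Ordered per-answer event times within a trial (gamma-renewal
    process), with an optional end-of-test spurt, for duration-
    truncation analyses.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from digibench.scoring import PROFILE_COLUMNS, TRIAL_COLUMNS

SCORE_RANGE = (0.0, 110.0)

#: digital-biomarker generating coefficients (original scale)
DEFAULT_BIOMARKER_COEFFS = {
    "bpfr": 55.5, "t2ll": -306.5, "dh_taps": 0.24, "age": -0.16,
    "intercept": -5.9,
}

#: written-score noise SD as a multiple of residual_sd; at the default
#: residual_sd this puts the written-vs-app limits of agreement near the
#: clinically reported band (bias ± 1.96 * 6.7 points)
WRITTEN_NOISE_FACTOR = 1.33

_MS_SUBTYPES = ("PPMS", "SPMS", "RRMS")
_MS_WEIGHTS = np.array([54, 42, 58]) / 154
_AGE_BY_COHORT = {  # mean, sd in years
    "HV": (41.1, 14.0), "PPMS": (58.7, 11.1), "SPMS": (58.3, 10.3),
    "RRMS": (47.3, 9.6),
}
_SEVERITY_BY_COHORT = {  # latent severity mean, sd
    "HV": (0.15, 0.15), "PPMS": (1.8, 0.5), "SPMS": (1.9, 0.5),
    "RRMS": (1.0, 0.5),
}


@dataclass(frozen=True)
class CohortParams:
    """Cross-sectional generator configuration (defaults emulate the
    study cohort sizes and score structure)."""

    n_hv: int = 39
    n_ms: int = 154
    app_median_hv: float = 54.0
    app_median_ms: float = 34.8
    written_bias: float = 7.8
    biomarker_coeffs: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_COEFFS))
    residual_sd: float = 5.0
    bpfr_range: tuple[float, float] = (0.75, 0.95)
    t2ll_range: tuple[float, float] = (0.0, 0.05)
    seed: int = 0

    def __post_init__(self):
        if self.n_hv < 0 or self.n_ms < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class LearningCurveParams:
    """Longitudinal generator configuration.

    Noise is decomposed ANOVA-style: ``session_noise_sd`` is the noise
    of the sitting-level score (the mean of the two trials), while
    ``trial_noise_sd`` drives only the within-sitting trial contrast
    (its default makes the trial-1 minus trial-2 spread match the
    repeated-measures limits of agreement near ±11 points).
    ``plateau_between_sd`` spreads subject plateaus so between-subject
    clustering dominates (ICC near 0.9 post-learning).
    """

    n_subjects: int = 16
    n_sittings: int = 25
    plateau: float = 40.0
    plateau_between_sd: float = 17.0
    learning_slope: float = 3.5
    break_sitting: int = 8
    session_noise_sd: float = 5.0
    trial_noise_sd: float = 4.0
    trial2_advantage: float = 0.19
    prop_never_plateau: float = 2 / 16
    never_plateau_slope: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sittings < 2:
            raise ValueError("n_sittings must be >= 2")
        if not self.break_sitting < self.n_sittings:
            raise ValueError("break_sitting must be < n_sittings")
        if min(self.session_noise_sd, self.trial_noise_sd,
               self.plateau_between_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.prop_never_plateau <= 1:
            raise ValueError("prop_never_plateau must lie in [0, 1]")


def _clip_score(x):
    return np.clip(x, *SCORE_RANGE)


def generate_cross_sectional(params: CohortParams) -> pd.DataFrame:
    """Generate one profile row per subject (wide covariate table)."""
    if params.n_hv + params.n_ms == 0:
        warnings.warn("empty cohort requested; returning empty table",
                      stacklevel=2)
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    rng = np.random.default_rng(params.seed)
    c = params.biomarker_coeffs

    n_ms_sub = np.floor(_MS_WEIGHTS * params.n_ms).astype(int)
    n_ms_sub[0] += params.n_ms - n_ms_sub.sum()
    cohorts = (["HV"] * params.n_hv
               + [s for s, n in zip(_MS_SUBTYPES, n_ms_sub)
                  for _ in range(n)])

    rows = []
    bp_lo, bp_hi = params.bpfr_range
    t2_lo, t2_hi = params.t2ll_range
    bp_mid = 0.5 * (bp_lo + bp_hi) + 0.25 * (bp_hi - bp_lo)
    for i, cohort in enumerate(cohorts):
        sev_mu, sev_sd = _SEVERITY_BY_COHORT[cohort]
        s = max(rng.normal(sev_mu, sev_sd), 0.0)
        age_mu, age_sd = _AGE_BY_COHORT[cohort]
        age = float(np.clip(rng.normal(age_mu, age_sd), 18, 90))
        bpfr = float(np.clip(bp_mid - 0.035 * s + rng.normal(0, 0.012),
                             bp_lo + 1e-6, bp_hi))
        t2ll = float(np.clip(0.0005 + 0.24 * (t2_hi - t2_lo) * s
                             + abs(rng.normal(0, 0.06 * (t2_hi - t2_lo))),
                             t2_lo, t2_hi))
        rows.append((cohort, s, age, bpfr, t2ll))
    df = pd.DataFrame(rows, columns=["cohort", "severity", "age",
                                     "bpfr", "t2ll"])
    df.insert(0, "subject_id",
              [f"S{i:04d}" for i in range(len(df))])

    # solve per-group tap means so group app-SDMT medians hit targets
    is_hv = df["cohort"] == "HV"
    taps = np.empty(len(df))
    for mask, target in ((is_hv, params.app_median_hv),
                         (~is_hv, params.app_median_ms)):
        if not mask.any():
            continue
        base = (c["bpfr"] * df.loc[mask, "bpfr"].mean()
                + c["t2ll"] * df.loc[mask, "t2ll"].mean()
                + c["age"] * df.loc[mask, "age"].mean() + c["intercept"])
        taps_mu = (target - base) / c["dh_taps"]
        sev = df.loc[mask, "severity"]
        taps[mask.to_numpy()] = (taps_mu - 10.0 * (sev - sev.mean())
                                 + rng.normal(0, 8.0, mask.sum()))
    df["dh_taps"] = np.round(np.maximum(taps, 0.0))

    eps = rng.normal(0, params.residual_sd, len(df))
    app = (c["bpfr"] * df["bpfr"] + c["t2ll"] * df["t2ll"]
           + c["dh_taps"] * df["dh_taps"] + c["age"] * df["age"]
           + c["intercept"] + eps)
    df["app_sdmt"] = _clip_score(app)
    eps_w = rng.normal(0, WRITTEN_NOISE_FACTOR * params.residual_sd, len(df))
    df["written_sdmt"] = _clip_score(df["app_sdmt"] + params.written_bias
                                     + eps_w)

    sev = df["severity"].to_numpy()
    n = len(df)
    df["pasat3"] = np.clip(np.round(52 - 8 * sev + rng.normal(0, 6, n)),
                           0, 60)
    df["neurex_total"] = np.clip(
        20 + 95 * sev + rng.normal(0, 20, n), 0, 1349).round(1)
    for col, share, spread in (
            ("neurex_cognitive", 0.10, 0.04),
            ("neurex_dh_cerebellar", 0.12, 0.05),
            ("neurex_upper_motor", 0.22, 0.08),
            ("neurex_vision", 0.08, 0.03),
            ("neurex_eye_movements", 0.06, 0.03),
            ("neurex_brainstem", 0.05, 0.02)):
        frac = np.clip(rng.normal(share, spread, n), 0, 1)
        df[col] = (frac * df["neurex_total"]).round(1)
    df["edss"] = np.clip(
        np.round((0.8 + 2.8 * sev + rng.normal(0, 0.5, n)) * 2) / 2, 0, 10)
    df["combiwise"] = np.clip(2 + 25 * sev + rng.normal(0, 5, n),
                              0, 100).round(1)
    df["gender"] = rng.choice(["F", "M"], size=n, p=[0.58, 0.42])
    return df.drop(columns="severity")[PROFILE_COLUMNS]


def _learning_mean(t, plateau, slope, brk):
    return plateau - slope * np.maximum(0.0, brk - t)


def generate_longitudinal(params: LearningCurveParams) -> pd.DataFrame:
    """Generate the canonical long trials table: two 90-s trials per
    sitting per subject, following piecewise-linear learning curves."""
    rng = np.random.default_rng(params.seed)
    n_np = int(round(params.prop_never_plateau * params.n_subjects))
    never = np.zeros(params.n_subjects, dtype=bool)
    never[rng.permutation(params.n_subjects)[:n_np]] = True

    # mirror the longitudinal cohort mix: mostly progressive MS, one HV
    cohorts = ["HV"] + ["PPMS"] * 8 + ["SPMS"] * 5 + ["RRMS"] * 2
    if params.n_subjects != len(cohorts):
        cohorts = ["HV"] + [
            _MS_SUBTYPES[i % 3] for i in range(params.n_subjects - 1)]

    t = np.arange(1, params.n_sittings + 1, dtype=float)
    rows = []
    for i in range(params.n_subjects):
        plateau_i = rng.normal(params.plateau, params.plateau_between_sd)
        if never[i]:
            mean_t = plateau_i - params.never_plateau_slope * (
                params.n_sittings - t)
        else:
            mean_t = _learning_mean(t, plateau_i, params.learning_slope,
                                    float(params.break_sitting))
        session = mean_t + rng.normal(0, params.session_noise_sd, t.size)
        # within-sitting trial contrast: trial2 - trial1 difference has
        # mean trial2_advantage and SD sqrt(2)*trial_noise_sd
        contrast = rng.normal(params.trial2_advantage,
                              np.sqrt(2) * params.trial_noise_sd, t.size)
        for j, sitting in enumerate(t.astype(int)):
            for trial in (1, 2):
                score = session[j] + (trial - 1.5) * contrast[j]
                n_correct = int(np.clip(np.round(score), *SCORE_RANGE))
                rows.append((f"L{i:03d}", cohorts[i], int(sitting), trial,
                             n_correct, 90.0, None))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.attrs["never_plateau"] = {f"L{i:03d}": bool(never[i])
                                 for i in range(params.n_subjects)}
    return df


#: six-month written-SDMT difference distribution: a calibrated
#: uniform-normal mixture.  The reported difference statistics (2*SD
#: near 10.3 points alongside a mean - 1.5*IQR threshold near 13) imply
#: a mid-heavy, short-tailed shape that no single Gaussian reproduces;
#: the dominant uniform component supplies the wide IQR, the narrow
#: normal the central mass, and the broad normal a modest tail of large
#: decliners.
RETEST_MIXTURE = {"weights": (0.84, 0.10, 0.06),
                  "uniform_halfwidth": 8.6, "narrow_sd": 2.5,
                  "tail_sd": 10.0}


def generate_written_retest(n_subjects: int = 112, baseline_mean: float = 35.0,
                            baseline_sd: float = 12.0,
                            diff_mean: float = -0.7,
                            seed: int = 0) -> pd.DataFrame:
    """Paired written SDMT scores collected six months apart, with
    disability-change covariates.

    The score differences follow the calibrated :data:`RETEST_MIXTURE`
    around ``diff_mean``; disability changes (CombiWISE, NeurEx) are
    drawn independently of the SDMT change, mirroring the observed lack
    of association between four-point SDMT decline and disability
    progression.
    """
    rng = np.random.default_rng(seed)
    base = np.clip(rng.normal(baseline_mean, baseline_sd, n_subjects),
                   *SCORE_RANGE)
    m = RETEST_MIXTURE
    comp = rng.choice(3, n_subjects, p=m["weights"])
    v = np.where(
        comp == 0,
        rng.uniform(-m["uniform_halfwidth"], m["uniform_halfwidth"],
                    n_subjects),
        np.where(comp == 1, rng.normal(0, m["narrow_sd"], n_subjects),
                 rng.normal(0, m["tail_sd"], n_subjects)))
    follow = np.clip(base + diff_mean + v, *SCORE_RANGE)
    return pd.DataFrame({
        "subject_id": [f"W{i:03d}" for i in range(n_subjects)],
        "written_t1": base, "written_t2": follow,
        "delta_combiwise": rng.normal(0.9, 2.0, n_subjects),
        "delta_neurex": rng.normal(7.0, 12.0, n_subjects),
    })


def generate_answer_stream(trial_speed: float, duration_s: float = 90.0,
                           seed=None, deterministic: bool = False,
                           regularity: float = 4.0,
                           onset_delay: float = 0.0,
                           end_spurt_start: float | None = None,
                           end_spurt_factor: float = 1.0) -> np.ndarray:
    """Ordered correct-answer event times within one trial.

    Events follow a gamma-renewal process with mean rate ``trial_speed``
    (answers/second, must lie in (0, 2]); ``regularity`` is the gamma
    shape (higher = more metronome-like answering).  ``onset_delay``
    suppresses answers for the first seconds of the trial (re-orienting
    to the freshly randomized symbol-digit key).  With
    ``deterministic=True`` events are exactly uniformly spaced.  An
    end-of-test spurt multiplies the rate by ``end_spurt_factor`` from
    ``end_spurt_start`` seconds on.
    """
    if not 0 < trial_speed <= 2:
        raise ValueError("trial_speed must lie in (0, 2] answers/second")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if deterministic:
        n = int(np.floor(trial_speed * duration_s))
        return (np.arange(1, n + 1) / trial_speed)[
            np.arange(1, n + 1) / trial_speed <= duration_s]
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    times = []
    now = float(onset_delay)
    while True:
        rate = trial_speed
        if end_spurt_start is not None and now >= end_spurt_start:
            rate *= end_spurt_factor
        gap = rng.gamma(regularity, 1.0 / (rate * regularity))
        now += gap
        if now > duration_s:
            break
        times.append(now)
    return np.asarray(times)


def generate_stream_cohort(n_subjects: int = 22, cohort: str = "HV",
                           speed_range: tuple[float, float] = (0.2, 0.9),
                           duration_s: float = 90.0,
                           trial_jitter_sd: float = 0.04,
                           regularity: float = 3.0,
                           onset_delay_max: float = 3.0,
                           end_spurt_start: float | None = 75.0,
                           end_spurt_factor: float = 1.033,
                           seed: int = 0) -> pd.DataFrame:
    """Two same-sitting trials with event streams per subject.

    Subject speeds are uniform on ``speed_range`` (the observed
    between-subject spread of 0.2-0.9 correct answers/second); each
    trial's speed is jittered by ``trial_jitter_sd`` and starts after a
    random onset delay (uniform up to ``onset_delay_max`` seconds —
    each trial re-randomizes the symbol-digit key, so the first answers
    come slowly), which makes very short cutoffs unreliable.  The
    default end spurt slightly raises the answering rate over the last
    15 s of a 90-s trial, producing a within-trial 75-s vs 90-s speed
    difference of order 0.003 points/s.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        base = rng.uniform(*speed_range)
        for trial in (1, 2):
            speed = float(np.clip(base + rng.normal(0, trial_jitter_sd),
                                  0.05, 2.0))
            ev = generate_answer_stream(
                speed, duration_s, seed=rng, regularity=regularity,
                onset_delay=float(rng.uniform(0, onset_delay_max)),
                end_spurt_start=end_spurt_start,
                end_spurt_factor=end_spurt_factor)
            rows.append((f"T{i:03d}", cohort, 1, trial, len(ev),
                         duration_s, tuple(float(x) for x in ev)))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
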