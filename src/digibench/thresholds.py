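"""Intra-individual decline thresholds for repeated SDMT testing.

Group-level test-retest reliability can be excellent while individual
scores still fluctuate by far more than the conventional 4-point
"clinically meaningful" decline.  This module derives data-driven
thresholds from the distribution of within-subject score differences:

* ``iqr1.5`` — decline exceeding ``|mean - 1.5*IQR|`` of the difference
  distribution (the rule that yields the 13-point six-month threshold
  for the written test);
* ``sd2`` — the conventional ``|mean| + 2*SD`` band.

Averaging k adjacent sittings before differencing shrinks the noise
(variance of a mean), so the threshold falls roughly as ``1/sqrt(k)`` —
the rationale for granular home testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("iqr1.5", "sd2")


@dataclass(frozen=True)
class ThresholdReport:
    method: str
    threshold_points: float      # magnitude of decline, >= 0
    diff_mean: float
    diff_sd: float
    diff_iqr: float
    k: int                       # averaging-window size
    n_differences: int


@dataclass(frozen=True)
class DeclinerComparison:
    threshold_points: float
    n_total: int
    n_decliners: int
    proportion: float
    decliner_ids: tuple
    disability_medians: dict     # measure -> (decliners, non-decliners)
    disability_p: dict           # measure -> rank-sum p (or None)


def paired_differences(score_t1, score_t2) -> tuple[np.ndarray, dict]:
    """Within-subject differences (later - earlier) with their summary.

    Unpaired (NaN) rows are dropped with a warning.  The summary holds
    the mean, sample SD, 2*SD and IQR of the differences.
    """
    t1 = np.asarray(score_t1, dtype=float)
    t2 = np.asarray(score_t2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("scores must be paired by subject")
    ok = ~(np.isnan(t1) | np.isnan(t2))
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} unpaired row(s)",
                      stacklevel=2)
    d = t2[ok] - t1[ok]
    summary = {
        "mean": float(np.mean(d)),
        "sd": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        "two_sd": 2 * float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        "iqr": float(np.subtract(*np.percentile(d, [75, 25]))),
        "n": int(d.size),
    }
    return d, summary


def decline_threshold(differences, method: str = "iqr1.5",
                      min_n: int = 8, k: int = 1) -> ThresholdReport:
    """Decline threshold (in points of decline) from a difference
    distribution.

    ``iqr1.5`` takes ``|mean - 1.5*IQR|``; ``sd2`` takes
    ``|mean| + 2*SD``.  IQR uses the linear-interpolation quantile
    convention.  Withheld (ValueError) below ``min_n`` differences.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < min_n:
        raise ValueError(
            f"threshold withheld: need >= {min_n} differences, got {d.size}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    iqr = float(np.subtract(*np.percentile(d, [75, 25])))
    if method == "iqr1.5":
        thr = abs(mean - 1.5 * iqr)
    else:
        thr = abs(mean) + 2 * sd
    return ThresholdReport(method=method, threshold_points=float(thr),
                           diff_mean=mean, diff_sd=sd, diff_iqr=iqr,
                           k=k, n_differences=int(d.size))


def _block_means(scores: np.ndarray, k: int,
                 overlapping: bool) -> np.ndarray:
    if overlapping:
        if scores.size < k:
            return np.empty(0)
        return np.convolve(scores, np.ones(k) / k, mode="valid")
    n_blocks = scores.size // k
    if n_blocks == 0:
        return np.empty(0)
    return scores[: n_blocks * k].reshape(n_blocks, k).mean(axis=1)


def k_average_thresholds(longitudinal: pd.DataFrame, k_max: int = 4,
                         method: str = "iqr1.5",
                         subject_col: str = "subject_id",
                         sitting_col: str = "sitting",
                         score_col: str = "score_90s",
                         overlapping: bool = False,
                         min_n: int = 8) -> list[ThresholdReport]:
    """Decline thresholds for scores averaged over k adjacent sittings.

    For each k in 1..k_max and each subject, consecutive non-overlapping
    blocks of k sittings (in sitting order) are averaged and adjacent
    block means differenced; differences are pooled across subjects and
    fed to :func:`decline_threshold`.  ``k = 1`` reduces to adjacent-
    sitting differences.  Subjects with fewer than ``2*k`` sittings are
    excluded for that k with a warning.
    """
    reports = []
    for k in range(1, k_max + 1):
        pooled = []
        skipped = 0
        for _, grp in longitudinal.groupby(subject_col):
            scores = (grp.sort_values(sitting_col)[score_col]
                      .to_numpy(dtype=float))
            if scores.size < 2 * k:
                skipped += 1
                continue
            means = _block_means(scores, k, overlapping)
            pooled.append(np.diff(means))
        if skipped:
            warnings.warn(
                f"k={k}: excluded {skipped} subject(s) with < {2 * k} "
                "sittings", stacklevel=2)
        d = np.concatenate(pooled) if pooled else np.empty(0)
        reports.append(decline_threshold(d, method=method, min_n=min_n, k=k))
    return reports


def classify_decliners(baseline, follow_up, threshold_points: float,
                       disability_deltas: pd.DataFrame | None = None,
                       subject_ids=None) -> DeclinerComparison:
    """Flag subjects whose score dropped by at least the threshold and
    compare disability progression between decliners and the rest.

    ``disability_deltas`` holds per-subject changes (e.g. columns
    ``delta_combiwise``, ``delta_neurex``) aligned with the score
    arrays; each measure is compared between groups with the Wilcoxon
    rank-sum test, with medians always reported.  With an empty group
    the comparison p-value is withheld (None).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(follow_up, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must be paired")
    decline = b - f
    flag = decline >= threshold_points
    ids = (np.asarray(subject_ids) if subject_ids is not None
           else np.arange(b.size))

    medians, pvals = {}, {}
    if disability_deltas is not None:
        for col in disability_deltas.columns:
            v = disability_deltas[col].to_numpy(dtype=float)
            grp1, grp0 = v[flag], v[~flag]
            medians[col] = (float(np.median(grp1)) if grp1.size else np.nan,
                            float(np.median(grp0)) if grp0.size else np.nan)
            if grp1.size and grp0.size:
                pvals[col] = float(stats.mannwhitneyu(
                    grp1, grp0, alternative="two-sided").pvalue)
            else:
                pvals[col] = None
    return DeclinerComparison(
        threshold_points=float(threshold_points), n_total=int(b.size),
        n_decliners=int(flag.sum()), proportion=float(flag.mean()),
        decliner_ids=tuple(ids[flag].tolist()),
        disability_medians=medians, disability_p=pvals)
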