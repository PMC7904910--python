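"""Contiguous piecewise-linear regression and its two applications:
per-subject learning-plateau detection and minimum reliable test duration.

The model fits the data with several contiguous lines — a linear spline
``y = b0 + b1*x + sum_j g_j * max(x - t_j, 0)`` whose segments meet at
every breakpoint — minimizing the squared distance between the data and
the regression model.  Breakpoint locations are found by exhaustive
search over the intervals between observed x values (the least-squares
solution for fixed breakpoints is linear, so each candidate is solved
exactly), optionally refined within the best interval by bounded scalar
minimization.  Ties in SSE are broken toward the earlier breakpoint,
which for learning curves is the conservative (shorter learning period)
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: minimum observations per segment (identifiability)
MIN_SEGMENT_POINTS = 3


@dataclass(frozen=True)
class ChangePointFit:
    """A continuity-constrained piecewise-linear least-squares fit.

    ``segments`` holds (slope, intercept) per segment in x order;
    adjacent segments agree at each breakpoint by construction.
    """

    breakpoints: tuple[float, ...]
    segments: tuple[tuple[float, float], ...]
    sse: float
    n_segments: int
    identified: bool = True

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        edges = (-np.inf,) + self.breakpoints + (np.inf,)
        for j, (slope, intercept) in enumerate(self.segments):
            m = (x > edges[j]) & (x <= edges[j + 1]) if j else (x <= edges[1])
            out[m] = intercept + slope * x[m]
        return out


@dataclass(frozen=True)
class LearningEndResult:
    identified: bool
    sitting: int | None
    reason: str
    fit: ChangePointFit | None = None
    fit_linear: ChangePointFit | None = None


@dataclass(frozen=True)
class MinimumTestTimeResult:
    curve: pd.DataFrame          # columns cutoff_s, rho, n
    fit: ChangePointFit
    min_time_s: float            # first inflection, 1-s resolution


@dataclass(frozen=True)
class SpeedChangeResult:
    mean_diff: float             # points/s, speed(t2) - speed(t1)
    p_value: float               # Wilcoxon signed-rank
    n: int


def _spline_design(x: np.ndarray, breaks) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols.extend(np.maximum(x - b, 0.0) for b in breaks)
    return np.column_stack(cols)


def _solve(x: np.ndarray, y: np.ndarray, breaks):
    A = _spline_design(x, breaks)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def _coef_to_segments(coef, breaks):
    slope, intercept = float(coef[1]), float(coef[0])
    segs = [(slope, intercept)]
    for b, g in zip(breaks, coef[2:]):
        slope += float(g)
        intercept -= float(g) * float(b)
        segs.append((slope, intercept))
    return tuple(segs)


def fit_piecewise(x, y, n_breakpoints: int,
                  min_segment_points: int = MIN_SEGMENT_POINTS,
                  refine: bool = True) -> ChangePointFit:
    """Fit a contiguous piecewise-linear model with a fixed number of
    breakpoints by exhaustive candidate search.

    Candidate breakpoints lie strictly between consecutive observed x
    values, restricted so every segment keeps at least
    ``min_segment_points`` observations.  With ``refine=True`` the best
    candidate's breakpoints are polished by bounded scalar minimization
    within their intervals (coordinate descent, two passes); the refined
    fit is kept only if it does not increase the SSE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D and the same length")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    n = x.size
    k = int(n_breakpoints)
    if k == 0:
        if n < 2:
            raise ValueError("need >= 2 points for a line")
        sse, coef = _solve(x, y, ())
        return ChangePointFit(breakpoints=(), sse=sse, n_segments=1,
                              segments=_coef_to_segments(coef, ()))
    if n < min_segment_points * (k + 1):
        raise ValueError(
            f"{k} breakpoints need >= {min_segment_points * (k + 1)} points "
            f"({min_segment_points} per segment); got {n}")

    # candidates: interval midpoints and observed x values; a breakpoint
    # at an observed x puts that observation on the left segment
    cand = np.unique(np.concatenate([0.5 * (x[:-1] + x[1:]), x[1:-1]]))
    n_left = np.searchsorted(x, cand, side="right")
    keep = (n_left >= min_segment_points) & (n - n_left >= min_segment_points)
    cand, n_left = cand[keep], n_left[keep]
    if cand.size < k:
        raise ValueError("no admissible breakpoint placement")

    best = None  # (sse, breaks, coef)
    for combo in combinations(range(cand.size), k):
        counts = np.diff([0, *(n_left[i] for i in combo), n])
        if np.any(counts < min_segment_points):
            continue
        breaks = tuple(cand[i] for i in combo)
        sse, coef = _solve(x, y, breaks)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, breaks, coef)
    if best is None:
        raise ValueError("no admissible breakpoint placement")
    sse, breaks, coef = best

    if refine:
        breaks = list(breaks)
        for _ in range(2):
            for j, bj in enumerate(breaks):
                lo = float(x[x < bj].max()) if np.any(x < bj) else float(x[0])
                hi = float(x[x > bj].min()) if np.any(x > bj) else float(x[-1])
                span = hi - lo
                if span <= 1e-12:
                    continue

                def f(t, j=j):
                    trial = breaks.copy()
                    trial[j] = t
                    return _solve(x, y, tuple(trial))[0]

                res = optimize.minimize_scalar(
                    f, bounds=(lo + 1e-9 * span, hi - 1e-9 * span),
                    method="bounded")
                if res.fun < sse - 1e-12:
                    breaks[j] = float(res.x)
                    sse = float(res.fun)
        sse, coef = _solve(x, y, tuple(breaks))
        breaks = tuple(breaks)

    return ChangePointFit(breakpoints=tuple(float(b) for b in breaks),
                          sse=sse, n_segments=k + 1,
                          segments=_coef_to_segments(coef, breaks))


# ---------------------------------------------------------------------------
# Learning-plateau detection

def _segment_slope_inference(x, y):
    """OLS slope, its SE and residual df on one segment."""
    m = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    df = m - 2
    sxx = float(np.sum((x - x.mean()) ** 2))
    if df <= 0 or sxx == 0:
        return float(slope), np.inf, df
    s2 = float(resid @ resid) / df
    return float(slope), float(np.sqrt(s2 / sxx)), df


def detect_learning_end(sittings, scores,
                        min_sittings: int = 20,
                        slope_tol: float = 0.5,
                        alpha: float = 0.01,
                        improvement_alpha: float = 0.05,
                        enforce_min_sittings: bool = True,
                        ) -> LearningEndResult:
    """Locate the sitting at which the practice effect stops.

    Fits a one-breakpoint contiguous model to the per-sitting scores and
    declares the breakpoint the learning end when

    1. the pre-break slope is positive (scores were improving),
    2. the post-break slope is compatible with a plateau: its
       ``(1 - alpha)`` CI contains 0 and the point estimate is below
       ``slope_tol`` points/sitting,
    3. the one-breakpoint model improves on the plain line by an F-test
       at level ``improvement_alpha`` (a model-selection gate, kept at
       the conventional 0.05 rather than the stricter level used for
       inferential claims).

    Otherwise the subject is reported as "not identified" — e.g. a
    continuously positive slope means learning is still ongoing at the
    last observed sitting.  The breakpoint is reported at data
    resolution (nearest observed sitting).
    """
    x = np.asarray(sittings, dtype=float)
    y = np.asarray(scores, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if enforce_min_sittings and x.size < min_sittings:
        raise ValueError(
            f"learning-end detection needs >= {min_sittings} sittings, "
            f"got {x.size}")

    fit0 = fit_piecewise(x, y, 0)
    fit1 = fit_piecewise(x, y, 1, refine=False)
    bp = fit1.breakpoints[0]
    n = x.size

    # (iii) does the breakpoint earn its two extra parameters?
    if fit1.sse <= 1e-12:
        p_improve = 0.0
    else:
        f_stat = ((fit0.sse - fit1.sse) / 2) / (fit1.sse / (n - 4))
        p_improve = float(stats.f.sf(f_stat, 2, n - 4))

    pre_slope = fit1.segments[0][0]
    post = x > bp
    post_slope, post_se, post_df = _segment_slope_inference(x[post], y[post])
    if np.isinf(post_se):
        ci_half = 0.0 if np.allclose(y[post], y[post].mean()) else np.inf
    else:
        ci_half = stats.t.ppf(1 - alpha / 2, post_df) * post_se

    if p_improve >= improvement_alpha:
        return LearningEndResult(False, None, "no breakpoint improvement",
                                 fit1, fit0)
    if pre_slope <= 0:
        return LearningEndResult(False, None, "pre-break slope not positive",
                                 fit1, fit0)
    if not (abs(post_slope) <= ci_half + 1e-12 and post_slope < slope_tol):
        return LearningEndResult(False, None,
                                 "post-break slope still positive",
                                 fit1, fit0)
    nearest = int(x[np.argmin(np.abs(x - bp))])
    fit1 = ChangePointFit(fit1.breakpoints, fit1.segments, fit1.sse,
                          fit1.n_segments, identified=True)
    return LearningEndResult(True, nearest, "plateau identified", fit1, fit0)


# ---------------------------------------------------------------------------
# Minimum reliable test duration

def _counts_at(event_times, cutoff: float) -> int:
    return int(np.searchsorted(np.asarray(event_times, dtype=float),
                               cutoff, side="right"))


def minimum_test_time(trials: pd.DataFrame, step_s: float = 5.0,
                      max_s: float = 90.0, n_breakpoints: int = 2,
                      min_subjects: int = 10) -> MinimumTestTimeResult:
    """Determine the shortest test duration providing reliable scores.

    For every cutoff on a ``step_s`` grid up to ``max_s`` both same-
    sitting trials are truncated and the between-trial Spearman
    correlation of correct-answer counts is computed across subjects.
    A two-breakpoint contiguous model is fitted to the
    (cutoff, correlation) curve; the first inflection marks the duration
    after which reliability keeps improving only at a slower pace, i.e.
    the minimum reliable test time.
    """
    needed = {"subject_id", "trial", "event_times"}
    if not needed.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(needed)}")
    if trials["event_times"].isna().any():
        raise ValueError("minimum_test_time requires event streams "
                         "for every trial")
    wide = trials.pivot_table(index="subject_id", columns="trial",
                              values="event_times", aggfunc="first")
    if not {1, 2}.issubset(wide.columns):
        raise ValueError("need trial 1 and trial 2 per subject")
    wide = wide.dropna(subset=[1, 2])
    if len(wide) < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects with two trials, "
                         f"got {len(wide)}")

    cutoffs = np.arange(step_s, max_s + step_s / 2, step_s)
    rows = []
    for c in cutoffs:
        c1 = [_counts_at(ev, c) for ev in wide[1]]
        c2 = [_counts_at(ev, c) for ev in wide[2]]
        rho = stats.spearmanr(c1, c2).statistic
        rows.append((float(c), float(rho), len(wide)))
    curve = pd.DataFrame(rows, columns=["cutoff_s", "rho", "n"])

    fit = fit_piecewise(curve["cutoff_s"].to_numpy(),
                        curve["rho"].to_numpy(), n_breakpoints)
    min_time = float(np.round(fit.breakpoints[0]))
    return MinimumTestTimeResult(curve=curve, fit=fit, min_time_s=min_time)


def speed_change(trials: pd.DataFrame, t1: float = 75.0,
                 t2: float = 90.0) -> SpeedChangeResult:
    """Within-trial testing-speed difference between two durations.

    For every trial with an event stream the speed (correct answers per
    second) is evaluated at ``t1`` and ``t2``; the paired difference
    ``speed(t2) - speed(t1)`` quantifies the end-of-test spurt.  Tested
    with the Wilcoxon signed-rank test.
    """
    if trials["event_times"].isna().any():
        raise ValueError("speed_change requires event streams")
    diffs = []
    for ev in trials["event_times"]:
        diffs.append(_counts_at(ev, t2) / t2 - _counts_at(ev, t1) / t1)
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        raise ValueError("no trials with event streams")
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
    return SpeedChangeResult(mean_diff=float(diffs.mean()), p_value=p,
                             n=int(diffs.size))
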