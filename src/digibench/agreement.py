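"""Agreement statistics between paired measurements.

Implements Bland-Altman analysis (simple and repeated-measures via a
random-intercept model of within-sitting differences), Lin's concordance
correlation coefficient, and the outlier-adjustment rule for two-trial
sittings: a sitting whose trial-1 minus trial-2 difference falls outside
the limits of agreement is considered to contain one outlying trial, and
the lower-performing trial's score is raised by exactly the amount that
brings the difference back to the nearest limit.

Conventions (fixed so signs match clinical reporting):

* written vs app pairs are differenced as ``written - app`` — the
  systematic design bias appears as a positive number (≈ +7.8 points);
* two trials within a sitting are differenced as ``trial1 - trial2`` —
  the within-sitting practice advantage appears as a negative mean
  (≈ -0.19 points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

#: conventional 95% limits-of-agreement multiplier
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementReport:
    bias: float            # mean of differences, points
    sd_diff: float         # SD of differences, points
    loa_low: float         # lower limit of agreement
    loa_high: float        # upper limit of agreement
    n_pairs: int
    method: str            # {"simple", "mixed_effects"}
    var_between: float | None = None
    var_within: float | None = None

    def __post_init__(self):
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int


def bland_altman(x, y, multiplier: float = LOA_MULTIPLIER) -> AgreementReport:
    """Simple Bland-Altman agreement between paired measurements.

    Differences are taken as ``x - y``; limits are
    ``bias ± multiplier * sd(differences)`` with the sample SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementReport(
        bias=bias, sd_diff=sd,
        loa_low=bias - multiplier * sd, loa_high=bias + multiplier * sd,
        n_pairs=int(x.size), method="simple",
    )


def mixed_effects_bland_altman(pairs: pd.DataFrame,
                               subject_col: str = "subject_id",
                               x_col: str = "x", y_col: str = "y",
                               multiplier: float = LOA_MULTIPLIER,
                               ) -> AgreementReport:
    """Repeated-measures Bland-Altman for pairs clustered within subjects.

    Each subject may contribute several paired measurements (e.g. one
    trial-1/trial-2 pair per test sitting).  The within-pair differences
    are modelled with a subject-level random intercept; the bias is the
    fixed-effect mean and the limits use the total difference variance
    (between-subject + residual), so they describe a new difference from
    a new subject.

    Falls back to the simple method, with a warning, when clustering is
    unidentifiable (a single subject, or no subject with replicate pairs).
    """
    d = (np.asarray(pairs[x_col], dtype=float)
         - np.asarray(pairs[y_col], dtype=float))
    groups = np.asarray(pairs[subject_col])
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    sizes = pd.Series(d).groupby(groups).size()
    if len(sizes) < 2 or (sizes <= 1).all():
        warnings.warn(
            "subject clustering unidentifiable; using simple Bland-Altman",
            stacklevel=2)
        return bland_altman(np.zeros_like(d) + d, np.zeros_like(d),
                            multiplier=multiplier)
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(d, np.ones((d.size, 1)), groups=groups)
        fit = model.fit(reml=True)
    bias = float(fit.params[0])
    var_between = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    var_within = max(float(fit.scale), 0.0)
    total_sd = float(np.sqrt(var_between + var_within))
    return AgreementReport(
        bias=bias, sd_diff=total_sd,
        loa_low=bias - multiplier * total_sd,
        loa_high=bias + multiplier * total_sd,
        n_pairs=int(d.size), method="mixed_effects",
        var_between=var_between, var_within=var_within,
    )


def adjust_outlier_trials(sittings: pd.DataFrame, report: AgreementReport,
                          trial1_col: str = "trial1_score",
                          trial2_col: str = "trial2_score",
                          ) -> pd.DataFrame:
    """Apply the outlier-adjustment rule to two-trial sittings.

    A sitting is an outlier when its ``trial1 - trial2`` difference falls
    strictly outside the closed interval ``[loa_low, loa_high]`` of
    ``report``.  The lower-performing trial's score is then raised by
    exactly the amount that brings the difference to the nearest limit;
    no score is ever decreased, and differences already at a limit are
    untouched.  Sittings with a missing trial pass through unflagged.

    Returns a copy with adjusted scores and a boolean ``outlier`` column.
    The operation is idempotent.
    """
    out = sittings.copy()
    t1 = out[trial1_col].to_numpy(dtype=float)
    t2 = out[trial2_col].to_numpy(dtype=float)
    diff = t1 - t2
    have_both = ~(np.isnan(t1) | np.isnan(t2))
    # closed interval: a difference exactly at a limit is not an outlier
    # (with a small tolerance so float round-off cannot re-flag it)
    tol = 1e-9 * max(1.0, abs(report.loa_low), abs(report.loa_high))
    high = have_both & (diff > report.loa_high + tol)
    low = have_both & (diff < report.loa_low - tol)
    # diff too large -> trial 2 underperformed; raise it to hit loa_high
    t2 = np.where(high, t2 + (diff - report.loa_high), t2)
    # diff too small -> trial 1 underperformed; raise it to hit loa_low
    t1 = np.where(low, t1 + (report.loa_low - diff), t1)
    out[trial1_col] = t1
    out[trial2_col] = t2
    out["outlier"] = high | low
    return out


def lin_ccc(x, y, alpha: float = 0.05) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    CCC measures agreement with the 1:1 line::

        CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2)

    using population (1/n) moments as in Lin's original formulation.
    ``|CCC| <= |r|`` always holds, with equality only when the pairs are
    already on the identity line up to a scale-free rotation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or x.shape != y.shape:
        raise ValueError("lin_ccc needs >= 3 paired observations")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = sx2 + sy2 + (float(x.mean()) - float(y.mean())) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: no variance and no location shift")
    ccc = 2 * sxy / denom

    z_crit = stats.norm.ppf(1 - alpha / 2)
    if sx2 > 0 and sy2 > 0:
        r = sxy / np.sqrt(sx2 * sy2)
    else:
        r = 0.0
    if abs(ccc) >= 1 - 1e-12 or abs(r) < 1e-12 or n <= 3:
        # degenerate: perfect agreement or no correlation; CI collapses
        # to the estimate (former) or uses the plain Fisher SE (latter)
        if abs(ccc) >= 1 - 1e-12:
            return ConcordanceResult(ccc=float(ccc), ci_low=float(ccc),
                                     ci_high=float(ccc), n=n)
        se_z = 1.0 / np.sqrt(max(n - 3, 1))
    else:
        # Lin (1989) variance of the z-transformed CCC
        u = (float(x.mean()) - float(y.mean())) / (sx2 * sy2) ** 0.25
        c2 = ccc * ccc
        se_z2 = ((1 - r * r) * c2 / ((1 - c2) * r * r)
                 + 2 * ccc ** 3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
                 - ccc ** 4 * u ** 4 / (2 * r * r * (1 - c2) ** 2))
        se_z = np.sqrt(max(se_z2, 0.0) / (n - 2))
    z = np.arctanh(np.clip(ccc, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(z - z_crit * se_z), np.tanh(z + z_crit * se_z)
    return ConcordanceResult(ccc=float(ccc), ci_low=float(lo),
                             ci_high=float(hi), n=n)
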