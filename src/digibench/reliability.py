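"""Test-retest reliability: mixed-model intraclass correlation and
six-month retest correlations.

The ICC used here is the proportion of total score variance attributable
to differences between individuals::

    ICC = var_between / (var_between + var_within)

estimated from a linear mixed model with a subject-level random
intercept and the test-sitting number (or days from the first test) as
the fixed effect, so that a shared practice trend is not mistaken for
within-subject noise.  ICC = 1 means an individual's repeated scores are
identical; high values mean scores cluster tightly within individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FIXED_EFFECTS = ("sitting_number", "days_from_first", "none")


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    var_between: float
    var_within: float
    n_subjects: int
    n_obs: int
    fixed_effect: str
    estimator: str = "reml"   # "reml" or "moments" (fallback)

    def __post_init__(self):
        if self.var_between < 0 or self.var_within < 0:
            raise ValueError("variance components must be >= 0")


def _moment_components(df: pd.DataFrame, score_col: str,
                       subject_col: str) -> tuple[float, float]:
    """One-way ANOVA method-of-moments variance components on a
    (possibly detrended) panel; negative estimates truncated at 0."""
    groups = df.groupby(subject_col)[score_col]
    k = groups.ngroups
    n = len(df)
    grand = df[score_col].mean()
    ssb = float((groups.size() * (groups.mean() - grand) ** 2).sum())
    ssw = float(((df[score_col] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    # average group size correction for unbalanced designs
    sizes = groups.size().to_numpy(dtype=float)
    n0 = (n - (sizes ** 2).sum() / n) / (k - 1)
    var_b = max((msb - msw) / n0, 0.0)
    return var_b, max(msw, 0.0)


def icc_mixed(data: pd.DataFrame, fixed_effect: str = "sitting_number",
              score_col: str = "score_90s", subject_col: str = "subject_id",
              sitting_col: str = "sitting", days_col: str = "days_from_first",
              sitting_as_factor: bool = False) -> ReliabilityReport:
    """Intraclass correlation from a random-intercept mixed model.

    ``fixed_effect`` chooses the covariate absorbing the shared trend:
    the sitting number (default, entered as a linear slope, or as a
    categorical factor with ``sitting_as_factor=True``) or days from the
    first test.  Variance components are estimated by REML; on
    convergence failure the report falls back to method-of-moments
    components on fixed-effect-detrended scores and is flagged.
    """
    if fixed_effect not in FIXED_EFFECTS:
        raise ValueError(f"fixed_effect must be one of {FIXED_EFFECTS}")
    df = data.dropna(subset=[score_col]).copy()
    sizes = df.groupby(subject_col).size()
    if len(sizes) < 2 or (sizes >= 2).sum() < 2:
        raise ValueError("ICC needs >= 2 subjects with >= 2 sittings each")

    y = df[score_col].to_numpy(dtype=float)
    if fixed_effect == "sitting_number":
        t = df[sitting_col].to_numpy(dtype=float)
    elif fixed_effect == "days_from_first":
        t = df[days_col].to_numpy(dtype=float)
    else:
        t = None
    if t is None:
        X = np.ones((len(df), 1))
    elif sitting_as_factor:
        X = pd.get_dummies(t.astype(int), drop_first=False,
                           dtype=float).to_numpy()
    else:
        X = np.column_stack([np.ones_like(y), t])

    import statsmodels.api as sm

    estimator = "reml"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=df[subject_col]).fit(reml=True)
        var_b = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
        var_w = max(float(fit.scale), 0.0)
        if not np.isfinite(var_b) or not np.isfinite(var_w):
            raise np.linalg.LinAlgError("non-finite variance components")
    except Exception:
        estimator = "moments"
        detr = df.copy()
        if t is not None:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            detr[score_col] = y - X @ beta + float(np.mean(y))
        var_b, var_w = _moment_components(detr, score_col, subject_col)

    total = var_b + var_w
    icc = var_b / total if total > 0 else 1.0
    return ReliabilityReport(icc=float(icc), var_between=var_b,
                             var_within=var_w, n_subjects=int(len(sizes)),
                             n_obs=int(len(df)), fixed_effect=fixed_effect,
                             estimator=estimator)


@dataclass(frozen=True)
class TestRetestResult:
    rho: float
    ci_low: float
    ci_high: float
    r_squared: float
    p_value: float
    n: int


def test_retest(x_t1, x_t2, alpha: float = 0.05) -> TestRetestResult:
    """Six-month (or any interval) test-retest association.

    Returns the Spearman rank correlation with a Fisher-z CI, the
    squared Pearson correlation of the same pairs, and the Spearman
    p-value.
    """
    x1 = np.asarray(x_t1, dtype=float)
    x2 = np.asarray(x_t2, dtype=float)
    if x1.shape != x2.shape or x1.size < 4:
        raise ValueError("test_retest needs >= 4 paired observations")
    if np.all(x1 == x1[0]) or np.all(x2 == x2[0]):
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(x1, x2)
    rho = float(res.statistic)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    if abs(rho) >= 1 - 1e-12:
        lo = hi = rho
    else:
        se = 1.0 / np.sqrt(x1.size - 3)
        z = np.arctanh(rho)
        lo, hi = np.tanh(z - z_crit * se), np.tanh(z + z_crit * se)
    r = float(stats.pearsonr(x1, x2).statistic)
    return TestRetestResult(rho=rho, ci_low=float(lo), ci_high=float(hi),
                            r_squared=r * r, p_value=float(res.pvalue),
                            n=int(x1.size))
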