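"""Criterion validity against MRI: feature correlations, elastic-net
models on a stratified train/validation split, and rearrangement of the
fitted model into the adjusted digital-biomarker formula.

The headline model regresses the SDMT score on brain parenchymal
fraction (BPFr) and T2 lesion load (T2LL) while controlling for motoric
and demographic covariates (dominant-hand taps, age; optionally NeurEx
subsystem scores).  Because the fit is affine, it can be rearranged so
the covariate-adjusted app score estimates the MRI composite directly::

    55.5*BPFr - 306.5*T2LL  =  App SDMT - 0.24*DH_taps + 0.16*Age + 5.9

which is the "adjusted SDMT" digital biomarker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from digibench.agreement import ConcordanceResult, lin_ccc

SIGNIFICANCE_TIERS = (0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation split: tertile bins of age crossed
    with tertile bins of the SDMT score (9 strata)."""

    train_fraction: float = 2 / 3
    n_age_bins: int = 3
    n_score_bins: int = 3
    seed: int = 0


@dataclass
class BiomarkerModel:
    outcome: str
    coefficients: dict            # original-scale weights by column
    intercept: float
    l1_ratio: float
    alpha: float
    n_train: int
    dropped: tuple = ()
    validation_metrics: dict | None = None

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        out = np.full(len(df), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * df[name].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class AdjustedBiomarker:
    """The rearranged affine map: covariate-adjusted app SDMT as a
    direct estimate of the model's MRI composite."""

    taps_coef: float
    age_coef: float
    intercept: float

    def __call__(self, app_sdmt, dh_taps, age):
        app = np.asarray(app_sdmt, dtype=float)
        out = (app - self.taps_coef * np.asarray(dh_taps, dtype=float)
               - self.age_coef * np.asarray(age, dtype=float)
               - self.intercept)
        return float(out) if out.ndim == 0 else out


def correlation_matrix(profiles: pd.DataFrame, features: list[str],
                       min_pairs: int = 4):
    """Pairwise-complete Spearman correlation matrix with p-values.

    Returns ``(rho, p, stars)`` DataFrames; stars mark the significance
    tiers ``* p<0.01, ** p<0.001, *** p<0.0001``.  Cells with fewer than
    ``min_pairs`` complete pairs are NaN (flagged not-computable).
    """
    k = len(features)
    rho = pd.DataFrame(np.eye(k), index=features, columns=features)
    pmat = pd.DataFrame(np.zeros((k, k)), index=features, columns=features)
    for i, a in enumerate(features):
        for j, b in enumerate(features):
            if j <= i:
                continue
            sub = profiles[[a, b]].dropna()
            if len(sub) < min_pairs:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                pmat.loc[a, b] = pmat.loc[b, a] = np.nan
                continue
            res = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = float(res.statistic)
            pmat.loc[a, b] = pmat.loc[b, a] = float(res.pvalue)
    stars = pmat.map(
        lambda p: "" if not np.isfinite(p) else
        "***" if p < SIGNIFICANCE_TIERS[2] else
        "**" if p < SIGNIFICANCE_TIERS[1] else
        "*" if p < SIGNIFICANCE_TIERS[0] else "")
    np.fill_diagonal(stars.values, "")
    return rho, pmat, stars


def split_cohort(profiles: pd.DataFrame, spec: SplitSpec,
                 score_col: str = "app_sdmt", age_col: str = "age",
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified split into training and validation sets.

    Strata are the cross-tabulated age and score tertiles; within each
    stratum a seeded shuffle assigns ``train_fraction`` of subjects to
    training.  Single-member strata go to training with a warning.
    """
    if len(profiles) < 12:
        raise ValueError("stratified split needs >= 12 subjects")
    df = profiles.reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)

    def bins(col, n):
        return pd.qcut(df[col].rank(method="first"), n, labels=False)

    strata = (bins(age_col, spec.n_age_bins) * spec.n_score_bins
              + bins(score_col, spec.n_score_bins))
    train_idx: list[int] = []
    for _, members in df.groupby(strata).groups.items():
        members = np.asarray(list(members))
        if members.size == 1:
            warnings.warn("single-member stratum assigned to training",
                          stacklevel=2)
            train_idx.extend(members.tolist())
            continue
        perm = rng.permutation(members)
        n_train = int(round(spec.train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train].tolist())
    mask = df.index.isin(train_idx)
    return df[mask].copy(), df[~mask].copy()


def fit_biomarker_model(train: pd.DataFrame, outcome: str = "app_sdmt",
                        predictors=("bpfr", "t2ll"),
                        covariates=("dh_taps", "age"),
                        l1_ratio: float = 0.5, alpha: float | None = None,
                        cv: int = 10, seed: int = 0) -> BiomarkerModel:
    """Elastic-net fit of an SDMT outcome on MRI predictors + covariates.

    Features are standardized internally; the penalty strength is chosen
    by ``cv``-fold cross-validation on the training set unless ``alpha``
    is given.  Coefficients are reported back on the original scale so
    they are directly comparable to the published biomarker formula.
    Constant predictors are dropped with a warning.
    """
    from sklearn.linear_model import ElasticNet, ElasticNetCV

    cols = list(predictors) + list(covariates)
    data = train[cols + [outcome]].dropna()
    X = data[cols].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)

    sd = X.std(axis=0)
    dropped = tuple(c for c, s in zip(cols, sd) if s == 0)
    if dropped:
        warnings.warn(f"dropping constant predictor(s): {dropped}",
                      stacklevel=2)
        keep = [i for i, c in enumerate(cols) if c not in dropped]
        cols = [cols[i] for i in keep]
        X, sd = X[:, keep], sd[keep]
    mu = X.mean(axis=0)
    Xs = (X - mu) / sd

    if alpha is None:
        est = ElasticNetCV(l1_ratio=l1_ratio, cv=cv,
                           random_state=seed, max_iter=50000)
        est.fit(Xs, y)
        alpha_used = float(est.alpha_)
        coef_s, icept_s = est.coef_, float(est.intercept_)
    else:
        est = ElasticNet(alpha=max(alpha, 1e-12), l1_ratio=l1_ratio,
                         max_iter=50000)
        est.fit(Xs, y)
        alpha_used = float(max(alpha, 1e-12))
        coef_s, icept_s = est.coef_, float(est.intercept_)

    coef = coef_s / sd
    intercept = icept_s - float(np.sum(coef * mu))
    return BiomarkerModel(
        outcome=outcome,
        coefficients={c: float(w) for c, w in zip(cols, coef)},
        intercept=float(intercept), l1_ratio=float(l1_ratio),
        alpha=alpha_used, n_train=int(len(data)), dropped=dropped)


def validate_model(model: BiomarkerModel, validation: pd.DataFrame,
                   ) -> dict:
    """Held-out validation metrics: R², Spearman rho with CI, and Lin's
    CCC of predicted vs actual.  Metrics are withheld (ValueError) below
    4 validation subjects."""
    cols = list(model.coefficients) + [model.outcome]
    data = validation[cols].dropna()
    if len(data) < 4:
        raise ValueError("validation metrics withheld: fewer than 4 "
                         "complete validation subjects")
    pred = model.predict(data)
    actual = data[model.outcome].to_numpy(dtype=float)
    ss_res = float(np.sum((actual - pred) ** 2))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if np.all(pred == pred[0]):
        rho, ci = 0.0, (0.0, 0.0)
        ccc = ConcordanceResult(0.0, 0.0, 0.0, len(data))
    else:
        sp = stats.spearmanr(actual, pred)
        rho = float(sp.statistic)
        se = 1.0 / np.sqrt(max(len(data) - 3, 1))
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
        ccc = lin_ccc(actual, pred)
    metrics = {"r2": r2, "rho": rho, "rho_ci": ci, "ccc": ccc.ccc,
               "ccc_ci": (ccc.ci_low, ccc.ci_high), "n": int(len(data))}
    model.validation_metrics = metrics
    return metrics


def to_adjusted_biomarker(model: BiomarkerModel,
                          taps_col: str = "dh_taps",
                          age_col: str = "age") -> AdjustedBiomarker:
    """Rearrange a fitted model into the adjusted-SDMT formula.

    For a fit ``outcome = w_b*BPFr + w_t*T2LL + w_taps*taps + w_age*age
    + b`` the covariate-adjusted score ``outcome - w_taps*taps -
    w_age*age - b`` equals the MRI-side prediction ``w_b*BPFr +
    w_t*T2LL`` exactly (algebraic identity).
    """
    missing = [c for c in (taps_col, age_col)
               if c not in model.coefficients]
    if missing:
        raise ValueError(
            f"model lacks required covariate(s) {missing}; cannot form "
            "the adjusted biomarker")
    return AdjustedBiomarker(
        taps_coef=model.coefficients[taps_col],
        age_coef=model.coefficients[age_col],
        intercept=model.intercept)


#: the published adjusted-biomarker map (App - 0.24*taps + 0.16*age + 5.9)
PUBLISHED_ADJUSTMENT = AdjustedBiomarker(taps_coef=0.24, age_coef=-0.16,
                                         intercept=-5.9)
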