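"""Elastic-net Cox risk modeling and biochemical-recurrence labeling.

The risk model is a penalized Cox proportional-hazards fit over
z-normalized features: penalty lambda * [alpha * ||b||_1 +
(1 - alpha) * ||b||_2^2 / 2] with mixing alpha = 0.5, lambda chosen by
10-fold cross-validated partial-likelihood deviance (Verweij &
van Houwelingen), Breslow tie handling.  Normalization (mean 0, SD 1) is
always fit on training data and applied unchanged to validation data, so
per-feature hazard ratios e^beta are per-SD and comparable.

The continuous risk score is the logistic of the linear predictor,
mapping it to [0, 1]; a threshold learned on training scores (maximizing
the logrank chi-square over candidate cuts) stratifies patients into
low/high-risk categories.  A patient exactly at the threshold is
low-risk (strict inequality).

The published six-feature gland-lumen model ships with per-SD weights;
its normalization (mu/sigma) must come from a reference cohort before it
can score anyone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io_core import ValidationError

#: Table of per-SD hazard ratios of the published six-feature model.
PUBLISHED_MODEL_HAZARD_RATIOS: dict[str, float] = {
    "shape:mean:fd3": 1.002,
    "shape:sd:hu1": 0.932,
    "shape:median:distance_ratio": 1.100,
    "shape:p5_p95:fd6": 0.968,
    "shape:p5_p95:fd9": 0.929,
    "subgraph:kurtosis:edge_length": 0.977,
}


# ---------------------------------------------------------------------------
# BCR labeling from PSA series
# ---------------------------------------------------------------------------

def bcr_label(
    psa_series: list[tuple[float, float]], surgery_time: float = 0.0
) -> tuple[float, int]:
    """Label recurrence from a post-surgery PSA series.

    ``psa_series`` is a list of (time_in_years, psa_ng_per_ml).  A patient
    is an event (1) at the time of the *second* test strictly > 0.2 ng/mL
    (the two qualifying tests need not be consecutive); otherwise censored
    (0) at the last available test.  Patients without a qualifying test at
    least 30 days (30/365.25 y) post-surgery are excluded.
    """
    tests = sorted(
        (t - surgery_time, v) for t, v in psa_series if t - surgery_time > 0
    )
    qualifying = [t for t, _ in tests if t >= 30.0 / 365.25]
    if not qualifying:
        raise ValidationError("excluded: no PSA test >= 30 days post-surgery")
    above = [t for t, v in tests if v > 0.2]
    if len(above) >= 2:
        return above[1], 1
    return tests[-1][0], 0


# ---------------------------------------------------------------------------
# Z-normalization
# ---------------------------------------------------------------------------

def fit_zscore(X_train: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Training-set column means and SDs; sigma = 0 columns are flagged NaN.

    Validation data must be transformed with these (training) parameters.
    """
    if len(X_train) < 2:
        raise ValidationError("fit_zscore requires >= 2 rows")
    mu = X_train.mean()
    sigma = X_train.std(ddof=1)
    sigma[sigma == 0] = np.nan  # flagged; excluded downstream
    return mu, sigma


def apply_zscore(X: pd.DataFrame, mu: pd.Series, sigma: pd.Series) -> pd.DataFrame:
    usable = sigma.dropna().index
    return (X[usable] - mu[usable]) / sigma[usable]


# ---------------------------------------------------------------------------
# Breslow partial likelihood (used for cross-validated deviance)
# ---------------------------------------------------------------------------

def breslow_log_partial_likelihood(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow-approximation Cox log partial likelihood at ``beta``.

    Tied event times share one risk set (subjects with time >= t) and
    contribute d * log(sum of risk-set hazards) to the denominator.
    """
    eta = X @ beta
    order = np.argsort(time, kind="stable")
    eta_s, t_s, e_s = eta[order], time[order], event[order]
    m = eta_s.max() if len(eta_s) else 0.0
    denom = np.cumsum(np.exp(eta_s - m)[::-1])[::-1]
    ll = 0.0
    i, n = 0, len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        ev = e_s[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            ll += float(eta_s[i:j][ev].sum()) - d * (np.log(denom[i]) + m)
        i = j
    return ll


# ---------------------------------------------------------------------------
# Elastic-net Cox model
# ---------------------------------------------------------------------------

@dataclass
class CoxEnModel:
    """A fitted (or published) elastic-net Cox risk model.

    beta is on the per-SD scale (features are z-scored with mu/sigma before
    the inner product), so the hazard ratio of feature x is e^{beta_x} per
    one-SD increase.
    """

    feature_names: list[str]
    beta: np.ndarray
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    alpha: float = 0.5
    lam: float | None = None
    threshold: float | None = None
    score_scale: str = "logistic"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.feature_names) != self.beta.size:
            raise ValidationError("beta / feature_names length mismatch")

    @property
    def hazard_ratios(self) -> dict[str, float]:
        return {f: float(np.exp(b)) for f, b in zip(self.feature_names, self.beta)}

    def set_normalization(self, mu: pd.Series, sigma: pd.Series) -> None:
        self.mu = np.array([mu[f] for f in self.feature_names], dtype=float)
        self.sigma = np.array([sigma[f] for f in self.feature_names], dtype=float)
        if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
            raise ValidationError("sigma must be positive for all model features")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "mu": None if self.mu is None else np.asarray(self.mu).tolist(),
            "sigma": None if self.sigma is None else np.asarray(self.sigma).tolist(),
            "alpha": self.alpha,
            "lambda": self.lam,
            "threshold": self.threshold,
            "score_scale": self.score_scale,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxEnModel":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(
            feature_names=payload["feature_names"],
            beta=np.asarray(payload["beta"]),
            alpha=payload.get("alpha", 0.5),
            lam=payload.get("lambda"),
            threshold=payload.get("threshold"),
            score_scale=payload.get("score_scale", "logistic"),
        )
        if payload.get("mu") is not None:
            model.mu = np.asarray(payload["mu"], dtype=float)
            model.sigma = np.asarray(payload["sigma"], dtype=float)
        return model


def fit_elasticnet_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambdas: list[float] | None = None,
) -> CoxEnModel:
    """Fit a penalized Cox model with lambda chosen by 10-fold CV deviance.

    ``X`` must already be z-scored (mean 0, SD 1 on the training set).
    The lambda path comes from the coordinate-descent solver; each
    candidate is scored by the Verweij-van-Houwelingen cross-validated
    partial-likelihood deviance -2 * [ll_full(beta_k) - ll_train(beta_k)]
    summed over the 10 seeded folds, and the minimizer is refit on the
    full training set.  Returns a sparse beta (many exact zeros).
    """
    from sklearn.model_selection import KFold

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValidationError("no events in training data")
    if event.sum() < 10:
        raise ValidationError("fit_elasticnet_cox requires >= 10 events")
    Xv = X.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    l1_ratio = max(alpha, 1e-6)  # sksurv requires l1_ratio > 0
    if lambdas is None:
        path_model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, n_alphas=n_lambdas, alpha_min_ratio=0.01,
        )
    else:
        path_model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, alphas=list(lambdas),
        )
    path_model.fit(Xv, y)
    lambdas = np.asarray(path_model.alphas_)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_dev = np.zeros(len(lambdas))
    for train_idx, _ in kf.split(Xv):
        fold = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=lambdas, fit_baseline_model=False)
        fold.fit(Xv[train_idx], y[train_idx])
        # the solver may truncate the path; align fitted columns to the
        # requested lambdas, reusing the smallest fitted one beyond the end
        fitted = {round(float(a), 12): c for a, c in
                  zip(fold.alphas_, fold.coef_.T)}
        coefs = np.column_stack([
            fitted.get(round(float(lam), 12), fold.coef_[:, -1])
            for lam in lambdas
        ])
        for k in range(len(lambdas)):
            beta_k = coefs[:, k]
            ll_full = breslow_log_partial_likelihood(beta_k, Xv, time, event)
            ll_train = breslow_log_partial_likelihood(beta_k, Xv[train_idx], time[train_idx], event[train_idx])
            cv_dev[k] += -2.0 * (ll_full - ll_train)
    best = int(np.argmin(cv_dev))
    lam = float(lambdas[best])
    beta = path_model.coef_[:, best].copy()
    return CoxEnModel(
        feature_names=list(X.columns), beta=beta,
        mu=np.zeros(Xv.shape[1]), sigma=np.ones(Xv.shape[1]),
        alpha=alpha, lam=lam,
    )


# ---------------------------------------------------------------------------
# Scoring and threshold learning
# ---------------------------------------------------------------------------

def risk_score(
    model: CoxEnModel, x: pd.Series | dict | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(linear predictor, logistic score in [0,1], low/high category).

    Accepts one record (Series/dict) or a DataFrame of records; every model
    feature must be present.  Category is "high" iff score > threshold
    (strictly), so a score exactly at the threshold is low-risk.
    """
    if model.mu is None or model.sigma is None:
        raise ValidationError("model normalization (mu/sigma) not set")
    if isinstance(x, dict):
        x = pd.Series(x)
    single = isinstance(x, pd.Series)
    df = x.to_frame().T if single else x
    for f in model.feature_names:
        if f not in df.columns:
            raise ValidationError(f"missing model feature {f!r}")
    Z = (df[model.feature_names].to_numpy(dtype=float) - model.mu) / model.sigma
    lp = Z @ model.beta
    score = 1.0 / (1.0 + np.exp(-lp))
    if model.threshold is not None:
        category = np.where(score > model.threshold, "high", "low")
    else:
        category = np.full(len(lp), "", dtype=object)
    return lp, score, category


def learn_threshold(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Training-set threshold maximizing the two-group logrank chi-square.

    Candidate cuts are the observed scores between the 10th and 90th
    percentiles; ties in chi-square resolve to the lower threshold.
    Scoring convention: high-risk iff score > threshold.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 10:
        raise ValidationError("learn_threshold requires >= 10 events")
    if np.allclose(scores, scores[0]):
        raise ValidationError("degenerate: all scores equal")
    lo, hi = np.percentile(scores, [10, 90])
    candidates = np.unique(scores[(scores >= lo) & (scores <= hi)])
    best_t, best_chi2 = None, -np.inf
    for t in candidates:
        high = scores > t
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        res = logrank_test(time[high], time[~high], event[high], event[~high])
        chi2 = float(res.test_statistic)
        if chi2 > best_chi2 + 1e-12:  # strict improvement; ties keep lower t
            best_chi2, best_t = chi2, float(t)
    if best_t is None:
        raise ValidationError("no admissible threshold candidate")
    return best_t


def median_threshold(scores: np.ndarray) -> float:
    """Config alternative: median split."""
    return float(np.median(scores))


# ---------------------------------------------------------------------------
# Published model and Histotyping+
# ---------------------------------------------------------------------------

def published_model() -> CoxEnModel:
    """The published six-feature gland-lumen model (per-SD weights).

    beta_x = ln(HR_x); normalization mu/sigma must be supplied from a
    reference cohort (set_normalization) before scoring, and a threshold
    must be learned before categorization.
    """
    names = list(PUBLISHED_MODEL_HAZARD_RATIOS)
    beta = np.log([PUBLISHED_MODEL_HAZARD_RATIOS[n] for n in names])
    return CoxEnModel(feature_names=names, beta=beta, alpha=0.5)


def histotyping_plus(
    scores: np.ndarray,
    clinical: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    seed: int = 0,
    alpha: float = 0.5,
    n_folds: int = 10,
) -> tuple[CoxEnModel, pd.DataFrame]:
    """Combined model over {risk score, log2 PSA, grade-group dummies}.

    Grade groups are reference-coded against group 1 (dummies gg2..gg5;
    a group absent from training drops its dummy with a warning).  The
    design is z-scored, fit with the same elastic-net Cox procedure, and
    a new threshold is learned downstream by the caller.  Returns the
    model and the raw (pre-z-score) design matrix.
    """
    import logging

    logger = logging.getLogger("histotyping")
    design = pd.DataFrame(index=clinical.index)
    design["histotyping_score"] = np.asarray(scores, dtype=float)
    design["log2_psa"] = np.log2(clinical["psa_preop"].to_numpy(dtype=float))
    for g in (2, 3, 4, 5):
        col = (clinical["grade_group"].to_numpy(dtype=float) == g).astype(float)
        if col.sum() == 0:
            logger.warning("grade group %d absent from training; dummy dropped", g)
            continue
        design[f"grade_group_{g}"] = col
    mask = design.notna().all(axis=1).to_numpy()
    design = design.loc[mask]
    mu, sigma = fit_zscore(design)
    Z = apply_zscore(design, mu, sigma)
    model = fit_elasticnet_cox(
        Z, np.asarray(time)[mask], np.asarray(event)[mask],
        alpha=alpha, n_folds=n_folds, seed=seed,
    )
    model = CoxEnModel(
        feature_names=list(Z.columns), beta=model.beta, alpha=alpha, lam=model.lam,
    )
    model.set_normalization(mu, sigma)
    return model, design
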