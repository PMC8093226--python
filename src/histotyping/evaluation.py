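"""Survival evaluation: Kaplan-Meier/logrank, Harrell's c-index, paired
bootstrap model comparison, multivariable Cox, subgroup analysis with
Bonferroni correction, and the commercial genomic-score risk categories.

Conventions (pinned):

* c-index follows Harrell's original rules — a pair is comparable iff the
  smaller observed time is an event; ties in score count 0.5; orientation
  is higher score = higher risk (earlier event), so perfect risk ranking
  gives 1 and perfect anti-ranking gives 0;
* the Bonferroni-corrected significance threshold is reported to four
  decimal places (0.05 / 15 = 0.0033);
* genomic-score categories: low < 0.45, high > 0.60, both endpoints
  inclusive to intermediate; merged mode pools low + intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io_core import ValidationError


@dataclass
class EvalReport:
    """Two-group survival evaluation results."""

    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    cindex: float
    cindex_ci: tuple[float, float] | None
    km_curves: dict[str, pd.DataFrame]
    median_years_to_event: dict[str, float]
    n_per_group: dict[str, int]


# ---------------------------------------------------------------------------
# Kaplan-Meier and logrank
# ---------------------------------------------------------------------------

def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve with at-risk counts."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tab = kmf.event_table
    out = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        }
    )
    out["at_risk"] = tab["at_risk"].reindex(out["time"]).to_numpy()
    return out


def km_logrank(
    groups: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[dict[str, pd.DataFrame], float]:
    """Per-group KM curves and the two-sample logrank p.

    With no events in either group the logrank test is undefined and the
    p-value is reported as NaN.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValidationError("km_logrank requires exactly 2 groups")
    curves = {}
    for lab in labels:
        sel = groups == lab
        if sel.sum() == 0:
            raise ValidationError(f"group {lab!r} is empty")
        curves[str(lab)] = km_curve(time[sel], event[sel])
    if event.sum() == 0:
        return curves, float("nan")
    a = groups == labels[0]
    res = logrank_test(time[a], time[~a], event[a], event[~a])
    return curves, float(res.p_value)


# ---------------------------------------------------------------------------
# Harrell's c-index
# ---------------------------------------------------------------------------

def harrell_cindex(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Concordant / comparable pairs; NaN when no pair is comparable."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(scores)
    if n < 2:
        raise ValidationError("harrell_cindex requires n >= 2")
    concordant = 0.0
    comparable = 0
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = time[i], time[j]
            if ti == tj:
                # comparable only if exactly one is an event; the event
                # subject is the earlier failure
                if event[i] + event[j] != 1:
                    continue
                first, second = (i, j) if event[i] == 1 else (j, i)
            elif ti < tj:
                if event[i] != 1:
                    continue
                first, second = i, j
            else:
                if event[j] != 1:
                    continue
                first, second = j, i
            comparable += 1
            if scores[first] > scores[second]:
                concordant += 1.0
            elif scores[first] == scores[second]:
                concordant += 0.5
    if comparable == 0:
        return float("nan")
    return concordant / comparable


# ---------------------------------------------------------------------------
# Bootstrap model comparison
# ---------------------------------------------------------------------------

def bootstrap_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired patient-level bootstrap comparison of two risk scores.

    Returns 2.5/97.5 percentile CIs of each model's c-index, the fraction
    of iterations where model A wins (ties count 0.5), and the two-tailed
    paired t-test p on the per-iteration c-index differences (1.0 when the
    scores are identical).
    """
    import logging

    if n_boot < 100:
        logging.getLogger("histotyping").warning(
            "bootstrap_compare with B=%d < 100 iterations", n_boot
        )
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(time)):
        raise ValidationError("bootstrap_compare requires one cohort for A and B")
    rng = np.random.default_rng(seed)
    n = len(time)
    ca = np.empty(n_boot)
    cb = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ca[b] = harrell_cindex(scores_a[idx], time[idx], event[idx])
        cb[b] = harrell_cindex(scores_b[idx], time[idx], event[idx])
    ok = np.isfinite(ca) & np.isfinite(cb)
    ca, cb = ca[ok], cb[ok]
    diff = ca - cb
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.ttest_1samp(diff, 0.0).pvalue)
    return {
        "cindex_a": harrell_cindex(scores_a, time, event),
        "cindex_b": harrell_cindex(scores_b, time, event),
        "ci_a": (float(np.percentile(ca, 2.5)), float(np.percentile(ca, 97.5))),
        "ci_b": (float(np.percentile(cb, 2.5)), float(np.percentile(cb, 97.5))),
        "win_fraction": float(np.mean((ca > cb) + 0.5 * (ca == cb))),
        "p": p,
        "n_boot": int(ok.sum()),
    }


# ---------------------------------------------------------------------------
# Multivariable Cox
# ---------------------------------------------------------------------------

def multivariable_cox(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Unpenalized Cox fit; per-covariate HR (95% CI) and p.

    Complete-case analysis; requires >= 10 events after case deletion.
    Rank-deficient designs raise an error naming the collinear columns.
    """
    cols = [time_col, event_col] + covariates
    df = data[cols].dropna()
    if df[event_col].sum() < 10:
        raise ValidationError("multivariable_cox requires >= 10 complete-case events")
    X = df[covariates].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) < len(covariates) + 1:
        corr = pd.DataFrame(X, columns=covariates).corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [
            f"{a} ~ {b}"
            for a in covariates
            for b in covariates
            if a < b and corr.loc[a, b] > 0.999999
        ]
        raise ValidationError(
            "rank-deficient design; collinear columns: " + (", ".join(pairs) or "unknown")
        )
    cph = CoxPHFitter()
    cph.fit(df, duration_col=time_col, event_col=event_col)
    summary = cph.summary
    return pd.DataFrame(
        {
            "hazard_ratio": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )


def table2_design(
    clinical: pd.DataFrame,
    scores: np.ndarray,
    categories: np.ndarray | None = None,
) -> pd.DataFrame:
    """The multivariable design: risk score (per 0.1 or categorical),
    grade-group dummies (reference group 1), margins, log2 PSA, stage."""
    design = pd.DataFrame(index=clinical.index)
    if categories is not None:
        design["histotyping_high"] = (np.asarray(categories) == "high").astype(float)
    else:
        design["histotyping_per_0.1"] = np.asarray(scores, dtype=float) / 0.1
    for g in (2, 3, 4, 5):
        design[f"grade_group_{g}"] = (
            clinical["grade_group"].to_numpy(dtype=float) == g
        ).astype(float)
    design["margins_positive"] = clinical["margins_positive"].astype(float)
    design["log2_psa"] = np.log2(clinical["psa_preop"].to_numpy(dtype=float))
    design["stage_ge_T2b"] = clinical["stage_ge_T2b"].astype(float)
    design["time"] = clinical["time"].to_numpy(dtype=float)
    design["event"] = clinical["event"].to_numpy(dtype=float)
    return design


# ---------------------------------------------------------------------------
# Subgroup analysis
# ---------------------------------------------------------------------------

def bonferroni_threshold(k: int, family_alpha: float = 0.05) -> float:
    """alpha / k, reported to 4 decimal places."""
    return round(family_alpha / k, 4)


def subgroup_analysis(
    clinical: pd.DataFrame,
    categories: np.ndarray,
    subgroups: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-subgroup logrank p and HR with a Bonferroni significance flag.

    Each subgroup is a boolean mask over ``clinical``; subgroups with < 2
    patients in either risk group are skipped with a reason.  The
    significance threshold is 0.05 / k, k the number of subgroups tested.
    """
    categories = np.asarray(categories)
    k = len(subgroups)
    thr = bonferroni_threshold(k)
    rows = []
    for name, mask in subgroups.items():
        mask = np.asarray(mask, dtype=bool)
        sub = clinical.loc[mask]
        cat = categories[mask]
        high = cat == "high"
        if high.sum() < 2 or (~high).sum() < 2:
            rows.append(
                {"subgroup": name, "n": int(mask.sum()), "p": np.nan,
                 "hazard_ratio": np.nan, "significant": False,
                 "skipped": "fewer than 2 patients per risk group"}
            )
            continue
        t = sub["time"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=int)
        res = logrank_test(t[high], t[~high], e[high], e[~high])
        df = pd.DataFrame({"time": t, "event": e, "high": high.astype(float)})
        try:
            cph = CoxPHFitter().fit(df, "time", "event")
            hr = float(np.exp(cph.params_["high"]))
        except Exception:
            hr = np.nan
        p = float(res.p_value)
        rows.append(
            {"subgroup": name, "n": int(mask.sum()), "p": p,
             "hazard_ratio": hr, "significant": bool(p < thr), "skipped": ""}
        )
    out = pd.DataFrame(rows).set_index("subgroup")
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["k"] = k
    return out


# ---------------------------------------------------------------------------
# Genomic-score risk categories
# ---------------------------------------------------------------------------

def decipher_categorize(score: float, merged: bool = False) -> str:
    """Risk category from a [0, 1] genomic classifier score.

    low < 0.45, high > 0.60, else intermediate (both endpoints inclusive
    to intermediate); merged mode pools low + intermediate as "low_int".
    """
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score {score} outside [0, 1]")
    if score > 0.60:
        return "high"
    cat = "low" if score < 0.45 else "intermediate"
    if merged:
        return "low_int" if cat in ("low", "intermediate") else "high"
    return cat


def evaluate_risk_groups(
    categories: np.ndarray, time: np.ndarray, event: np.ndarray,
    scores: np.ndarray | None = None,
) -> EvalReport:
    """Full two-group evaluation: KM, logrank, HR, c-index, medians."""
    categories = np.asarray(categories)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    curves, p = km_logrank(categories, time, event)
    high = categories == "high"
    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(float)})
    cph = CoxPHFitter().fit(df, "time", "event")
    hr = float(np.exp(cph.params_["high"]))
    ci = (
        float(np.exp(cph.confidence_intervals_.iloc[0, 0])),
        float(np.exp(cph.confidence_intervals_.iloc[0, 1])),
    )
    c = harrell_cindex(
        scores if scores is not None else high.astype(float), time, event
    )
    medians = {}
    for lab in ("low", "high"):
        sel = categories == lab
        et = time[sel & (event == 1)]
        medians[lab] = float(np.median(et)) if et.size else float("nan")
    return EvalReport(
        logrank_p=p, hazard_ratio=hr, hr_ci=ci, cindex=c, cindex_ci=None,
        km_curves=curves, median_years_to_event=medians,
        n_per_group={lab: int((categories == lab).sum()) for lab in set(categories.tolist())},
    )
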