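"""Survival analysis: Kaplan-Meier curves, log-rank tests, median-split
biomarker screens, and Cox proportional-hazards screening of clinical
covariates (Efron tie handling, the lifelines default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import SurvivalTable


@dataclass
class KMEstimate:
    """Product-limit estimate evaluated at the event times."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time


def km_curve(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator for one group.

    Censored observations reduce the risk set without a survival step;
    with no events at all the estimate stays at 1 (empty step arrays).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    if len(ev) == 0:
        return KMEstimate(np.array([]), np.array([]), np.array([]), np.array([]))
    ts = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ts, kmf.survival_function_.columns[0]].to_numpy()
    return KMEstimate(
        ts,
        ev["at_risk"].to_numpy(dtype=int),
        ev["observed"].to_numpy(dtype=int),
        surv,
    )


def km_by_group(times, events, groups) -> dict:
    """Per-group :func:`km_curve`; empty groups are an error upstream."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    return {val: km_curve(t[g == val], e[g == val]) for val in pd.unique(g)}


def logrank_test(times_a, events_a, times_b, events_b) -> tuple:
    """One-degree-of-freedom log-rank test between two groups.

    Returns (chi-square statistic, p-value); with no events anywhere the
    convention is (0, 1).
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


@dataclass
class MedianSplitResult:
    groups: pd.Series  # sample -> "low" | "high"
    median: float
    statistic: float
    p_value: float


def median_split_screen(values: pd.Series, survival: SurvivalTable) -> MedianSplitResult:
    """Split samples at the feature median (ties to the low group) and
    log-rank test the two survival curves."""
    v = values.loc[survival.data.index].astype(float)
    if v.nunique() < 2:
        raise ValueError("constant feature cannot be median-split")
    med = float(np.median(v))
    groups = pd.Series(np.where(v > med, "high", "low"), index=v.index)
    hi = groups == "high"
    stat, p = logrank_test(
        survival.os_days[hi], survival.event[hi],
        survival.os_days[~hi], survival.event[~hi],
    )
    return MedianSplitResult(groups, med, stat, p)


@dataclass
class CoxScreenRow:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    risk_factor: bool
    estimable: bool = True


def _cox_rows(df: pd.DataFrame, covariates: list, p_flag: float) -> list:
    rows = []
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_days", event_col="event")
    except Exception:
        return [
            CoxScreenRow(c, np.nan, np.nan, np.nan, np.nan, False, estimable=False)
            for c in covariates
        ]
    summ = cph.summary
    for c in covariates:
        if c not in summ.index:
            rows.append(CoxScreenRow(c, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        r = summ.loc[c]
        rows.append(
            CoxScreenRow(
                c,
                float(r["exp(coef)"]),
                float(r["exp(coef) lower 95%"]),
                float(r["exp(coef) upper 95%"]),
                float(r["p"]),
                bool(r["p"] < p_flag),
            )
        )
    return rows


def cox_screen(
    survival: SurvivalTable,
    covariates: list | None = None,
    mode: str = "univariate",
    p_flag: float = 0.05,
) -> list:
    """Cox PH screen of clinical covariates.

    ``mode='univariate'`` fits one model per covariate; ``'multivariate'``
    one joint model. Covariates must be numeric (encode categoricals
    upstream). Constant covariates or non-convergent fits yield rows
    flagged unestimable rather than raising.
    """
    if covariates is None:
        covariates = survival.covariates
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    base = survival.data[["os_days", "event"]].astype(float)
    if int(base["event"].sum()) < 2:
        raise ValueError("need at least 2 events for Cox screening")
    rows: list = []
    if mode == "univariate":
        for c in covariates:
            x = pd.to_numeric(survival.data[c], errors="coerce")
            if x.isna().any() or x.nunique() < 2:
                rows.append(CoxScreenRow(c, np.nan, np.nan, np.nan, np.nan, False, False))
                continue
            rows.extend(_cox_rows(base.assign(**{c: x}), [c], p_flag))
    else:
        df = base.copy()
        good = []
        for c in covariates:
            x = pd.to_numeric(survival.data[c], errors="coerce")
            if x.isna().any() or x.nunique() < 2:
                rows.append(CoxScreenRow(c, np.nan, np.nan, np.nan, np.nan, False, False))
            else:
                df[c] = x
                good.append(c)
        if good:
            rows.extend(_cox_rows(df, good, p_flag))
    return rows


def stratified_prb_screen(
    profile: pd.DataFrame,
    survival: SurvivalTable,
    stratifier: pd.Series,
    prb_features: list,
    p_flag: float = 0.05,
    min_stratum: int = 4,
) -> pd.DataFrame:
    """Median-split screen of each biomarker within each clinical stratum.

    Strata smaller than ``min_stratum`` are skipped with a warning; a
    stratifier with fewer than two non-empty levels is an error. Returns a
    tidy table (stratum, feature, p_value, significant)."""
    strat = stratifier.loc[survival.data.index]
    levels = [lv for lv in pd.unique(strat)]
    if len(levels) < 2:
        raise ValueError("stratifier must define at least two non-empty strata")
    out = []
    for lv in levels:
        ids = list(strat.index[strat == lv])
        if len(ids) < min_stratum:
            warnings.warn(f"stratum {lv!r} has {len(ids)} samples; skipped", stacklevel=2)
            continue
        sub_surv = survival.restrict_samples(ids)
        for f in prb_features:
            try:
                res = median_split_screen(profile.loc[ids, f], sub_surv)
                p = res.p_value
            except ValueError:
                p = np.nan
            out.append(
                {
                    "stratum": lv,
                    "feature": f,
                    "p_value": p,
                    "significant": bool(p < p_flag) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(out)
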