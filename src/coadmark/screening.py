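"""Prognosis dichotomization and differential-feature screening.

Samples are split at 5 years (1,825 days) of overall survival into a
good-prognosis (positive) and poor-prognosis (negative) group; samples
censored before the threshold are excluded since their 5-year status is
unknowable. Each omics layer is then screened feature-wise with a
two-sided Welch t-test; the top 1,000 features by ascending p-value are
kept and further gated at P < 0.01 with fold change (poor/good means)
above 1.5 or below 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix, SurvivalTable

DEFAULT_OS_THRESHOLD = 1825.0
DEFAULT_P_MAX = 0.01
DEFAULT_FC_HI = 1.5
DEFAULT_FC_LO = 2.0 / 3.0
DEFAULT_TOP_N = 1000

POSITIVE, NEGATIVE, EXCLUDED = "positive", "negative", "excluded"


@dataclass
class PrognosisLabels:
    """Per-sample prognosis label (positive = high OS, negative = low OS,
    excluded = censored before the threshold)."""

    labels: pd.Series
    threshold_days: float

    @property
    def positive_ids(self) -> list:
        return list(self.labels.index[self.labels == POSITIVE])

    @property
    def negative_ids(self) -> list:
        return list(self.labels.index[self.labels == NEGATIVE])

    @property
    def excluded_ids(self) -> list:
        return list(self.labels.index[self.labels == EXCLUDED])

    def binary(self) -> pd.Series:
        """Labeled samples as 1 (positive) / 0 (negative), excluded dropped."""
        kept = self.labels[self.labels != EXCLUDED]
        return (kept == POSITIVE).astype(int)


def dichotomize_by_os(
    survival: SurvivalTable, threshold_days: float = DEFAULT_OS_THRESHOLD
) -> PrognosisLabels:
    """Label each sample by its 5-year survival status.

    positive iff OS > threshold; negative iff OS <= threshold with the
    death observed; excluded iff censored at or before the threshold.
    """
    os_days = survival.os_days
    event = survival.event
    lab = pd.Series(EXCLUDED, index=survival.data.index, dtype=object)
    lab[os_days > threshold_days] = POSITIVE
    lab[(os_days <= threshold_days) & (event == 1)] = NEGATIVE
    return PrognosisLabels(lab, threshold_days)


def _fold_change(mean_neg, mean_pos, global_mean: float) -> np.ndarray:
    eps = 1e-8 * abs(global_mean)
    if eps == 0.0:
        eps = 1e-8
    return (mean_neg + eps) / (mean_pos + eps)


def welch_t_screen(matrix: OmicsMatrix, labels: PrognosisLabels) -> pd.DataFrame:
    """Per-feature two-sided Welch t-test between prognosis groups.

    Returns a DataFrame indexed by feature id with columns ``p_value``,
    ``fold_change`` (poor/good group means, epsilon-guarded),
    ``mean_positive`` and ``mean_negative``. Features identical in both
    groups get t = 0, p = 1.
    """
    pos = [s for s in labels.positive_ids if s in matrix.data.columns]
    neg = [s for s in labels.negative_ids if s in matrix.data.columns]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need >=2 samples per class, got {len(pos)} positive / {len(neg)} negative"
        )
    a = matrix.data[pos].to_numpy(dtype=float)
    b = matrix.data[neg].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    mean_pos = a.mean(axis=1)
    mean_neg = b.mean(axis=1)
    # zero variance in both groups: identical means -> no evidence (p=1),
    # different means -> arbitrarily strong evidence (p=0)
    degenerate = np.isnan(p)
    p[degenerate & np.isclose(mean_pos, mean_neg)] = 1.0
    p[degenerate & ~np.isclose(mean_pos, mean_neg)] = 0.0
    fc = _fold_change(mean_neg, mean_pos, float(matrix.data.to_numpy().mean()))
    return pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "mean_positive": mean_pos,
            "mean_negative": mean_neg,
        },
        index=matrix.data.index,
    )


def select_differential(
    results: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    fc_hi: float = DEFAULT_FC_HI,
    fc_lo: float = DEFAULT_FC_LO,
    top_n: int = DEFAULT_TOP_N,
) -> list:
    """Apply the top-n ascending-p prefilter then the p/fold-change gates.

    Returns the surviving feature ids ordered by ascending p-value
    (ties broken by feature id). Empty output is allowed.
    """
    # p ascending, ties broken by feature id for a stable prefilter
    order = sorted(results.index, key=lambda f: (results.at[f, "p_value"], str(f)))
    ranked = results.loc[order].head(top_n)
    keep = ranked[
        (ranked["p_value"] < p_max)
        & ((ranked["fold_change"] > fc_hi) | (ranked["fold_change"] < fc_lo))
    ]
    return list(keep.index)


@dataclass
class TwoGroupResult:
    p_value: float
    fold_change: float
    significant_p: bool
    significant_fc: bool


def two_group_validation(
    case_values,
    control_values,
    p_max: float = 0.05,
    abs_log2fc_min: float = 1.0,
) -> TwoGroupResult:
    """Wilcoxon rank-sum + fold-change check between two sample groups
    (e.g. tumor vs normal cells for a candidate biomarker)."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(case, control, alternative="two-sided").pvalue)
    eps = 1e-8 * abs(float(pooled.mean()))
    if eps == 0.0:
        eps = 1e-8
    fc = float((case.mean() + eps) / (control.mean() + eps))
    return TwoGroupResult(
        p_value=p,
        fold_change=fc,
        significant_p=p < p_max,
        significant_fc=abs(np.log2(fc)) > abs_log2fc_min,
    )
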