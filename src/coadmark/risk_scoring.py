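"""Linear prognosis risk score (PRS).

A linear regression of the binary prognosis label (good prognosis = 1) on
a small panel of prognosis risk biomarkers yields an additive risk score
``PRS = intercept + sum_i coef_i * x_i``; the decision threshold is chosen
by maximizing Youden's J (sensitivity + specificity - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PRSModel:
    """Linear risk score over an ordered biomarker panel.

    ``means``/``stds`` hold the standardization applied to inputs before
    the linear form; they default to the identity so a model can be
    instantiated directly from published coefficients.
    """

    features: list
    coefficients: np.ndarray
    intercept: float
    threshold: float | None = None
    means: np.ndarray | None = None
    stds: np.ndarray | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.features):
            raise ValueError("coefficient count must equal feature count")
        k = len(self.features)
        if self.means is None:
            self.means = np.zeros(k)
        if self.stds is None:
            self.stds = np.ones(k)


def fit_prs(profile: pd.DataFrame, labels: pd.Series) -> PRSModel:
    """Ordinary least squares of the 0/1 prognosis label on the biomarker
    panel (samples x features), with features standardized first and the
    constants stored on the model. Rank-deficient designs are rejected."""
    y = labels.loc[profile.index].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both prognosis classes required to fit the PRS")
    X = profile.to_numpy(dtype=float)
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=0)
    if (stds == 0).any():
        bad = profile.columns[np.flatnonzero(stds == 0)[0]]
        raise ValueError(f"constant feature {bad!r} makes the design rank-deficient")
    Z = (X - means) / stds
    design = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: collinear biomarker panel")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return PRSModel(
        features=list(profile.columns),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        means=means,
        stds=stds,
    )


def score_prs(model: PRSModel, sample) -> float:
    """Evaluate the risk score for one sample (mapping or Series of
    feature -> value); missing panel features are an error."""
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    try:
        x = np.array([float(sample[f]) for f in model.features])
    except KeyError as e:
        raise ValueError(f"sample lacks panel feature {e.args[0]!r}") from None
    z = (x - model.means) / model.stds
    return float(model.intercept + model.coefficients @ z)


def score_profile(model: PRSModel, profile: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`score_prs` over a samples x features table."""
    missing = [f for f in model.features if f not in profile.columns]
    if missing:
        raise ValueError(f"profile lacks panel feature {missing[0]!r}")
    Z = (profile[model.features].to_numpy(dtype=float) - model.means) / model.stds
    return pd.Series(model.intercept + Z @ model.coefficients, index=profile.index)


def choose_threshold(scores, labels) -> tuple:
    """Score threshold maximizing Youden's J.

    Candidates are midpoints between consecutive sorted unique scores
    (samples scoring >= threshold are called good-prognosis); ties resolve
    to the lowest optimal threshold. Returns (threshold, sensitivity,
    specificity)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to choose a threshold")
    uniq = np.unique(s)
    if len(uniq) == 1:
        cands = uniq
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    for t in cands:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), float(sens), float(spec))
    return best[1], best[2], best[3]
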