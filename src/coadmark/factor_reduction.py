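"""Exploratory factor analysis over differential features and extraction
of one essential feature per factor.

Each omics layer's differential submatrix is reduced by EFA on the feature
correlation matrix (maximum-likelihood extraction with varimax rotation;
factor count by the Kaiser eigenvalue > 1 rule). Loadings are taken as
importance weights: absolute values, min-max scaled to [0,1] per factor,
and the top-weight feature of each factor becomes an "essential feature".
Factor score matrices of the chosen omics layers are concatenated, joined
with log-transformed OS, and hierarchically clustered to visualise how
well the factors separate prognosis groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import FactorAnalysis

from .containers import SurvivalTable


@dataclass
class FactorModel:
    """EFA result for one omics layer: loadings (features x factors) and
    factor scores (samples x factors)."""

    omics_type: str
    n_factors: int
    weights: pd.DataFrame
    scores: pd.DataFrame
    rotation: str = "varimax"


@dataclass
class EssentialFeatureSet:
    """Per-omics essential feature lists and their deduplicated union."""

    per_omics: dict  # omics-type -> ordered feature list

    @property
    def union(self) -> list:
        seen, out = set(), []
        for feats in self.per_omics.values():
            for f in feats:
                if f not in seen:
                    seen.add(f)
                    out.append(f)
        return out


def _drop_constant(data: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance feature rows (they have no correlation structure)."""
    sd = data.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant feature(s) before factor analysis",
            stacklevel=3,
        )
        data = data.loc[~const]
    return data


def choose_n_factors(data: pd.DataFrame) -> int:
    """Kaiser criterion: eigenvalues of the feature correlation matrix
    strictly greater than 1, floored at 1.

    ``data`` is a features x samples table (a differential submatrix).
    """
    data = _drop_constant(data)
    if len(data) < 2:
        return 1
    corr = np.corrcoef(data.to_numpy(dtype=float))
    eigvals = np.linalg.eigvalsh(corr)
    k = int((eigvals > 1.0).sum())
    k = max(k, 1)
    return min(k, len(data), data.shape[1])


def fit_efa(data: pd.DataFrame, n_factors: int, omics_type: str = "gene") -> FactorModel:
    """Fit EFA with varimax rotation on a features x samples submatrix.

    Features are standardized so the decomposition acts on the correlation
    matrix; scores are the posterior-mean (regression-type) factor scores.
    Deterministic: extraction is SVD-initialised with a fixed state.
    """
    data = _drop_constant(data)
    if n_factors > min(data.shape):
        raise ValueError(
            f"n_factors={n_factors} exceeds min(n_features, n_samples)={min(data.shape)}"
        )
    X = data.to_numpy(dtype=float).T  # samples x features
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    fa = FactorAnalysis(
        n_components=n_factors, rotation="varimax", random_state=0, max_iter=2000
    )
    scores = fa.fit_transform(X)
    weights = pd.DataFrame(
        fa.components_.T,
        index=data.index,
        columns=[f"F{j + 1}" for j in range(n_factors)],
    )
    score_df = pd.DataFrame(scores, index=data.columns, columns=weights.columns)
    return FactorModel(omics_type, n_factors, weights, score_df)


def normalize_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale |loading| to [0,1] within each factor column.

    A constant column (no spread) maps to all 0.5 with a warning.
    """
    absw = weights.abs()
    out = pd.DataFrame(index=weights.index, columns=weights.columns, dtype=float)
    for col in absw.columns:
        v = absw[col].to_numpy()
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"constant weight column {col!r}; set to 0.5", stacklevel=2)
            out[col] = 0.5
        else:
            out[col] = (v - lo) / (hi - lo)
    return out


def select_essential(normalized: pd.DataFrame) -> list:
    """Per factor, the feature with maximal normalized weight; ties break
    lexicographically by feature id; duplicates across factors collapse."""
    chosen = []
    for col in normalized.columns:
        v = normalized[col]
        top = v.max()
        candidates = sorted(str(f) for f in v.index[v == top])
        chosen.append(candidates[0])
    seen, out = set(), []
    for f in chosen:
        if f not in seen:
            seen.add(f)
            out.append(f)
    return out


def essential_features(
    differential: pd.DataFrame, omics_type: str, n_factors: int | None = None
) -> tuple:
    """Convenience: EFA -> normalized weights -> essential features for one
    omics differential submatrix. Returns (FactorModel, feature list)."""
    if n_factors is None:
        n_factors = choose_n_factors(differential)
    model = fit_efa(differential, n_factors, omics_type)
    return model, select_essential(normalize_weights(model.weights))


@dataclass
class CombinedScores:
    """Concatenated factor scores + log-OS with a hierarchical-clustering
    sample order."""

    table: pd.DataFrame  # samples x (factors + log_os)
    leaf_order: list  # sample ids in dendrogram leaf order
    linkage_matrix: np.ndarray


def combine_scores(models: list, survival: SurvivalTable) -> CombinedScores:
    """Column-concatenate factor score matrices across omics, append
    log10(OS days + 1), and average-linkage cluster the samples on the
    Euclidean distance of the standardized columns."""
    idx = models[0].scores.index
    for m in models[1:]:
        if not m.scores.index.equals(idx):
            raise ValueError("factor models do not share an aligned sample set")
    if not set(idx).issubset(set(survival.sample_ids)):
        raise ValueError("survival table does not cover the factor-model samples")
    blocks = [
        m.scores.add_prefix(f"{m.omics_type}_") for m in models
    ]
    table = pd.concat(blocks, axis=1)
    table["log_os"] = np.log10(survival.os_days.loc[idx] + 1.0)
    z = (table - table.mean()) / table.std(ddof=1).replace(0.0, 1.0)
    if len(table) > 1:
        lk = linkage(z.to_numpy(), method="average", metric="euclidean")
        order = [idx[i] for i in leaves_list(lk)]
    else:
        lk = np.empty((0, 4))
        order = list(idx)
    return CombinedScores(table, order, lk)
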