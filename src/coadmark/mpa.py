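"""Multi-omics prognostic analysis (MPA) models.

All non-empty subsets of the four omics layers (15 combinations when all
four are present) each define a classifier over the union of the member
layers' essential features. Train/test splits use Diverse Subset
(farthest-point) sampling within each prognosis class, so the training
set spans the feature space. Classifiers: logistic regression (LR), RBF
support-vector machine (SVM), Gaussian naive Bayes (NB), a single-hidden-
layer neural network (NN), random forest (RF) and ordinary least squares
on the 0/1 labels (LiR). Performance is summarised as ROC/AUC, with AUC
in the Mann-Whitney (pair-concordance) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

METHODS = ("LR", "SVM", "NB", "NN", "RF", "LiR")


def enumerate_combinations(available) -> list:
    """All non-empty omics subsets, ordered by size then lexicographically."""
    omics = sorted(set(available))
    if not omics:
        raise ValueError("no omics layers available")
    out = []
    for k in range(1, len(omics) + 1):
        out.extend(tuple(c) for c in _combinations(omics, k))
    return out


def combination_features(combo, essential_per_omics: dict) -> list:
    """Deduplicated union (first-seen order) of the member omics'
    essential feature lists."""
    seen, out = set(), []
    for omics in combo:
        for f in essential_per_omics[omics]:
            if f not in seen:
                seen.add(f)
                out.append(f)
    return out


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    seed: int


def _diverse_select(dist: np.ndarray, ids: list, n_train: int, rng) -> list:
    """Greedy farthest-point selection: random seed point, then the point
    farthest from it, then repeatedly the point with the largest mean
    distance to the selected set. Ties break by sample-id order."""
    n = len(ids)
    order = np.arange(n)
    selected = [int(rng.integers(n))]
    remaining = [i for i in order if i != selected[0]]
    while len(selected) < n_train:
        mean_d = dist[np.ix_(remaining, selected)].mean(axis=1)
        best = mean_d.max()
        # ties -> earliest sample id among the argmax set
        cand = [remaining[j] for j in np.flatnonzero(np.isclose(mean_d, best))]
        pick = min(cand, key=lambda i: ids[i])
        selected.append(pick)
        remaining.remove(pick)
    return [ids[i] for i in selected]


def diverse_subset_split(
    profile: pd.DataFrame,
    labels: pd.Series,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SplitResult:
    """Diverse Subset sampling, stratified by prognosis class.

    ``profile`` is samples x features; ``labels`` a binary/boolean series
    over the same samples. Features are z-scored and Euclidean distance
    used. Each class contributes ceil(train_fraction * class size)
    training samples; the remainder are the test set.
    """
    labels = labels.loc[profile.index]
    X = profile.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(seed)
    train: list = []
    for value in sorted(pd.unique(labels), key=str):
        mask = (labels == value).to_numpy()
        ids = [s for s, m in zip(profile.index, mask) if m]
        if len(ids) < 2:
            raise ValueError(f"class {value!r} has fewer than 2 samples")
        sub = X[mask]
        dist = cdist(sub, sub)
        n_train = ceil(train_fraction * len(ids))
        train.extend(_diverse_select(dist, ids, n_train, rng))
    train_set = set(train)
    train_ids = [s for s in profile.index if s in train_set]
    test_ids = [s for s in profile.index if s not in train_set]
    return SplitResult(train_ids, test_ids, seed)


@dataclass
class MPAModel:
    """A fitted prognosis classifier bound to an ordered feature list and
    the training-set standardization constants."""

    method: str
    features: list
    estimator: object
    means: np.ndarray
    stds: np.ndarray

    def transform(self, profile: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in profile.columns]
        if missing:
            raise ValueError(f"profile missing model feature {missing[0]!r}")
        X = profile[self.features].to_numpy(dtype=float)
        return (X - self.means) / self.stds


def _make_estimator(method: str, seed: int, hyperparams: dict | None):
    hp = hyperparams or {}
    if method == "LR":
        return LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
    if method == "SVM":
        return SVC(probability=True, random_state=seed, **hp)
    if method == "NB":
        return GaussianNB(**hp)
    if method == "NN":
        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (100,)),
            random_state=seed,
            max_iter=hp.get("max_iter", 500),
        )
    if method == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed
        )
    if method == "LiR":
        return LinearRegression()
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def train_mpa(
    train_profile: pd.DataFrame,
    train_labels: pd.Series,
    method: str = "LR",
    seed: int = 0,
    hyperparams: dict | None = None,
) -> MPAModel:
    """Fit one MPA classifier.

    Features are z-scored with training-set statistics only (stored on the
    model, reused verbatim at prediction time). ``train_labels`` is 1 for
    good prognosis (positive class), 0 for poor prognosis.
    """
    y = train_labels.loc[train_profile.index].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both prognosis classes")
    X = train_profile.to_numpy(dtype=float)
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=0)
    stds = np.where(stds > 0, stds, 1.0)
    est = _make_estimator(method, seed, hyperparams)
    est.fit((X - means) / stds, y)
    return MPAModel(method, list(train_profile.columns), est, means, stds)


def predict_scores(model: MPAModel, profile: pd.DataFrame) -> pd.DataFrame:
    """Probability-like score in [0,1] for the good-prognosis class plus
    the 0.5-threshold class call, per sample."""
    Z = model.transform(profile)
    if model.method == "LiR":
        score = np.clip(model.estimator.predict(Z), 0.0, 1.0)
    else:
        proba = model.estimator.predict_proba(Z)
        score = proba[:, list(model.estimator.classes_).index(1)]
    return pd.DataFrame(
        {"score": score, "predicted_positive": (score >= 0.5).astype(int)},
        index=profile.index,
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and Mann-Whitney AUC (ties count one half).

    AUC is the probability a random positive sample outscores a random
    negative one; the curve comes from a threshold sweep.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s)
    return ROCResult(thr, tpr, 1.0 - fpr, float(auc))
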