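"""Target regulation simulation (TRS).

For every true-negative test sample (poor prognosis by both label and
model), each essential feature — alone and in every unordered pair — is
down-regulated to the minimum value observed among good-prognosis
patients, and the sample is re-classified. A "flip" is a re-prediction to
good prognosis; features and pairs with flips form the flip network, whose
node sizes count affected patients and edge weights count pair flips.
For a binary mutation feature whose good-prognosis patients carry no
alteration, the clamp value is 0, i.e. the regulation removes the mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .mpa import MPAModel, predict_scores


@dataclass(frozen=True)
class RegulationSpec:
    """One in-silico intervention: 1 or 2 features with their clamp values."""

    features: tuple
    clamp_values: tuple

    def __post_init__(self):
        if not 1 <= len(self.features) <= 2:
            raise ValueError("a regulation targets 1 or 2 features")
        if len(self.features) != len(self.clamp_values):
            raise ValueError("one clamp value per feature required")
        if not all(np.isfinite(self.clamp_values)):
            raise ValueError("clamp values must be finite")


@dataclass
class FlipResult:
    spec: RegulationSpec
    flipped: list  # sample ids re-classified to good prognosis
    n_flipped: int


def eligible_true_negatives(
    model: MPAModel, test_profile: pd.DataFrame, test_labels: pd.Series
) -> list:
    """Samples that are poor-prognosis by label AND predicted poor by the
    model (the true-negative cell of the confusion matrix)."""
    pred = predict_scores(model, test_profile)["predicted_positive"]
    lab = test_labels.loc[test_profile.index].astype(int)
    return [s for s in test_profile.index if lab[s] == 0 and pred[s] == 0]


def clamp_value(feature: str, positive_profile: pd.DataFrame) -> float:
    """Minimum value of ``feature`` over good-prognosis patients."""
    if feature not in positive_profile.columns:
        raise ValueError(f"feature {feature!r} absent from positive profile")
    if len(positive_profile) == 0:
        raise ValueError("no positive samples to take the minimum over")
    return float(positive_profile[feature].min())


def simulate_regulation(
    model: MPAModel,
    profile: pd.DataFrame,
    eligible_ids: list,
    spec: RegulationSpec,
) -> FlipResult:
    """Clamp the spec's features in every eligible sample and re-classify.

    The input profile is left untouched; standardization reuses the
    model's stored training constants via the normal prediction path.
    """
    for f in spec.features:
        if f not in model.features:
            raise ValueError(f"feature {f!r} not in the model's feature list")
    if not eligible_ids:
        return FlipResult(spec, [], 0)
    mod = profile.loc[eligible_ids].copy()
    for f, v in zip(spec.features, spec.clamp_values):
        mod[f] = v
    pred = predict_scores(model, mod)["predicted_positive"]
    flipped = [s for s in eligible_ids if pred[s] == 1]
    return FlipResult(spec, flipped, len(flipped))


def scan_all(
    model: MPAModel,
    profile: pd.DataFrame,
    eligible_ids: list,
    features: list,
    positive_profile: pd.DataFrame,
) -> list:
    """Evaluate all n single-feature and n(n-1)/2 pair regulations.

    Returns one :class:`FlipResult` per spec (n + C(n,2) in total).
    """
    if len(features) < 1:
        raise ValueError("need at least one feature to scan")
    clamps = {f: clamp_value(f, positive_profile) for f in features}
    results = []
    for f in features:
        results.append(
            simulate_regulation(
                model, profile, eligible_ids, RegulationSpec((f,), (clamps[f],))
            )
        )
    for a, b in combinations(features, 2):
        results.append(
            simulate_regulation(
                model,
                profile,
                eligible_ids,
                RegulationSpec((a, b), (clamps[a], clamps[b])),
            )
        )
    return results


@dataclass
class FlipNetwork:
    """Features/pairs whose regulation flips patients.

    ``node_sizes`` maps each flipping feature to the number of distinct
    patients affected by it (alone or in a pair); ``edges`` maps each
    flipping pair to its flip count; ``participation`` counts, per
    feature, the flipping pairs it belongs to; ``ranked`` orders features
    by descending pair participation (ties by feature id).
    """

    node_sizes: dict
    edges: dict
    participation: dict
    ranked: list

    @property
    def n_single_flips(self) -> int:
        return sum(1 for f in self.node_sizes)  # nodes with any flip

    def to_frames(self) -> tuple:
        nodes = pd.DataFrame(
            {
                "feature": list(self.node_sizes),
                "n_patients": [self.node_sizes[f] for f in self.node_sizes],
                "pair_participation": [
                    self.participation.get(f, 0) for f in self.node_sizes
                ],
            }
        )
        edges = pd.DataFrame(
            [(a, b, w) for (a, b), w in self.edges.items()],
            columns=["feature_a", "feature_b", "n_flipped"],
        )
        return nodes, edges


def build_flip_network(results: list) -> FlipNetwork:
    """Aggregate scan results into the flip network."""
    affected: dict = {}
    edges: dict = {}
    participation: dict = {}
    for res in results:
        if res.n_flipped == 0:
            continue
        feats = res.spec.features
        for f in feats:
            affected.setdefault(f, set()).update(res.flipped)
        if len(feats) == 2:
            key = tuple(sorted(feats))
            edges[key] = edges.get(key, 0) + res.n_flipped
            for f in feats:
                participation[f] = participation.get(f, 0) + 1
    node_sizes = {f: len(s) for f, s in affected.items()}
    ranked = sorted(node_sizes, key=lambda f: (-participation.get(f, 0), str(f)))
    return FlipNetwork(node_sizes, edges, participation, ranked)
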