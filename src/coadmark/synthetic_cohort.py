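"""Seeded synthetic multi-omics cohorts with planted prognostic effects.

The generator emulates the statistical structure of a tumor cohort carrying
four omics layers (gene expression, exon expression, DNA methylation beta
values, binary somatic mutations) plus overall survival: a poor-prognosis
group whose planted continuous features sit higher than in the
good-prognosis group, planted mutations that never occur in good-prognosis
samples, and survival times whose hazard increases with a latent risk built
from the planted features. Prognosis groups are ultimately defined by the
drawn survival time (OS above/below a 5-year threshold), so planted effects
are realistically attenuated rather than perfectly separating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OMICS_TYPES, OmicsMatrix, SurvivalTable

OS_THRESHOLD_DAYS = 1825.0

#: per-omics location/scale of background (non-planted) features, on the
#: layer's native scale: log2-like expression for gene/exon, logit scale
#: for methylation (inverse-transformed to beta), Bernoulli rate for
#: mutation background.
_BACKGROUND = {
    "gene": (1.5, 1.0),
    "exon": (1.8, 1.2),
    "methylation": (-1.5, 1.0),  # logit scale
    "mutation": 0.05,  # background mutation rate
}


def _default_features() -> dict:
    return {"gene": 300, "exon": 300, "methylation": 300, "mutation": 200}


def _default_planted() -> dict:
    return {"gene": 10, "exon": 10, "methylation": 10, "mutation": 10}


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the standardized mean shift (Cohen's d) of planted
    continuous features between the poor- and good-prognosis groups;
    ``mutation_rate_negative`` the probability a planted mutation is
    present in a poor-prognosis sample; ``baseline_hazard`` the per-day
    exponential hazard at zero latent risk (default puts median OS at the
    5-year dichotomization threshold); ``risk_coefficient`` the log-hazard
    increase per unit latent risk; ``censor_rate`` the probability a
    sample is administratively censored.
    """

    n_samples: int = 200
    n_features_per_omics: dict = field(default_factory=_default_features)
    n_planted_per_omics: dict = field(default_factory=_default_planted)
    effect_size: float = 1.5
    mutation_rate_negative: float = 0.3
    baseline_hazard: float = float(np.log(2) / OS_THRESHOLD_DAYS)
    risk_coefficient: float = 1.5
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for k, n in self.n_features_per_omics.items():
            if k not in OMICS_TYPES:
                raise ValueError(f"n_features_per_omics: unknown omics {k!r}")
            if n <= 0:
                raise ValueError(f"n_features_per_omics[{k!r}] must be positive")
        for k, n in self.n_planted_per_omics.items():
            if n < 0:
                raise ValueError(f"n_planted_per_omics[{k!r}] must be non-negative")
            if n > self.n_features_per_omics.get(k, 0):
                raise ValueError(
                    f"n_planted_per_omics[{k!r}] exceeds n_features_per_omics[{k!r}]"
                )
        for name in ("mutation_rate_negative", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


@dataclass
class SyntheticCohort:
    """A generated cohort: omics layers, survival, and the planted truth."""

    omics: dict  # omics-type -> OmicsMatrix
    survival: SurvivalTable
    planted_truth: dict  # omics-type -> list of planted feature ids
    latent_risk: pd.Series  # per-sample latent risk driving the hazard

    @property
    def sample_ids(self) -> list:
        return list(self.survival.sample_ids)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a seeded cohort per ``config``.

    Continuous planted features are shifted upward by ``effect_size``
    standard deviations in a provisional high-risk half of the cohort,
    drawn independently per omics layer so the layers carry partially
    complementary risk information; the latent risk is the standardized
    mean of planted continuous values and drives an exponential OS draw,
    after which the definitive prognosis label is OS > 1,825 days. Planted mutations are then placed
    only in definitive poor-prognosis samples, so good-prognosis samples
    carry none of them, matching the mutual-exclusivity structure the
    pipeline screens for.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    # one core high-risk subgroup, perturbed per omics layer: layers agree
    # on most samples but each carries some layer-specific risk signal, so
    # single layers are informative while their combination tracks the
    # core risk best
    core_poor = np.zeros(n, dtype=bool)
    core_poor[rng.permutation(n)[: n // 2]] = True

    def _layer_poor(flip_prob: float = 0.15):
        flips = rng.random(n) < flip_prob
        return np.where(flips, ~core_poor, core_poor)

    omics: dict = {}
    planted_truth: dict = {}
    planted_cont_values = []

    for omics_type, n_feat in config.n_features_per_omics.items():
        n_plant = int(config.n_planted_per_omics.get(omics_type, 0))
        feats = [f"{omics_type[:2]}_{j:05d}" for j in range(n_feat)]
        planted = feats[:n_plant]
        planted_truth[omics_type] = list(planted)

        if omics_type == "mutation":
            rate = _BACKGROUND["mutation"]
            vals = (rng.random((n_feat, n)) < rate).astype(float)
            # planted rows are filled in after survival is drawn
            vals[:n_plant, :] = 0.0
        else:
            loc, scale = _BACKGROUND[omics_type]
            vals = rng.normal(loc, scale, size=(n_feat, n))
            shift = config.effect_size * scale
            if n_plant:
                vals[:n_plant, _layer_poor()] += shift
            if omics_type == "methylation":
                vals = _expit(vals)
            else:
                vals = np.clip(vals, 0.0, None)
            if n_plant:
                planted_cont_values.append(vals[:n_plant, :])
        omics[omics_type] = OmicsMatrix(
            omics_type, pd.DataFrame(vals, index=feats, columns=samples)
        )

    if planted_cont_values:
        stacked = np.vstack(planted_cont_values)
        per_feat = (stacked - stacked.mean(axis=1, keepdims=True)) / np.where(
            stacked.std(axis=1, keepdims=True) > 0, stacked.std(axis=1, keepdims=True), 1.0
        )
        risk = per_feat.mean(axis=0)
        sd = risk.std()
        risk = risk / sd if sd > 0 else risk * 0.0
    else:
        risk = np.zeros(n)
    latent_risk = pd.Series(risk, index=samples, name="latent_risk")

    hazard = config.baseline_hazard * np.exp(config.risk_coefficient * risk)
    os_days = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=int)
    censored = rng.random(n) < config.censor_rate
    if censored.any():
        cens_time = rng.uniform(0.0, os_days.max(), size=n)
        take = censored & (cens_time < os_days)
        os_days = np.where(take, cens_time, os_days)
        event = np.where(take, 0, event)

    # definitive prognosis group: OS above the 5-year threshold
    good = os_days > OS_THRESHOLD_DAYS
    for omics_type, n_feat in config.n_features_per_omics.items():
        if omics_type != "mutation":
            continue
        n_plant = int(config.n_planted_per_omics.get(omics_type, 0))
        if n_plant == 0:
            continue
        df = omics[omics_type].data
        plant_block = (
            rng.random((n_plant, n)) < config.mutation_rate_negative
        ).astype(float)
        plant_block[:, good] = 0.0
        df.iloc[:n_plant, :] = plant_block
        omics[omics_type] = OmicsMatrix(omics_type, df)

    survival = SurvivalTable(
        pd.DataFrame(
            {"os_days": np.round(os_days, 3), "event": event}, index=samples
        )
    )
    return SyntheticCohort(omics, survival, planted_truth, latent_risk)


def attach_clinical_covariates(
    cohort: SyntheticCohort,
    seed: int = 0,
    log_hr_age: float = 0.0,
) -> SyntheticCohort:
    """Add simple clinical covariates (age, gender, weight, stage) to the
    survival table; ``log_hr_age`` > 0 regenerates OS with an age effect so
    Cox screening has a planted signal to recover."""
    rng = np.random.default_rng(seed)
    df = cohort.survival.data.copy()
    n = len(df)
    age = rng.normal(65.0, 10.0, n)
    df["age"] = np.round(age, 1)
    df["gender"] = rng.integers(0, 2, n)
    df["weight"] = np.round(rng.normal(75.0, 12.0, n), 1)
    df["pathologic_stage"] = rng.integers(1, 5, n)
    if log_hr_age != 0.0:
        age_z = (age - age.mean()) / age.std()
        hazard = (np.log(2) / OS_THRESHOLD_DAYS) * np.exp(log_hr_age * age_z)
        df["os_days"] = np.round(rng.exponential(1.0 / hazard), 3)
        df["event"] = 1
    return SyntheticCohort(
        cohort.omics, SurvivalTable(df), cohort.planted_truth, cohort.latent_risk
    )


def generate_ppi_edges(
    gene_symbols: list,
    n_hubs: int,
    hub_degree: int,
    seed: int,
    n_extra_edges: int = 0,
) -> list:
    """Generate a deterministic undirected toy PPI edge list.

    The first ``n_hubs`` symbols are made hubs by wiring each to
    ``hub_degree`` distinct partners; ``n_extra_edges`` random non-loop
    edges are added on top. Output has no self-loops or duplicates.
    """
    symbols = list(gene_symbols)
    if n_hubs > len(symbols):
        raise ValueError("n_hubs exceeds number of symbols")
    if hub_degree <= 0:
        raise ValueError("hub_degree must be positive")
    if hub_degree > len(symbols) - 1:
        raise ValueError(
            f"hub_degree {hub_degree} impossible with {len(symbols)} symbols"
        )
    rng = np.random.default_rng(seed)
    edges: set = set()
    for hub in symbols[:n_hubs]:
        partners = [s for s in symbols if s != hub]
        chosen = rng.choice(len(partners), size=hub_degree, replace=False)
        for idx in sorted(chosen):
            edges.add(tuple(sorted((hub, partners[idx]))))
    added = 0
    attempts = 0
    target = n_extra_edges
    while added < target and attempts < 100 * max(target, 1):
        i, j = rng.choice(len(symbols), size=2, replace=False)
        e = tuple(sorted((symbols[i], symbols[j])))
        attempts += 1
        if e not in edges:
            edges.add(e)
            added += 1
    return sorted(edges)
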