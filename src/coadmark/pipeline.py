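"""End-to-end orchestration: screening -> factor reduction -> MPA ->
TRS -> risk scoring -> survival analysis -> network annotation.

Each stage writes its outputs under the run directory and contributes a
row-count entry to a machine-readable JSON manifest, so any stage can be
audited or re-run from cached upstream TSVs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import factor_reduction, mpa, network_annotation, omics_io, risk_scoring
from . import screening, survival_analysis, trs
from .containers import OmicsMatrix, SurvivalTable


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    omics_paths: dict = field(default_factory=dict)  # omics-type -> TSV path
    survival_path: str | None = None
    annotation_path: str | None = None
    ppi_path: str | None = None
    os_threshold_days: float = 1825.0
    p_max: float = 0.01
    fc_hi: float = 1.5
    fc_lo: float = 2.0 / 3.0
    top_n: int = 1000
    min_degree: int = 5
    method: str = "LR"
    n_prs_features: int = 13
    seed: int = 0
    output_dir: str = "coadmark_run"

    def validate(self) -> None:
        if not (self.fc_lo < 1.0 < self.fc_hi):
            raise ValueError("fold-change gates must satisfy fc_lo < 1 < fc_hi")
        for name in ("os_threshold_days", "p_max", "top_n", "min_degree"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.method not in mpa.METHODS:
            raise ValueError(f"unknown classifier method {self.method!r}")


def _load_inputs(config: PipelineConfig):
    matrices = [
        omics_io.read_matrix(path, omics_type)
        for omics_type, path in sorted(config.omics_paths.items())
    ]
    survival = omics_io.read_survival(config.survival_path)
    return omics_io.align_samples(matrices, survival)


def run_pipeline(
    config: PipelineConfig,
    matrices: list | None = None,
    survival: SurvivalTable | None = None,
) -> dict:
    """Run every stage in order and return the manifest dict.

    Inputs may be passed in memory (``matrices``/``survival``) or read
    from the paths in ``config``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrices is None or survival is None:
        matrices, survival, shared = _load_inputs(config)
    else:
        matrices, survival, shared = omics_io.align_samples(matrices, survival)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "os_threshold_days": config.os_threshold_days,
            "p_max": config.p_max,
            "fc_hi": config.fc_hi,
            "fc_lo": config.fc_lo,
            "top_n": config.top_n,
            "min_degree": config.min_degree,
        },
        "method": config.method,
        "n_samples": len(shared),
        "stages": {},
    }

    # 1. screening
    labels = screening.dichotomize_by_os(survival, config.os_threshold_days)
    differential: dict = {}
    for m in matrices:
        res = screening.welch_t_screen(m, labels)
        kept = screening.select_differential(
            res, config.p_max, config.fc_hi, config.fc_lo, config.top_n
        )
        differential[m.omics_type] = (m, res, kept)
        res.assign(passed=res.index.isin(kept)).to_csv(
            out / f"screen_{m.omics_type}.tsv", sep="\t"
        )
    manifest["stages"]["screening"] = {
        "n_labeled": int((labels.labels != screening.EXCLUDED).sum()),
        "n_differential": {k: len(v[2]) for k, v in differential.items()},
    }

    # 2. factor reduction
    models: dict = {}
    essential: dict = {}
    for omics_type, (m, _res, kept) in differential.items():
        if len(kept) < 2:
            warnings.warn(f"{omics_type}: <2 differential features; omics skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fmodel, feats = factor_reduction.essential_features(
                m.data.loc[kept], omics_type
            )
        models[omics_type] = fmodel
        essential[omics_type] = feats
        fmodel.weights.to_csv(out / f"efa_weights_{omics_type}.tsv", sep="\t")
        fmodel.scores.to_csv(out / f"efa_scores_{omics_type}.tsv", sep="\t")
    if not models:
        raise RuntimeError("factor_reduction: no omics layer produced factors")
    combined = factor_reduction.combine_scores(list(models.values()), survival)
    pd.Series(combined.leaf_order).to_csv(
        out / "cluster_order.tsv", sep="\t", index=False, header=["sample"]
    )
    manifest["stages"]["factor_reduction"] = {
        "n_factors": {k: m.n_factors for k, m in models.items()},
        "n_essential": {k: len(v) for k, v in essential.items()},
        "combined_width": int(combined.table.shape[1]),
    }

    # 3. MPA models over all omics combinations
    feature_profile = pd.concat(
        [differential[k][0].data.loc[essential[k]].T for k in essential], axis=1
    )
    binary = labels.binary()
    labeled = [s for s in feature_profile.index if s in binary.index]
    feature_profile = feature_profile.loc[labeled]
    combos = mpa.enumerate_combinations(essential.keys())
    auc_rows = []
    quad_model = None
    # one Diverse Subset split of the samples, on the full essential
    # profile, shared by all combination models
    split = mpa.diverse_subset_split(feature_profile, binary, seed=config.seed)
    quad_split = split
    for combo in combos:
        feats = mpa.combination_features(combo, essential)
        prof = feature_profile[feats]
        model = mpa.train_mpa(
            prof.loc[split.train_ids], binary, config.method, seed=config.seed
        )
        test_scores = mpa.predict_scores(model, prof.loc[split.test_ids])
        roc = mpa.roc_auc(test_scores["score"], binary.loc[split.test_ids])
        auc_rows.append(
            {"combination": "+".join(combo), "n_features": len(feats), "auc": roc.auc}
        )
        if len(combo) == len(essential):
            quad_model, quad_features = model, feats
    pd.DataFrame(auc_rows).to_csv(out / "mpa_auc.tsv", sep="\t", index=False)
    manifest["stages"]["mpa"] = {
        "n_combinations": len(combos),
        "best_auc": float(max(r["auc"] for r in auc_rows)),
    }

    # 4. TRS on the all-omics model
    pos_profile = feature_profile.loc[
        [s for s in feature_profile.index if binary[s] == 1], quad_features
    ]
    test_prof = feature_profile.loc[quad_split.test_ids, quad_features]
    eligible = trs.eligible_true_negatives(quad_model, test_prof, binary)
    results = trs.scan_all(quad_model, test_prof, eligible, quad_features, pos_profile)
    network = trs.build_flip_network(results)
    nodes, edges = network.to_frames()
    nodes.to_csv(out / "trs_nodes.tsv", sep="\t", index=False)
    edges.to_csv(out / "trs_edges.tsv", sep="\t", index=False)
    manifest["stages"]["trs"] = {
        "n_eligible": len(eligible),
        "n_specs": len(results),
        "n_flipping_features": len(network.node_sizes),
        "n_flipping_pairs": len(network.edges),
    }

    # 5. PRS over the top-ranked TRS features (fallback: top essential)
    panel = network.ranked[: config.n_prs_features]
    if len(panel) < 2:
        panel = quad_features[: config.n_prs_features]
    prs_prof = feature_profile[panel]
    prs_model = risk_scoring.fit_prs(prs_prof, binary)
    scores = risk_scoring.score_profile(prs_model, prs_prof)
    thr, sens, spec = risk_scoring.choose_threshold(scores, binary.loc[scores.index])
    prs_model.threshold = thr
    pd.DataFrame(
        {"feature": prs_model.features, "coefficient": prs_model.coefficients}
    ).to_csv(out / "prs_model.tsv", sep="\t", index=False)
    manifest["stages"]["risk_scoring"] = {
        "n_panel": len(panel),
        "threshold": thr,
        "sensitivity": sens,
        "specificity": spec,
        "auc": mpa.roc_auc(scores, binary.loc[scores.index]).auc,
    }

    # 6. survival analysis of the model's test-set predictions
    test_pred = mpa.predict_scores(quad_model, test_prof)["predicted_positive"]
    surv_test = survival.restrict_samples(list(test_prof.index))
    grp = test_pred.to_numpy()
    if len(np.unique(grp)) == 2:
        stat, p = survival_analysis.logrank_test(
            surv_test.os_days[grp == 1], surv_test.event[grp == 1],
            surv_test.os_days[grp == 0], surv_test.event[grp == 0],
        )
    else:
        stat, p = float("nan"), float("nan")
    cox_rows = []
    if survival.covariates:
        cox_rows = survival_analysis.cox_screen(survival, mode="univariate")
        pd.DataFrame([r.__dict__ for r in cox_rows]).to_csv(
            out / "cox_screen.tsv", sep="\t", index=False
        )
    manifest["stages"]["survival_analysis"] = {
        "logrank_statistic": stat,
        "logrank_p": p,
        "n_cox_covariates": len(cox_rows),
    }

    # 7. network annotation
    annotation = (
        omics_io.read_annotation(config.annotation_path)
        if config.annotation_path
        else {f: f for feats in essential.values() for f in feats}
    )
    mapping = network_annotation.map_to_symbols(essential, annotation)
    edges_list = omics_io.read_edge_list(config.ppi_path) if config.ppi_path else []
    degrees = network_annotation.compute_degrees(
        mapping.symbols, edges_list, config.min_degree
    )
    degrees.to_csv(out / "ppi_degrees.tsv", sep="\t")
    hubs = network_annotation.hub_filter(degrees, config.min_degree)
    manifest["stages"]["network_annotation"] = {
        "n_symbols": len(mapping.symbols),
        "n_hubs": len(hubs),
    }

    manifest["completed_stages"] = list(manifest["stages"].keys())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
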