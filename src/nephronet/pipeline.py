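"""End-to-end pipeline tying the stages together.

``run_pipeline`` executes simulate/ingest -> impute -> reference network ->
perturbation networks -> feature extraction -> stratification -> severity
ordering -> prognostic evaluation -> surrogate interpretation -> omics
contrasts, persisting every intermediate under an artifacts directory and
logging the fully resolved configuration.  Deterministic given the seeds in
the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import io as nio
from .evaluate import (
    cluster_label_auc,
    cox_adjusted,
    logrank_test,
    treatment_contrast,
)
from .interpret import attribute_features, fit_surrogate
from .networks import build_reference_network, perturb_cohort
from .omics import (
    compute_vip,
    fit_plsda,
    fold_change,
    qc_filter,
    regroup_risk,
    sum_normalize,
)
from .preprocess import ReductionConfig
from .features import default_catalog, feature_matrix
from .schema import CohortTable
from .simulate import (
    SimConfig,
    generate_omics,
    generate_patients,
    generate_reference,
    generate_survival,
    generate_trajectories,
)
from .stratify import KMN, SchemeSpec, StratifiedCohort, assign_new, fit_scheme


@dataclass
class PipelineConfig:
    scheme: SchemeSpec = field(default_factory=lambda: KMN)
    alpha: float = 0.05
    reduction: ReductionConfig | None = None  # defaults to the run seed
    seed: int = 1
    sim: SimConfig | None = None
    run_omics: bool = True
    run_interpret: bool = True
    surrogate_folds: int = 10
    auc_rounds: int = 10
    auc_folds: int = 10

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        d = {
            "scheme": {"algorithm": self.scheme.algorithm,
                       "feature_source": self.scheme.feature_source,
                       "k": self.scheme.k},
            "alpha": self.alpha,
            "reduction": enc(self.reduction),
            "seed": self.seed,
            "run_omics": self.run_omics,
            "run_interpret": self.run_interpret,
        }
        if self.sim is not None:
            sim = {k: enc(v) for k, v in dataclasses.asdict(self.sim).items()
                   if k != "schema"}
            d["sim"] = sim
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    strata: pd.Series
    model: object
    auc: object | None = None
    logrank: tuple[float, float] | None = None
    cox: object | None = None
    report: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full KMN pipeline on a synthetic cohort and persist artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim or SimConfig(seed=config.seed)
    report: dict = {"config": config.resolved()}

    # --- simulate
    reference = generate_reference(sim)
    patients, truth = generate_patients(sim)
    survival = generate_survival(truth, sim)
    nio.write_cohort(reference, out / "reference.csv")
    nio.write_cohort(patients, out / "patients.csv")
    nio.write_survival(survival, out / "survival.csv")
    truth.subtype_labels.to_csv(out / "ground_truth_subtypes.csv",
                                index_label="patient_id")

    # --- stratify (fit includes impute -> networks -> features -> reduce)
    model = fit_scheme(
        patients, config.scheme, reference=reference, seed=config.seed,
        reduction=config.reduction or ReductionConfig(seed=config.seed),
        alpha=config.alpha,
    )
    strata = model.training_strata
    nio.write_labels(strata, config.scheme.tag, out / "labels.csv")
    joblib.dump(model, out / "cluster_model.joblib")
    report["stratum_counts"] = {int(k): int(v)
                                for k, v in strata.value_counts().sort_index().items()}

    # persist the network feature matrix for the network scheme
    if config.scheme.feature_source == "network" and model.reference is not None:
        imputed = model.imputer.apply(patients) if model.imputer else patients
        nets = perturb_cohort(model.reference, imputed, alpha=config.alpha)
        feats = feature_matrix(nets, model.catalog)
        feats.to_csv(out / "network_features.csv", index_label="patient_id")
    else:
        feats = None

    # --- evaluate
    records = survival.join(
        (model.imputer.apply(patients) if model.imputer else patients).data,
        how="left")
    stat, p = logrank_test(records, strata)
    report["logrank"] = {"statistic": stat, "p": p}
    cox = None
    try:
        cox = cox_adjusted(records, strata)
        report["cox_hr_vs_stratum1"] = {int(k): float(v)
                                        for k, v in cox.hr.items()}
    except ValueError as exc:
        report["cox_hr_vs_stratum1"] = f"not estimable: {exc}"
    auc = cluster_label_auc(
        strata, survival["event"], rounds=config.auc_rounds,
        folds=config.auc_folds, seed=config.seed)
    report["cluster_label_auc"] = {
        "cv": auc.auc_cv, "apparent": auc.auc_apparent,
        "rank_oracle": auc.auc_rank_oracle,
    }
    trajectories = generate_trajectories(truth, sim)
    trajectories.to_csv(out / "trajectories.csv", index=False)
    contrasts = {}
    for s in sorted(strata.unique()):
        sub = records.loc[strata[strata == s].index]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tc = treatment_contrast(sub, stratum=int(s))
            contrasts[int(s)] = {
                "global_logrank_p": tc.global_logrank[1],
                "combo_vs_sc_hr": (float(tc.combo_vs_sc.hr.iloc[0])
                                   if tc.combo_vs_sc is not None else None),
            }
        except ValueError as exc:
            contrasts[int(s)] = f"not estimable: {exc}"
    report["treatment_contrasts"] = contrasts

    # --- interpret
    if config.run_interpret and feats is not None:
        try:
            surrogate = fit_surrogate(feats, strata,
                                      folds=config.surrogate_folds,
                                      seed=config.seed)
            attribution = attribute_features(surrogate, feats)
            attribution.mean_abs.sort_values(ascending=False).to_csv(
                out / "attribution.csv", header=["mean_abs_attribution"])
            report["interpret"] = {
                "surrogate_cv_accuracy": surrogate.cv_accuracy,
                "attribution_method": attribution.method,
                "top_features": attribution.ranking[:10],
            }
        except ValueError as exc:
            report["interpret"] = f"skipped: {exc}"

    # --- omics
    if config.run_omics:
        metab, genus = generate_omics(truth, sim)
        nio.write_omics(metab, out / "metabolites.csv")
        nio.write_omics(genus, out / "genera.csv")
        risk = regroup_risk(strata)
        filtered, removed = qc_filter(metab)
        normalized = sum_normalize(filtered)
        pls = fit_plsda(normalized.data, risk.loc[normalized.data.index])
        vip = compute_vip(pls)
        fc = fold_change(normalized, risk)
        vip.vip.sort_values(ascending=False).to_csv(out / "vip_metabolites.csv")
        fc.to_csv(out / "fold_changes.csv")
        report["omics"] = {
            "n_features_removed_qc": len(removed),
            "n_vip_selected": int(vip.selected.sum()),
            "explained_y_fraction": pls.explained_y_fraction,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return PipelineResult(out_dir=out, strata=strata, model=model, auc=auc,
                          logrank=(stat, p), cox=cox, report=report)


def assign_external(model, new_patients: CohortTable, out_path=None) -> StratifiedCohort:
    """Assign external patients through a frozen model, optionally persisting."""
    assigned = assign_new(model, new_patients)
    if out_path is not None:
        nio.write_labels(assigned.strata, assigned.scheme.tag, out_path)
    return assigned
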