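"""Patient stratification: six clustering schemes and frozen assignment.

Two algorithms (k-means, Ward agglomerative) crossed with three feature
sources — demographic+renal indicators, all indicators, or the network
feature vectors — give six schemes; KMN (k-means on network features) is the
recommended one.  Clusters are renumbered by severity so stratum 1 always has
the highest mean eGFR (best renal profile) and stratum k the lowest, with
ties broken by rising mean urine protein.

A fitted :class:`ClusterModel` freezes every stage (imputer, reference
network, standardizer, reduction, centroids, severity permutation); external
patients are pushed through the frozen state one at a time and land in the
stratum of the nearest training centroid (ties go to the lowest stratum
index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .features import FeatureCatalog, default_catalog, extract_features, feature_matrix
from .networks import ReferenceNetwork, build_reference_network, perturb_cohort, perturb_sample
from .preprocess import (
    FittedImputer,
    FittedReduction,
    ReductionConfig,
    Standardizer,
    fit_imputer,
    fit_reduction,
    fit_standardizer,
)
from .schema import CohortTable

ALGORITHMS = ("kmeans", "hierarchical")
FEATURE_SOURCES = ("renal", "all", "network")


@dataclass(frozen=True)
class SchemeSpec:
    algorithm: Literal["kmeans", "hierarchical"] = "kmeans"
    feature_source: Literal["renal", "all", "network"] = "network"
    k: int = 4

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(f"unknown feature source {self.feature_source!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @property
    def tag(self) -> str:
        return f"{self.algorithm}-{self.feature_source}"


#: the recommended scheme: k-means on network biomarkers
KMN = SchemeSpec("kmeans", "network", 4)


def all_schemes(k: int = 4) -> list[SchemeSpec]:
    return [SchemeSpec(a, s, k) for a in ALGORITHMS for s in FEATURE_SOURCES]


@dataclass
class ClusterModel:
    scheme: SchemeSpec
    imputer: FittedImputer | None
    standardizer: Standardizer
    reduction: FittedReduction
    centroids: np.ndarray  # (k, d) in embedded space, raw-label order
    severity_map: dict[int, int]  # raw label -> stratum 1..k
    training_strata: pd.Series  # per-patient stratum 1..k
    reference: ReferenceNetwork | None = None
    catalog: FeatureCatalog | None = None
    alpha: float = 0.05
    inertia: float | None = None

    @property
    def k(self) -> int:
        return self.scheme.k


@dataclass
class StratifiedCohort:
    strata: pd.Series  # per-patient stratum 1..k
    scheme: SchemeSpec

    def counts(self) -> pd.Series:
        return self.strata.value_counts().sort_index()


def fit_clusters(embedding: np.ndarray, scheme: SchemeSpec, seed: int = 0,
                 n_init: int = 50) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Cluster the embedded feature matrix.

    Returns (raw labels, centroids in embedded space, inertia).  k-means runs
    ``n_init`` restarts keeping the lowest inertia; hierarchical clustering is
    Ward-linkage agglomerative cut at k, with centroids taken as training
    cluster means (used later for external assignment).
    """
    arr = np.asarray(embedding, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("features must be complete")
    if scheme.k > arr.shape[0]:
        raise ValueError(f"k={scheme.k} exceeds number of rows {arr.shape[0]}")
    if arr.shape[0] < 10 * scheme.k:
        warnings.warn(f"only {arr.shape[0]} rows for k={scheme.k}", stacklevel=2)

    if scheme.algorithm == "kmeans":
        km = KMeans(n_clusters=scheme.k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(arr)
        centroids = km.cluster_centers_
        inertia = float(km.inertia_)
    else:
        hc = AgglomerativeClustering(n_clusters=scheme.k, linkage="ward")
        labels = hc.fit_predict(arr)
        centroids = np.vstack([arr[labels == c].mean(axis=0)
                               for c in range(scheme.k)])
        inertia = None
    occupied = np.unique(labels)
    if occupied.size < scheme.k:
        warnings.warn(
            f"only {occupied.size} of {scheme.k} clusters are nonempty",
            stacklevel=2,
        )
    return labels, centroids, inertia


def severity_order(raw_labels: np.ndarray, training_table: CohortTable | pd.DataFrame,
                   k: int, egfr_col: str = "egfr",
                   upro_col: str = "urine_protein_24h") -> dict[int, int]:
    """Map raw cluster labels to strata 1..k by falling mean eGFR, ties
    broken by rising mean urine protein."""
    frame = training_table.data if isinstance(training_table, CohortTable) else training_table
    if egfr_col not in frame.columns:
        raise ValueError(f"training table lacks the eGFR column {egfr_col!r}")
    egfr = frame[egfr_col].to_numpy(dtype=float)
    upro = (frame[upro_col].to_numpy(dtype=float)
            if upro_col in frame.columns else np.zeros_like(egfr))
    means = []
    for c in range(k):
        sel = raw_labels == c
        if sel.any():
            means.append((np.nanmean(egfr[sel]), np.nanmean(upro[sel])))
        else:
            means.append((-np.inf, np.inf))  # empty clusters sink to the worst stratum
    order = sorted(range(k), key=lambda c: (-means[c][0], means[c][1]))
    return {raw: stratum + 1 for stratum, raw in enumerate(order)}


def _training_features(
    patients: CohortTable,
    scheme: SchemeSpec,
    reference: CohortTable | None,
    alpha: float,
) -> tuple[pd.DataFrame, ReferenceNetwork | None, FeatureCatalog | None]:
    if scheme.feature_source == "network":
        if reference is None:
            raise ValueError("network schemes require a healthy reference cohort")
        refnet = build_reference_network(reference)
        nets = perturb_cohort(refnet, patients, alpha=alpha)
        catalog = default_catalog(refnet.names)
        return feature_matrix(nets, catalog), refnet, catalog
    roles = ("demographic", "renal") if scheme.feature_source == "renal" else (
        "demographic", "renal", "extrarenal")
    return patients.subset(roles).data, None, None


def fit_scheme(
    patients: CohortTable,
    scheme: SchemeSpec = KMN,
    reference: CohortTable | None = None,
    seed: int = 0,
    reduction: ReductionConfig | None = None,
    alpha: float = 0.05,
    n_init: int = 50,
) -> ClusterModel:
    """Fit one stratification scheme end to end on a training cohort.

    Pipeline: impute -> (network features for network schemes) ->
    standardize -> reduce -> cluster -> severity relabel.
    """
    reduction = reduction or ReductionConfig(seed=seed)
    imputer = fit_imputer(patients) if not patients.is_complete else None
    imputed = imputer.apply(patients) if imputer is not None else patients

    feats, refnet, catalog = _training_features(imputed, scheme, reference, alpha)
    constant = feats.columns[feats.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s) before "
            f"standardization: {constant}", stacklevel=2)
        feats = feats.drop(columns=constant)
    standardizer = fit_standardizer(feats)
    z = standardizer.apply(feats)
    reducer = fit_reduction(z, reduction)
    embedding = reducer.apply(z)
    raw_labels, centroids, inertia = fit_clusters(embedding, scheme, seed, n_init)
    sev = severity_order(raw_labels, imputed, scheme.k)
    strata = pd.Series([sev[c] for c in raw_labels],
                       index=patients.data.index, name="stratum")
    return ClusterModel(
        scheme=scheme, imputer=imputer, standardizer=standardizer,
        reduction=reducer, centroids=centroids, severity_map=sev,
        training_strata=strata, reference=refnet, catalog=catalog,
        alpha=alpha, inertia=inertia,
    )


def relabel_by_severity(model: ClusterModel,
                        training_table: CohortTable) -> ClusterModel:
    """Recompute the severity permutation from a training table (idempotent)."""
    raw = np.array([
        {v: k for k, v in model.severity_map.items()}[s]
        for s in model.training_strata
    ])
    sev = severity_order(raw, training_table, model.scheme.k)
    model.severity_map = sev
    model.training_strata = pd.Series(
        [sev[c] for c in raw], index=model.training_strata.index, name="stratum"
    )
    return model


def _embed_one(model: ClusterModel, row: pd.Series) -> np.ndarray:
    frame = row.to_frame().T.astype(float)
    if model.imputer is not None and frame.isna().any().any():
        frame = model.imputer.apply(
            CohortTable(frame, model.imputer.schema)).data
    elif frame.isna().any().any():
        raise ValueError(f"patient {row.name} has missing values and no fitted imputer")
    if model.scheme.feature_source == "network":
        net = perturb_sample(model.reference, frame.iloc[0], alpha=model.alpha)
        feats = extract_features(net, model.catalog).to_frame().T
    else:
        feats = frame
    z = model.standardizer.apply(feats[list(model.standardizer.mean.index)])
    return model.reduction.apply(z)[0]


def assign_stratum(model: ClusterModel, point: np.ndarray) -> int:
    """Nearest-centroid stratum for one embedded point; equidistant ties go
    to the lowest stratum index."""
    d = np.linalg.norm(model.centroids - point, axis=1)
    strata = np.array([model.severity_map[c] for c in range(model.k)])
    best = np.isclose(d, d.min(), rtol=0.0, atol=1e-12)
    return int(strata[best].min())


def assign_new(model: ClusterModel, new_patients: CohortTable) -> StratifiedCohort:
    """Assign external patients to strata through the frozen pipeline.

    Patients are processed sequentially: frozen imputer -> (perturbation
    network against the original healthy reference -> features, for network
    schemes) -> frozen standardizer -> frozen reduction -> nearest training
    centroid -> severity mapping.
    """
    if model.scheme.feature_source == "network":
        expected = model.reference.names
    elif model.imputer is not None:
        expected = model.imputer.schema.names
    else:
        expected = None
    if expected is not None and list(new_patients.data.columns) != expected:
        raise ValueError("schema mismatch with the fitted model")
    labels = {}
    for idx, row in new_patients.data.iterrows():
        point = _embed_one(model, row)
        labels[idx] = assign_stratum(model, point)
    return StratifiedCohort(
        strata=pd.Series(labels, name="stratum"), scheme=model.scheme
    )
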