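"""Imputation, standardization and dimensionality reduction.

All transforms follow a fit/apply contract: statistics and model state are
estimated once on the training (cluster) cohort and frozen; external patients
are pushed through the stored state without refitting, which is what makes
label assignment for new patients well-defined.

Missing values are filled by iterative chained linear regression: each
incomplete column is regressed on all the others in round-robin sweeps,
starting from column means, until the imputed values stabilise.  Continuous
imputations are clipped to the observed range of their column;
binary/ordinal imputations are rounded to the nearest valid coded level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

from .schema import CohortTable, IndicatorSchema


@dataclass
class FittedImputer:
    schema: IndicatorSchema
    model: IterativeImputer
    observed_min: pd.Series
    observed_max: pd.Series

    def apply(self, table: CohortTable) -> CohortTable:
        return _finish_imputation(self, table)


def _check_imputable(data: pd.DataFrame) -> None:
    fully_missing = [c for c in data.columns if data[c].isna().all()]
    if fully_missing:
        raise ValueError(f"fully-missing column(s): {fully_missing}")
    few = [c for c in data.columns if data[c].notna().sum() < 2]
    if few:
        raise ValueError(f"column(s) with fewer than 2 observed values: {few}")
    if data.isna().all(axis=1).any():
        raise ValueError("at least one row is fully missing")


def fit_imputer(table: CohortTable, max_iter: int = 10, tol: float = 1e-3) -> FittedImputer:
    """Fit the chained-regression imputer on a training cohort."""
    data = table.data
    _check_imputable(data)
    model = IterativeImputer(
        estimator=LinearRegression(),
        max_iter=max_iter,
        tol=tol,
        initial_strategy="mean",
        imputation_order="ascending",
        sample_posterior=False,
        random_state=0,
        keep_empty_features=False,
    )
    model.fit(data.to_numpy(dtype=float))
    return FittedImputer(
        schema=table.schema,
        model=model,
        observed_min=data.min(),
        observed_max=data.max(),
    )


def _finish_imputation(fitted: FittedImputer, table: CohortTable) -> CohortTable:
    data = table.data
    if list(data.columns) != fitted.schema.names:
        raise ValueError("indicator mismatch with fitted imputer")
    raw = fitted.model.transform(data.to_numpy(dtype=float))
    out = pd.DataFrame(raw, index=data.index, columns=data.columns)
    # observed cells must pass through untouched
    observed = data.notna()
    out = out.where(~observed, data)
    for ind in fitted.schema.indicators:
        col = out[ind.name]
        if ind.kind == "continuous":
            out[ind.name] = col.clip(fitted.observed_min[ind.name],
                                     fitted.observed_max[ind.name])
        else:
            levels = np.asarray(ind.levels, dtype=float)
            snapped = levels[np.argmin(
                np.abs(col.to_numpy()[:, None] - levels[None, :]), axis=1)]
            out[ind.name] = np.where(observed[ind.name], data[ind.name], snapped)
    return CohortTable(out, table.schema)


def impute_missing(table: CohortTable, max_iter: int = 10, tol: float = 1e-3) -> CohortTable:
    """Fit-and-apply imputation on a single table (training-time use)."""
    if table.is_complete:
        return CohortTable(table.data.copy(), table.schema)
    return fit_imputer(table, max_iter=max_iter, tol=tol).apply(table)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Frozen per-column zero-mean / unit-variance scaling."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        if list(data.columns) != list(self.mean.index):
            raise ValueError("column mismatch with fitted standardizer")
        return (data - self.mean) / self.sd


def fit_standardizer(data: pd.DataFrame | CohortTable) -> Standardizer:
    frame = data.data if isinstance(data, CohortTable) else data
    if frame.isna().any().any():
        raise ValueError("standardizer requires a complete table")
    sd = frame.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return Standardizer(mean=frame.mean(), sd=sd)


def apply_standardizer(t: Standardizer, data: pd.DataFrame | CohortTable) -> pd.DataFrame:
    frame = data.data if isinstance(data, CohortTable) else data
    return t.apply(frame)


# ---------------------------------------------------------------------------
# dimensionality reduction


@dataclass
class ReductionConfig:
    method: Literal["umap", "pca"] = "umap"
    n_components: int = 2
    n_neighbors: int = 100
    min_dist: float = 0.1
    seed: int = 0


@dataclass
class FittedReduction:
    config: ReductionConfig
    model: object
    columns: list[str] = field(default_factory=list)

    def apply(self, data: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            if self.columns and list(data.columns) != self.columns:
                raise ValueError("column mismatch with fitted reduction")
            data = data.to_numpy(dtype=float)
        return np.asarray(self.model.transform(data), dtype=float)


def fit_reduction(data: pd.DataFrame | np.ndarray,
                  config: ReductionConfig | None = None) -> FittedReduction:
    """Fit the manifold (UMAP) or PCA reduction on standardized features."""
    config = config or ReductionConfig()
    columns = list(data.columns) if isinstance(data, pd.DataFrame) else []
    arr = np.asarray(data, dtype=float)
    if config.method == "umap":
        if arr.shape[0] <= config.n_neighbors:
            raise ValueError(
                f"need more than n_neighbors={config.n_neighbors} rows, "
                f"got {arr.shape[0]}"
            )
        import umap

        model = umap.UMAP(
            n_components=config.n_components,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            random_state=config.seed,
            transform_seed=42,
        )
    elif config.method == "pca":
        if arr.shape[0] < config.n_components:
            raise ValueError("fewer rows than components")
        model = PCA(n_components=config.n_components, random_state=config.seed)
    else:
        raise ValueError(f"unknown reduction method {config.method!r}")
    model.fit(arr)
    return FittedReduction(config=config, model=model, columns=columns)


def apply_reduction(t: FittedReduction, data: pd.DataFrame | np.ndarray) -> np.ndarray:
    return t.apply(data)


# ---------------------------------------------------------------------------
# bundled pipeline state


@dataclass
class FittedTransform:
    """Frozen preprocessing state: imputer + standardizer + reduction."""

    imputer: FittedImputer | None
    standardizer: Standardizer
    reduction: FittedReduction

    def apply_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return self.reduction.apply(self.standardizer.apply(frame))
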