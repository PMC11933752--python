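"""Interpretability of the unsupervised strata.

The cluster labels are treated as surrogate targets for a supervised
multiclass gradient-boosted tree ensemble over the 46 network attributes;
stratified 10-fold cross-validation reports how learnable the strata are,
and per-feature Shapley values (exact TreeSHAP, via the booster's
``pred_contribs`` path) rank which network attributes drive the
stratification.  If Shapley attribution is unavailable for a model, a
permutation-importance fallback is used and flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold


@dataclass
class SurrogateModel:
    model: xgb.XGBClassifier
    feature_names: list[str]
    classes: np.ndarray  # original stratum labels in encoder order
    cv_accuracy: float
    fold_accuracies: list[float]


@dataclass
class AttributionReport:
    mean_abs: pd.Series  # per feature, averaged over patients and classes
    per_class_mean: pd.DataFrame  # signed mean attribution per stratum
    ranking: list[str]
    method: str  # "shapley" or "permutation"
    cv_accuracy: float
    base_values: np.ndarray | None = None


def fit_surrogate(
    features: pd.DataFrame,
    strata: pd.Series,
    folds: int = 10,
    seed: int = 0,
) -> SurrogateModel:
    """Fit the surrogate classifier and report stratified CV accuracy."""
    strata = strata.loc[features.index]
    counts = strata.value_counts()
    small = counts[counts < folds]
    if not small.empty:
        raise ValueError(
            f"stratum smaller than {folds} patients: {dict(small)}")
    classes = np.sort(strata.unique())
    y = np.searchsorted(classes, strata.to_numpy())
    x = features.to_numpy(dtype=float)

    def _model() -> xgb.XGBClassifier:
        return xgb.XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.3,
            random_state=seed, verbosity=0)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    for train, test in skf.split(x, y):
        m = _model().fit(x[train], y[train])
        fold_acc.append(float((m.predict(x[test]) == y[test]).mean()))
    model = _model().fit(x, y)
    return SurrogateModel(
        model=model, feature_names=list(features.columns), classes=classes,
        cv_accuracy=float(np.mean(fold_acc)), fold_accuracies=fold_acc,
    )


def attribute_features(
    surrogate: SurrogateModel, features: pd.DataFrame, seed: int = 0
) -> AttributionReport:
    """Shapley attribution of the surrogate over the supplied patients."""
    if list(features.columns) != surrogate.feature_names:
        raise ValueError("feature mismatch with the fitted surrogate")
    x = features.to_numpy(dtype=float)
    try:
        booster = surrogate.model.get_booster()
        contribs = booster.predict(xgb.DMatrix(x), pred_contribs=True)
        # (n, classes, p+1) multiclass or (n, p+1) binary; last col = base value
        if contribs.ndim == 2:
            contribs = contribs[:, None, :]
        base = contribs[:, :, -1]
        shap_vals = contribs[:, :, :-1]  # (n, classes, p)
        mean_abs = pd.Series(
            np.abs(shap_vals).mean(axis=(0, 1)), index=surrogate.feature_names)
        per_class = pd.DataFrame(
            shap_vals.mean(axis=0).T,
            index=surrogate.feature_names,
            columns=[int(c) for c in surrogate.classes[: shap_vals.shape[1]]],
        )
        method = "shapley"
    except Exception:
        y = np.searchsorted(surrogate.classes,
                            surrogate.model.predict(x))
        imp = permutation_importance(
            surrogate.model, x, y, n_repeats=10, random_state=seed)
        mean_abs = pd.Series(np.abs(imp.importances_mean),
                             index=surrogate.feature_names)
        per_class = pd.DataFrame(
            {int(c): mean_abs for c in surrogate.classes})
        base = None
        method = "permutation"
    if not np.isfinite(mean_abs.to_numpy()).all():
        raise ValueError("non-finite attribution encountered")
    ranking = list(mean_abs.sort_values(ascending=False, kind="stable").index)
    return AttributionReport(
        mean_abs=mean_abs, per_class_mean=per_class, ranking=ranking,
        method=method, cv_accuracy=surrogate.cv_accuracy,
        base_values=base,
    )


def shapley_local_accuracy_error(
    surrogate: SurrogateModel, features: pd.DataFrame
) -> float:
    """Max |sum(attributions) + base - margin| over patients/classes.

    Exact Shapley attribution must reconstruct the model margin; exposed so
    tests can assert the local-accuracy property.
    """
    x = features.to_numpy(dtype=float)
    booster = surrogate.model.get_booster()
    contribs = booster.predict(xgb.DMatrix(x), pred_contribs=True)
    margins = booster.predict(xgb.DMatrix(x), output_margin=True)
    if contribs.ndim == 2:
        contribs = contribs[:, None, :]
        margins = margins.reshape(-1, 1)
    recon = contribs.sum(axis=2)
    return float(np.abs(recon - margins).max())
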