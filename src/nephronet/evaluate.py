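"""Prognostic evaluation of a stratification.

Survival machinery (Kaplan-Meier curves, log-rank tests, covariate-adjusted
Cox proportional hazards with Efron tie handling) is delegated to
``lifelines``.  The stratification-specific pieces live here: the
cluster-label-only AUC (a gradient-boosted classifier given nothing but the
stratum label, cross-validated, with a closed-form rank-AUC oracle), the
resampled scheme comparison via Mann-Whitney U, Cohen d effect-size
matrices, visit-aligned trajectory summaries, and within-stratum treatment
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

#: covariates the adjusted Cox models condition on, when present
DEFAULT_ADJUSTMENT = ("age", "sex", "urine_protein_24h", "urine_rbc",
                      "egfr", "sbp", "dbp")

IST_ARMS = ("GS", "II", "GS+II")  # immunosuppressive therapy = GS u II u GS+II


@dataclass
class KMCurve:
    group: object
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimate must be non-increasing")


@dataclass
class CoxResult:
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    adjusted_for: tuple[str, ...]
    n_events: int
    unstable: bool = False
    summary: pd.DataFrame | None = None


@dataclass
class AUCResult:
    scheme: str
    auc_cv: float
    auc_apparent: float
    auc_rank_oracle: float
    resampled: list[float] = field(default_factory=list)


@dataclass
class EffectSizeMatrix:
    indicators: list[str]
    strata: list[int]
    d: dict[str, pd.DataFrame]  # indicator -> (stratum x stratum) Cohen d

    def get(self, indicator: str, a: int, b: int) -> float:
        return float(self.d[indicator].loc[a, b])


def _check_survival(records: pd.DataFrame) -> None:
    for col in ("time_months", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records need a {col!r} column")
    if (records["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")


def km_estimate(records: pd.DataFrame, groups: pd.Series) -> dict[object, KMCurve]:
    """Product-limit survival curve per group."""
    _check_survival(records)
    groups = groups.loc[records.index]
    out = {}
    for g in sorted(pd.unique(groups)):
        sub = records.loc[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(
            kmf.survival_function_.index).to_numpy(dtype=float)
        out[g] = KMCurve(group=g, timeline=timeline, survival=surv, at_risk=at_risk)
    return out


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """K-group log-rank test; returns (chi-square statistic, p)."""
    _check_survival(records)
    groups = groups.loc[records.index]
    if pd.unique(groups).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if int(records["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(
        records["time_months"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_adjusted(
    records: pd.DataFrame,
    strata: pd.Series,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> CoxResult:
    """Multivariable Cox PH: stratum indicators (stratum 1 reference) plus
    the listed covariates; Efron handling for tied event times."""
    _check_survival(records)
    strata = strata.loc[records.index]
    n_events = int(records["event"].sum())
    if n_events == 0:
        raise ValueError("Cox model needs at least one event")
    covs = [c for c in covariates if c in records.columns]
    df = records[["time_months", "event"] + covs].copy()
    df["event"] = df["event"].astype(int)
    levels = sorted(pd.unique(strata))
    dummy_cols = []
    for lvl in levels[1:]:
        col = f"stratum_{lvl}"
        df[col] = (strata == lvl).astype(float)
        dummy_cols.append(col)
    n_params = len(covs) + len(dummy_cols)
    if n_events < 10 * n_params:
        warnings.warn(
            f"{n_events} events for {n_params} parameters; estimates may be "
            "unstable", stacklevel=2)
    cph = CoxPHFitter()
    unstable = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time_months", event_col="event")
        except Exception:
            # ridge-penalised retry flags possible separation
            unstable = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time_months", event_col="event")
    summ = cph.summary
    if (summ["se(coef)"] > 10).any():
        unstable = True
    idx = [f"stratum_{lvl}" for lvl in levels[1:]]
    return CoxResult(
        hr=np.exp(summ.loc[idx, "coef"]).rename(dict(zip(idx, levels[1:]))),
        ci_lower=np.exp(summ.loc[idx, "coef lower 95%"]).rename(
            dict(zip(idx, levels[1:]))),
        ci_upper=np.exp(summ.loc[idx, "coef upper 95%"]).rename(
            dict(zip(idx, levels[1:]))),
        p=summ.loc[idx, "p"].rename(dict(zip(idx, levels[1:]))),
        adjusted_for=tuple(covs),
        n_events=n_events,
        unstable=unstable,
        summary=summ,
    )


# ---------------------------------------------------------------------------
# cluster-label AUC


def rank_auc_oracle(strata: np.ndarray, outcome: np.ndarray) -> float:
    """Closed-form AUC of scoring each patient by its stratum's event rate.

    With a single categorical predictor, any monotone scorer's ROC is
    determined by the per-stratum event rates; this is the analytic ceiling
    the boosted model should match.
    """
    strata = np.asarray(strata)
    outcome = np.asarray(outcome).astype(int)
    rates = {s: outcome[strata == s].mean() for s in np.unique(strata)}
    score = np.array([rates[s] for s in strata])
    return float(roc_auc_score(outcome, score))


def cluster_label_auc(
    strata: pd.Series,
    outcome: pd.Series,
    rounds: int = 10,
    folds: int = 10,
    seed: int = 0,
    subsample: float = 0.8,
) -> AUCResult:
    """AUC of predicting the outcome from the stratum label alone.

    A gradient-boosted tree ensemble sees one feature (the stratum label);
    the cross-validated AUC pools out-of-fold scores.  ``rounds`` resampled
    AUCs (each on an ``subsample`` fraction drawn without replacement) feed
    the scheme comparison test.
    """
    import xgboost as xgb

    strata = strata.loc[outcome.index]
    y = outcome.to_numpy().astype(int)
    if pd.unique(strata).size < 2:
        raise ValueError("need at least two strata")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    x = strata.to_numpy(dtype=float).reshape(-1, 1)

    def _model():
        return xgb.XGBClassifier(
            n_estimators=50, max_depth=2, learning_rate=0.3,
            random_state=seed, verbosity=0, base_score=0.5)

    clf = _model().fit(x, y)
    auc_apparent = float(roc_auc_score(y, clf.predict_proba(x)[:, 1]))

    # cross-validated AUC = mean of per-fold held-out AUCs (pooling scores
    # across folds would mix fold-specific rate estimates and break ties
    # inconsistently for a categorical predictor)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train, test in skf.split(x, y):
        if y[test].min() == y[test].max():
            continue
        m = _model().fit(x[train], y[train])
        fold_aucs.append(roc_auc_score(y[test], m.predict_proba(x[test])[:, 1]))
    auc_cv = float(np.mean(fold_aucs))

    rng = np.random.default_rng(seed)
    resampled = []
    n_sub = int(round(subsample * y.size))
    for _ in range(rounds):
        idx = rng.choice(y.size, size=n_sub, replace=False)
        if y[idx].min() == y[idx].max():
            continue
        m = _model().fit(x[idx], y[idx])
        resampled.append(float(roc_auc_score(y[idx], m.predict_proba(x[idx])[:, 1])))

    return AUCResult(
        scheme="", auc_cv=auc_cv, auc_apparent=auc_apparent,
        auc_rank_oracle=rank_auc_oracle(strata.to_numpy(), y),
        resampled=resampled,
    )


def compare_scheme_aucs(auc_lists: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U over resampled AUC lists."""
    names = list(auc_lists)
    if len(names) < 2:
        raise ValueError("need at least two schemes to compare")
    rounds = {len(v) for v in auc_lists.values()}
    if len(rounds) != 1:
        raise ValueError("all schemes must have the same number of rounds")
    if rounds.pop() < 3:
        raise ValueError("need at least 3 rounds per scheme")
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                xa, xb = auc_lists[a], auc_lists[b]
                if np.allclose(xa, xb) and np.ptp(xa + xb) == 0:
                    p = 1.0
                else:
                    p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
                out.loc[a, b] = out.loc[b, a] = p
    return out


# ---------------------------------------------------------------------------
# effect sizes, trajectories, treatment contrasts


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return np.nan  # undefined: zero pooled spread
    return float((a.mean() - b.mean()) / pooled)


def cohen_d_matrix(table: pd.DataFrame, strata: pd.Series) -> EffectSizeMatrix:
    """Per-indicator pairwise Cohen d between strata (antisymmetric)."""
    strata = strata.loc[table.index]
    levels = sorted(pd.unique(strata))
    mats = {}
    for col in table.columns:
        m = pd.DataFrame(0.0, index=levels, columns=levels)
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                d = cohen_d(table.loc[strata == a, col].dropna(),
                            table.loc[strata == b, col].dropna())
                m.loc[a, b] = d
                m.loc[b, a] = -d
        mats[col] = m
    return EffectSizeMatrix(indicators=list(table.columns), strata=levels, d=mats)


def trajectory_summary(
    longitudinal: pd.DataFrame,
    strata: pd.Series,
    value_cols: tuple[str, ...] = ("serum_creatinine", "urine_protein_24h"),
    visits: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0),
) -> pd.DataFrame:
    """Per-stratum mean with 95% normal CI at each visit.

    ``longitudinal`` is long format with ``patient_id`` and ``visit_month``
    columns.  Visits absent for a stratum are reported as gaps (NaN rows),
    never imputed; single-patient cells get an undefined-CI flag.
    """
    known = set(longitudinal["visit_month"].unique())
    unknown = [v for v in visits if v not in known]
    if unknown:
        raise ValueError(f"unknown visit key(s): {unknown}")
    df = longitudinal.copy()
    df["stratum"] = df["patient_id"].map(strata)
    rows = []
    for col in value_cols:
        for s in sorted(strata.unique()):
            for v in visits:
                vals = df.loc[(df["stratum"] == s) & (df["visit_month"] == v), col].dropna()
                n = len(vals)
                mean = float(vals.mean()) if n else np.nan
                if n >= 2:
                    half = 1.959963984540054 * vals.std(ddof=1) / np.sqrt(n)
                    lo, hi, undef = mean - half, mean + half, False
                else:
                    lo = hi = np.nan
                    undef = True
                rows.append({"indicator": col, "stratum": s, "visit_month": v,
                             "n": n, "mean": mean, "ci_lower": lo,
                             "ci_upper": hi, "ci_undefined": undef})
    return pd.DataFrame(rows)


@dataclass
class TreatmentContrast:
    stratum: int
    km: dict[object, KMCurve]
    global_logrank: tuple[float, float]
    pairwise_logrank: pd.DataFrame
    ist_vs_sc: CoxResult | None
    combo_vs_sc: CoxResult | None
    dropped_arms: list[str]


def treatment_contrast(
    records: pd.DataFrame,
    stratum: int = 0,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> TreatmentContrast:
    """Within-stratum comparison of treatment arms.

    Per-arm KM curves, global and pairwise log-rank, and adjusted Cox HRs
    for immunosuppressive therapy (any of GS, II, GS+II) vs supportive care
    and for the GS+II combination vs supportive care.  Empty arms are
    dropped with a warning.
    """
    _check_survival(records)
    if "treatment" not in records.columns:
        raise ValueError("records need a 'treatment' column")
    counts = records["treatment"].value_counts()
    dropped = [a for a in ("SC", "GS", "II", "GS+II")
               if counts.get(a, 0) == 0]
    if dropped:
        warnings.warn(f"empty treatment arm(s) dropped: {dropped}", stacklevel=2)
    present = [a for a in ("SC", "GS", "II", "GS+II") if counts.get(a, 0) > 0]
    if len(present) < 2:
        raise ValueError("treatment contrast needs at least two nonempty arms")

    arm = records["treatment"]
    km = km_estimate(records, arm)
    global_lr = logrank_test(records, arm)
    pw = pd.DataFrame(np.nan, index=present, columns=present)
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            sub = records[arm.isin([a, b])]
            if sub["event"].sum() == 0:
                continue
            _, p = logrank_test(sub, sub["treatment"])
            pw.loc[a, b] = pw.loc[b, a] = p

    def _arm_cox(indicator: pd.Series) -> CoxResult | None:
        if indicator.nunique() < 2 or records["event"].sum() == 0:
            return None
        try:
            return cox_adjusted(records, indicator.map({False: 1, True: 2}),
                                covariates)
        except ValueError:
            return None

    ist = _arm_cox(arm.isin(IST_ARMS)) if "SC" in present else None
    combo = None
    if "SC" in present and "GS+II" in present:
        sub = records[arm.isin(["SC", "GS+II"])]
        combo_ind = sub["treatment"].eq("GS+II").map({False: 1, True: 2})
        try:
            combo = cox_adjusted(sub, combo_ind, covariates)
        except ValueError:
            combo = None
    return TreatmentContrast(
        stratum=stratum, km=km, global_logrank=global_lr,
        pairwise_logrank=pw, ist_vs_sc=ist, combo_vs_sc=combo,
        dropped_arms=dropped,
    )
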