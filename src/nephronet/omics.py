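"""Metabolomics and gut-microbiome contrasts under a stratification.

Pipeline order is fixed: QC filtering (drop features whose coefficient of
variation over QC replicate injections exceeds 20%), sum normalization
(close each sample to total 1), then PLS-DA with VIP scoring.  Two-class
contrasts (high vs low risk) code the response as +/-1; four-class
contrasts use a one-hot response with the explained response sum of squares
pooled over response columns.  Features with VIP > 1 are flagged as
discriminating.

Also here: the high/low risk regrouping (strata 1-2 vs 3-4), fold changes,
p-thresholded correlation networks (no multiplicity correction by default,
a Bonferroni flag is available), and Mantel tests between distance
matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression


@dataclass
class OmicsTable:
    """Samples x features matrix, optional QC replicate block, modality tag."""

    data: pd.DataFrame
    qc: pd.DataFrame | None = None
    modality: str = "metabolite"
    #: generator-known CVs, carried only by synthetic tables for testing
    true_cv: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("omics intensities must be nonnegative")
        if self.qc is not None and list(self.qc.columns) != list(self.data.columns):
            raise ValueError("QC block must cover the same features")

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def qc_cv(self) -> pd.Series:
        """Per-feature coefficient of variation (sd/mean) over QC replicates."""
        if self.qc is None:
            raise ValueError("table has no QC replicates")
        if len(self.qc) < 3:
            raise ValueError("need at least 3 QC replicates")
        mean = self.qc.mean()
        sd = self.qc.std(ddof=1)
        return (sd / mean).rename("cv")


def qc_filter(table: OmicsTable, cv_threshold: float = 0.20) -> tuple[OmicsTable, list[str]]:
    """Drop features whose QC CV exceeds the threshold (strictly).

    Returns the filtered table and the list of removed feature names.
    """
    cv = table.qc_cv()
    removed = list(cv.index[cv > cv_threshold])
    keep = [f for f in table.features if f not in removed]
    return (
        OmicsTable(
            data=table.data[keep].copy(),
            qc=table.qc[keep].copy(),
            modality=table.modality,
            true_cv=None if table.true_cv is None else table.true_cv[keep],
        ),
        removed,
    )


def sum_normalize(table: OmicsTable) -> OmicsTable:
    """Close each sample row to sum 1."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"zero-sum sample row(s): {zero}")
    return OmicsTable(
        data=table.data.div(totals, axis=0),
        qc=table.qc,
        modality=table.modality,
        true_cv=table.true_cv,
    )


# ---------------------------------------------------------------------------
# PLS-DA and VIP


@dataclass
class PLSDAModel:
    n_components: int
    weights: np.ndarray  # (p, A), columns unit norm
    scores: np.ndarray  # (n, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (q, A)
    ssy: np.ndarray  # (A,) explained response sum of squares per component
    feature_names: list[str]
    classes: list
    explained_y_fraction: float


@dataclass
class VIPResult:
    vip: pd.Series
    selected: pd.Series  # VIP > 1

    def __post_init__(self) -> None:
        p = len(self.vip)
        if abs(float((self.vip**2).mean()) - 1.0) > 1e-6:
            warnings.warn("VIP normalization identity violated", stacklevel=2)
        del p


def _encode_response(y: pd.Series | np.ndarray) -> tuple[np.ndarray, list]:
    y = pd.Series(np.asarray(y))
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    if len(classes) == 2:
        coded = np.where(y == classes[1], 1.0, -1.0).reshape(-1, 1)
    else:
        coded = np.zeros((len(y), len(classes)))
        for j, c in enumerate(classes):
            coded[y.to_numpy() == c, j] = 1.0
    return coded, classes


def fit_plsda(x: pd.DataFrame, y, n_components: int = 2) -> PLSDAModel:
    """NIPALS partial least squares discrimination.

    X is mean-centered; the response is +/-1 for two classes or one-hot for
    more.  Per-component explained response sum of squares is
    ``SSY_a = (t_a . t_a) * ||q_a||^2`` from the rank-one NIPALS
    decomposition of Y.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    coded, classes = _encode_response(y)
    n, p = x.shape
    if n_components >= min(n, p):
        raise ValueError(
            f"n_components={n_components} must be < min(samples={n}, features={p})")
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(x.to_numpy(dtype=float), coded)
    t = pls.x_scores_
    q = pls.y_loadings_  # (q_targets, A)
    ssy = np.einsum("na,na->a", t, t) * np.einsum("ja,ja->a", q, q)
    w = pls.x_weights_
    norms = np.linalg.norm(w, axis=0)
    w = w / np.where(norms == 0, 1.0, norms)
    total_ssy = float(((coded - coded.mean(axis=0)) ** 2).sum())
    return PLSDAModel(
        n_components=n_components,
        weights=w,
        scores=t,
        x_loadings=pls.x_loadings_,
        y_loadings=q,
        ssy=np.asarray(ssy, dtype=float),
        feature_names=list(x.columns),
        classes=classes,
        explained_y_fraction=float(ssy.sum() / total_ssy) if total_ssy > 0 else 0.0,
    )


def compute_vip(model: PLSDAModel) -> VIPResult:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with unit-norm
    weight vectors, so mean(VIP^2) = 1 over features.
    """
    if model.ssy.sum() <= 0:
        raise ValueError("model explains no response variance (all SSY zero)")
    p = len(model.feature_names)
    num = (model.weights**2) @ model.ssy
    vip = np.sqrt(p * num / model.ssy.sum())
    s = pd.Series(vip, index=model.feature_names, name="vip")
    return VIPResult(vip=s, selected=s > 1.0)


# ---------------------------------------------------------------------------
# risk regrouping and fold changes


def regroup_risk(strata: pd.Series) -> pd.Series:
    """Strata 1-2 -> 'low', 3-4 -> 'high'."""
    vals = pd.Series(strata)
    bad = set(vals.unique()) - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"strata outside 1..4: {sorted(bad)}")
    return vals.map({1: "low", 2: "low", 3: "high", 4: "high"}).rename("risk")


def fold_change(table: OmicsTable | pd.DataFrame, groups: pd.Series,
                numerator: str = "high", denominator: str = "low") -> pd.DataFrame:
    """Per-feature mean ratio numerator/denominator group with direction flags."""
    data = table.data if isinstance(table, OmicsTable) else table
    groups = groups.loc[data.index]
    for g in (numerator, denominator):
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    m_num = data.loc[groups == numerator].mean()
    m_den = data.loc[groups == denominator].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m_num / m_den
    undefined = m_den == 0
    fc = fc.mask(undefined)
    return pd.DataFrame({
        "fold_change": fc,
        "direction": np.where(undefined, "undefined",
                              np.where(fc > 1, "up", np.where(fc < 1, "down", "flat"))),
        "undefined": undefined,
    })


# ---------------------------------------------------------------------------
# correlation networks and Mantel tests


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # node_i, node_j, r, p
    method: str
    alpha: float = 0.05
    skipped: list[str] = field(default_factory=list)


def correlation_network(
    blocks: pd.DataFrame | dict[str, pd.DataFrame],
    method: str = "pearson",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> CorrelationNetwork:
    """All-pairs correlation network with a strict p < alpha edge rule.

    ``blocks`` is one frame or a dict of frames sharing an index (e.g.
    metabolites plus clinical indicators); constant columns are skipped with
    a warning.  No multiplicity correction by default; ``bonferroni=True``
    divides alpha by the number of pairs.
    """
    if isinstance(blocks, dict):
        frames = list(blocks.values())
        idx = frames[0].index
        for f in frames[1:]:
            if not f.index.equals(idx):
                raise ValueError("blocks must share the same samples")
        data = pd.concat(frames, axis=1)
    else:
        data = blocks
    if len(data) < 4:
        raise ValueError("need at least 4 paired observations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    skipped = [c for c in data.columns if data[c].nunique() <= 1]
    if skipped:
        warnings.warn(f"constant feature(s) skipped: {skipped}", stacklevel=2)
    cols = [c for c in data.columns if c not in skipped]
    n_pairs = len(cols) * (len(cols) - 1) // 2
    thresh = alpha / n_pairs if (bonferroni and n_pairs) else alpha

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            res = corr_fn(data[a], data[b])
            r, p = float(res.statistic), float(res.pvalue)
            if p < thresh:
                rows.append({"node_i": a, "node_j": b, "r": r, "p": p})
    edges = pd.DataFrame(rows, columns=["node_i", "node_j", "r", "p"])
    return CorrelationNetwork(nodes=cols, edges=edges, method=method,
                              alpha=thresh, skipped=skipped)


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    method: str


def mantel_test(
    d1: np.ndarray | pd.DataFrame,
    d2: np.ndarray | pd.DataFrame,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test between two distance matrices on one sample set."""
    from skbio.stats.distance import DistanceMatrix, mantel as _skbio_mantel

    def _as_dm(d) -> DistanceMatrix:
        arr = np.asarray(d, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrices must be square")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diag(arr), 0.0):
            raise ValueError("distance matrices must have zero diagonal")
        return DistanceMatrix(arr)

    dm1, dm2 = _as_dm(d1), _as_dm(d2)
    if dm1.shape != dm2.shape:
        raise ValueError("distance matrices must cover the same samples")
    r, p, _ = _skbio_mantel(dm1, dm2, method=method,
                            permutations=permutations, seed=seed)
    return MantelResult(r=float(r), p=float(p), permutations=permutations,
                        method=method)


def distance_matrix(data: pd.DataFrame, metric: str = "euclidean") -> np.ndarray:
    """Convenience pairwise distance matrix (samples x samples)."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(data.to_numpy(dtype=float), metric=metric))
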