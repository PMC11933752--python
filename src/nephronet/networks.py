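"""Sample-specific perturbation networks (SSN).

A healthy reference cohort fixes a baseline Pearson correlation
``PCC_ref(i, j)`` for every pair of indicators.  Adding a single patient to
the reference and recomputing the correlation gives a perturbed value; the
difference

    dPCC(i, j) = PCC_{ref + patient}(i, j) - PCC_ref(i, j)

measures how strongly that one patient disturbs the healthy dependence
between indicators i and j.  Under the null that the patient is drawn from
the reference distribution, dPCC is asymptotically normal with variance
``(1 - PCC_ref^2) / (n - 1)`` where ``n`` is the reference size, so

    Z(i, j) = dPCC(i, j) / ((1 - PCC_ref(i, j)^2) / (n - 1))

is referred to a standard normal and a two-sided p-value attaches to every
pair.  Pairs with p below the significance level alpha (strictly) form the
patient's undirected perturbation network over the indicator nodes.

The perturbed correlation is computed by a rank-one update of the reference
mean and centered cross-product matrix, so building each patient network
costs O(F^2) rather than a full correlation recomputation; a brute-force
recomputation serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortTable

_CLIP = 1.0 - 1e-12  # keep the null variance strictly positive


@dataclass
class ReferenceNetwork:
    """Reference pairwise Pearson correlations plus the sufficient statistics
    needed for O(F^2) single-sample updates."""

    names: list[str]
    pcc: np.ndarray  # (F, F) correlations, unit diagonal
    n: int
    _mean: np.ndarray = field(repr=False, default=None)
    _css: np.ndarray = field(repr=False, default=None)  # centered cross-products

    @property
    def n_indicators(self) -> int:
        return len(self.names)


@dataclass
class SampleNetwork:
    """Per-patient perturbation network."""

    patient_id: str
    names: list[str]
    delta_pcc: np.ndarray
    z: np.ndarray
    p: np.ndarray
    alpha: float = 0.05

    @property
    def adjacency(self) -> np.ndarray:
        adj = (self.p < self.alpha)
        np.fill_diagonal(adj, False)
        return adj

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.names)
        rows, cols = np.where(np.triu(self.adjacency, k=1))
        for i, j in zip(rows, cols):
            g.add_edge(self.names[i], self.names[j],
                       delta_pcc=float(self.delta_pcc[i, j]),
                       z=float(self.z[i, j]), p=float(self.p[i, j]))
        return g

    def edge_list(self) -> pd.DataFrame:
        rows, cols = np.where(np.triu(self.adjacency, k=1))
        return pd.DataFrame({
            "node_i": [self.names[i] for i in rows],
            "node_j": [self.names[j] for j in cols],
            "delta_pcc": self.delta_pcc[rows, cols],
            "z": self.z[rows, cols],
            "p": self.p[rows, cols],
        })


def _correlation_from_css(css: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(css), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = css / np.outer(d, d)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def build_reference_network(reference: CohortTable | pd.DataFrame) -> ReferenceNetwork:
    """Pearson correlations over the healthy reference cohort.

    Requires a complete numeric table with at least 10 samples and no
    constant column.
    """
    data = reference.data if isinstance(reference, CohortTable) else reference
    if data.isna().any().any():
        raise ValueError("reference table must be complete")
    n = len(data)
    if n < 10:
        raise ValueError(f"reference needs >= 10 samples, got {n}")
    arr = data.to_numpy(dtype=float)
    constant = [c for c, s in zip(data.columns, arr.std(axis=0)) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) in reference: {constant}")
    mean = arr.mean(axis=0)
    centered = arr - mean
    css = centered.T @ centered
    return ReferenceNetwork(
        names=list(data.columns),
        pcc=_correlation_from_css(css),
        n=n,
        _mean=mean,
        _css=css,
    )


def perturb_sample(
    ref: ReferenceNetwork,
    patient_row: pd.Series | np.ndarray,
    patient_id: str = "",
    alpha: float = 0.05,
) -> SampleNetwork:
    """Build one patient's perturbation network against the reference.

    The reference-plus-patient correlation comes from a rank-one update of
    the stored mean and centered cross-product matrix.
    """
    if isinstance(patient_row, pd.Series):
        if list(patient_row.index) != ref.names:
            raise ValueError("patient indicators do not match the reference")
        patient_id = patient_id or str(patient_row.name)
        x = patient_row.to_numpy(dtype=float)
    else:
        x = np.asarray(patient_row, dtype=float)
        if x.shape != (ref.n_indicators,):
            raise ValueError("patient row has wrong length for the reference")
    if np.isnan(x).any():
        raise ValueError("patient row must be complete (impute first)")

    n = ref.n
    delta = x - ref._mean
    css_new = ref._css + np.outer(delta, delta) * n / (n + 1)
    pcc_new = _correlation_from_css(css_new)
    delta_pcc = pcc_new - ref.pcc

    r = np.clip(ref.pcc, -_CLIP, _CLIP)
    variance = (1.0 - r**2) / (n - 1)
    z = delta_pcc / variance
    p = 2.0 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(p, 1.0)
    return SampleNetwork(
        patient_id=patient_id, names=list(ref.names),
        delta_pcc=delta_pcc, z=z, p=p, alpha=alpha,
    )


def perturb_cohort(
    ref: ReferenceNetwork, patients: CohortTable, alpha: float = 0.05
) -> list[SampleNetwork]:
    """Perturbation network for every patient row (post-imputation)."""
    if list(patients.data.columns) != ref.names:
        raise ValueError("cohort indicators do not match the reference")
    return [
        perturb_sample(ref, row, patient_id=str(idx), alpha=alpha)
        for idx, row in patients.data.iterrows()
    ]


def brute_force_delta_pcc(
    reference_data: pd.DataFrame | np.ndarray, patient_row: np.ndarray
) -> np.ndarray:
    """Direct recomputation of dPCC by stacking the patient onto the
    reference and calling ``np.corrcoef`` twice.  Test oracle for the
    incremental update; not used by the pipeline."""
    arr = np.asarray(reference_data, dtype=float)
    base = np.corrcoef(arr, rowvar=False)
    stacked = np.vstack([arr, np.asarray(patient_row, dtype=float)])
    return np.corrcoef(stacked, rowvar=False) - base
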