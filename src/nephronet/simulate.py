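"""Synthetic IgA nephropathy cohorts with retained ground truth.

The generator emulates the statistical structure the stratification pipeline
assumes: ``n_subtypes`` latent disease subtypes with monotone renal
deterioration (mean eGFR strictly decreasing, mean 24 h urine protein strictly
increasing from subtype 1 to K), subtype-specific perturbations of a healthy
reference correlation structure, subtype-proportional hazards for a composite
renal endpoint with arm-specific treatment effects, and risk-group-shifted
serum-metabolite and gut-genus tables.

All draws flow from a single integer seed, so identical configurations give
byte-identical outputs on one platform.  Ground truth (subtype labels, the
reference and subtype correlation matrices, hazard multipliers, shifted omics
feature names) is returned separately and never consumed by the pipeline; it
exists only so recovery tests can score the pipeline against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortTable, IndicatorSchema, default_schema

TREATMENT_ARMS = ("SC", "GS", "II", "GS+II")

#: healthy-reference location/scale per continuous indicator (clinical units)
_UNIT_SCALE: dict[str, tuple[float, float]] = {
    "age": (38.0, 12.0),
    "bmi": (23.0, 3.0),
    "serum_creatinine": (70.0, 15.0),
    "egfr": (105.0, 15.0),
    "urine_protein_24h": (0.15, 0.10),
    "urine_rbc": (5.0, 4.0),
    "blood_urea_nitrogen": (5.0, 1.2),
    "uric_acid": (330.0, 70.0),
    "cystatin_c": (0.9, 0.15),
    "sbp": (118.0, 12.0),
    "dbp": (75.0, 9.0),
    "global_sclerosis_pct": (5.0, 5.0),
    "hemoglobin": (140.0, 15.0),
    "albumin": (44.0, 4.0),
    "alt": (22.0, 10.0),
    "ast": (24.0, 8.0),
    "total_bilirubin": (12.0, 4.0),
    "direct_bilirubin": (4.0, 1.5),
    "total_cholesterol": (4.6, 0.9),
    "triglycerides": (1.3, 0.6),
    "hdl_cholesterol": (1.4, 0.3),
    "ldl_cholesterol": (2.7, 0.7),
    "fasting_glucose": (5.0, 0.6),
    "platelet_count": (220.0, 50.0),
    "serum_iga": (2.3, 0.8),
}

#: prevalence (or cumulative level prevalences) for thresholded indicators
_THRESHOLD_PREV: dict[str, tuple[float, ...]] = {
    "sex": (0.5,),
    "smoking": (0.30,),
    "drinking": (0.25,),
    "arteriolar_sclerosis": (0.35,),
    "diabetes": (0.10,),
    "hepatitis_b": (0.08,),
    "mest_m": (0.45,),
    "mest_e": (0.20,),
    "mest_s": (0.40,),
    "mest_t": (0.35, 0.10),
    "mest_c": (0.25, 0.05),
    "iga_intensity": (0.95, 0.70, 0.30),
    "igg_intensity": (0.40, 0.15, 0.05),
    "igm_intensity": (0.55, 0.25, 0.08),
    "c3_intensity": (0.80, 0.45, 0.15),
}

#: monotone renal deterioration backbone, in reference-sd units per
#: subtype step, multiplied by ``mean_shift_scale``; guarantees strictly
#: decreasing mean eGFR and strictly increasing mean urine protein 1..K
_RENAL_GRADIENT: dict[str, float] = {
    "egfr": -1.0,
    "serum_creatinine": 0.6,
    "urine_protein_24h": 0.9,
    "blood_urea_nitrogen": 0.4,
    "uric_acid": 0.3,
    "cystatin_c": 0.5,
    "global_sclerosis_pct": 0.4,
}

#: per-subtype clinical phenotype signatures (latent-sd coefficients,
#: multiplied by ``mean_shift_scale``).  Subtypes are qualitatively distinct
#: presentations — near-healthy, hematuric, proteinuric/nephrotic-range,
#: progressive function decline — not just points on one gradient, which is
#: what makes them recoverable as clusters rather than as quantile slices
#: of a continuum.
_SIGNATURES: tuple[dict[str, float], ...] = (
    {"hemoglobin": 0.8, "albumin": 0.8, "hdl_cholesterol": 0.8,
     "age": -0.8, "bmi": -0.5},
    {"urine_rbc": 1.8, "mest_m": 1.2, "iga_intensity": 1.2,
     "alt": 1.0, "ast": 1.0, "total_bilirubin": 0.8},
    {"albumin": -1.2, "total_cholesterol": 1.2, "triglycerides": 1.2,
     "ldl_cholesterol": 1.2, "mest_s": 0.8},
    {"serum_creatinine": 0.8, "hemoglobin": -1.2, "sbp": 1.2, "dbp": 0.8,
     "mest_t": 1.2, "fasting_glucose": 0.8, "platelet_count": -0.6},
)

#: constant disease-vs-healthy offset shared by every subtype (sd units);
#: keeps the patient cohort recognisably nephropathic without introducing
#: any between-subtype difference
_DISEASE_BASE: dict[str, float] = {"egfr": -0.5, "urine_protein_24h": 1.0, "urine_rbc": 0.8}

#: indicators forming the correlation block the subtype perturbation rotates
_PERTURBED_BLOCK: tuple[str, ...] = (
    "serum_creatinine",
    "egfr",
    "urine_protein_24h",
    "urine_rbc",
    "blood_urea_nitrogen",
    "uric_acid",
    "cystatin_c",
    "sbp",
    "dbp",
)


@dataclass
class SimConfig:
    """Conditions of a synthetic study.

    Defaults are the package's reference study conditions: four severity
    subtypes of equal size, consecutive subtype means 1.5 reference-sd apart
    along the renal gradient, a 0.5-strength rotation of the renal
    correlation block, 5% completely-at-random missingness, exponential
    event times with subtype hazard multipliers (1, 2, 4, 8) around a
    0.002/month baseline, uniform censoring over a 120-month horizon, and a
    combined glucocorticoid + immunosuppressant arm that is protective
    (hazard x 0.3) only in the two high-risk subtypes.
    """

    n_patients: int = 600
    n_reference: int = 50
    n_subtypes: int = 4
    mixing_proportions: tuple[float, ...] | None = None
    mean_shift_scale: float = 1.5
    correlation_perturbation_strength: float = 0.5
    missing_rate: float = 0.05
    baseline_hazard: float = 0.002  # events / month
    subtype_hazard_multipliers: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    censor_horizon: float = 120.0  # months
    treatment_probs: tuple[tuple[float, ...], ...] | None = None
    treatment_hazard_multipliers: tuple[tuple[float, ...], ...] | None = None
    omics_n_features: int = 200
    omics_n_genera: int = 60
    omics_shifted_fraction: float = 0.15
    omics_shift_size: float = 1.0  # sd units on the log scale
    qc_replicates: int = 8
    seed: int = 0
    schema: IndicatorSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        k = self.n_subtypes
        if self.mixing_proportions is None:
            self.mixing_proportions = tuple([1.0 / k] * k)
        if self.treatment_probs is None:
            base = [
                (0.70, 0.15, 0.10, 0.05),
                (0.55, 0.20, 0.15, 0.10),
                (0.30, 0.25, 0.15, 0.30),
                (0.25, 0.25, 0.15, 0.35),
            ]
            self.treatment_probs = tuple(base[min(s, 3)] for s in range(k))
        if self.treatment_hazard_multipliers is None:
            mults = []
            for s in range(k):
                row = [1.0, 1.0, 1.0, 1.0]
                if s >= 2:  # high-risk subtypes: combined IST is protective
                    row[3] = 0.3
                mults.append(tuple(row))
            self.treatment_hazard_multipliers = tuple(mults)
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.mixing_proportions) - 1.0) > 1e-12:
            raise ValueError("mixing_proportions must sum to 1")
        if len(self.mixing_proportions) != self.n_subtypes:
            raise ValueError("mixing_proportions length != n_subtypes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.correlation_perturbation_strength <= 1.0:
            raise ValueError("correlation_perturbation_strength must lie in [0, 1]")
        if any(m <= 0 for m in self.subtype_hazard_multipliers[: self.n_subtypes]):
            raise ValueError("subtype hazard multipliers must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        for row in self.treatment_hazard_multipliers:
            if any(m <= 0 for m in row):
                raise ValueError("treatment hazard multipliers must be positive")
        for row in self.treatment_probs:
            if abs(sum(row) - 1.0) > 1e-9 or any(p < 0 for p in row):
                raise ValueError("treatment_probs rows must be simplex vectors")
        if not 0.0 <= self.omics_shifted_fraction <= 1.0:
            raise ValueError("omics_shifted_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Latent structure retained for recovery tests (never fed to the pipeline)."""

    subtype_labels: pd.Series  # per-patient, values 1..K
    reference_correlation: np.ndarray
    subtype_correlations: list[np.ndarray]
    true_hazard_multipliers: tuple[float, ...]
    shifted_omics_features: set[str] = field(default_factory=set)
    shifted_genera: set[str] = field(default_factory=set)
    mean_shifts: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# correlation machinery


def nearest_psd_correlation(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix and re-normalise
    the diagonal to 1 (Higham-style eigenvalue clipping)."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    psd = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(psd))
    out = psd / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _factor_correlation(size: int, rng: np.random.Generator, rank: int = 2,
                        strength: float = 0.6) -> np.ndarray:
    """Random correlation matrix from a low-rank factor model."""
    load = rng.normal(size=(size, rank))
    load /= np.linalg.norm(load, axis=1, keepdims=True)
    load *= strength
    cov = load @ load.T
    np.fill_diagonal(cov, 1.0)
    return nearest_psd_correlation(cov)


def _rotated_block(block: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate a correlation block by a random orthogonal matrix, then
    renormalise to unit diagonal.  Stays a valid correlation matrix."""
    q = stats.ortho_group.rvs(dim=block.shape[0], random_state=rng)
    rotated = q @ block @ q.T
    d = np.sqrt(np.clip(np.diag(rotated), 1e-12, None))
    out = rotated / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _correlation_blocks(schema: IndicatorSchema) -> list[list[int]]:
    """Partition indicator indices into physiologically coherent blocks;
    cross-block reference correlation is zero, so block-level edits keep the
    full matrix PSD."""
    names = schema.names
    groups = [
        ["age", "sex", "bmi", "smoking", "drinking"],
        list(_PERTURBED_BLOCK),
        ["mest_m", "mest_e", "mest_s", "mest_t", "mest_c",
         "global_sclerosis_pct", "arteriolar_sclerosis",
         "iga_intensity", "igg_intensity", "igm_intensity", "c3_intensity"],
        ["hemoglobin", "albumin", "alt", "ast", "total_bilirubin",
         "direct_bilirubin"],
        ["total_cholesterol", "triglycerides", "hdl_cholesterol",
         "ldl_cholesterol", "fasting_glucose"],
        ["platelet_count", "serum_iga", "diabetes", "hepatitis_b"],
    ]
    covered = {n for g in groups for n in g}
    leftover = [n for n in names if n not in covered]
    if leftover:
        groups.append(leftover)
    return [[names.index(n) for n in g if n in names] for g in groups]


def build_reference_correlation(config: SimConfig) -> np.ndarray:
    """Block-diagonal reference correlation over the schema's indicators."""
    rng = np.random.default_rng(config.seed)
    f = len(config.schema)
    corr = np.eye(f)
    for idx in _correlation_blocks(config.schema):
        if len(idx) < 2:
            continue
        block = _factor_correlation(len(idx), rng)
        corr[np.ix_(idx, idx)] = block
    return corr


def build_subtype_correlations(config: SimConfig,
                               reference: np.ndarray) -> list[np.ndarray]:
    """Per-subtype correlation matrices: a convex blend of the renal block
    with a rotated copy; entries outside the block equal the reference
    exactly.  Subtype 1 keeps the reference structure unchanged."""
    rng = np.random.default_rng(config.seed + 1)
    names = config.schema.names
    idx = [names.index(n) for n in _PERTURBED_BLOCK if n in names]
    gamma = config.correlation_perturbation_strength
    out = []
    for s in range(config.n_subtypes):
        corr = reference.copy()
        if s > 0 and gamma > 0 and len(idx) >= 2:
            block = reference[np.ix_(idx, idx)]
            blended = (1 - gamma) * block + gamma * _rotated_block(block, rng)
            if np.linalg.eigvalsh(blended).min() < -1e-10:
                blended = nearest_psd_correlation(blended)
            corr[np.ix_(idx, idx)] = blended
        out.append(corr)
    return out


# ---------------------------------------------------------------------------
# latent -> clinical units


def _latent_to_clinical(latent: np.ndarray, schema: IndicatorSchema) -> pd.DataFrame:
    cols = {}
    for j, ind in enumerate(schema.indicators):
        z = latent[:, j]
        if ind.kind == "continuous":
            mu, sd = _UNIT_SCALE.get(ind.name, (0.0, 1.0))
            cols[ind.name] = mu + sd * z
        else:
            prevs = _THRESHOLD_PREV.get(ind.name, (0.5,))
            # cut points so that healthy prevalence of level >= l is prevs[l-1]
            cuts = stats.norm.ppf([1 - p for p in prevs])
            cols[ind.name] = np.searchsorted(cuts, z, side="right").astype(float)
    return pd.DataFrame(cols)


def _subtype_mean_shifts(config: SimConfig) -> np.ndarray:
    """(K x F) latent mean-shift matrix in reference-sd units."""
    names = config.schema.names
    shifts = np.zeros((config.n_subtypes, len(names)))
    for j, name in enumerate(names):
        base = _DISEASE_BASE.get(name, 0.0)
        grad = _RENAL_GRADIENT.get(name, 0.0)
        for s in range(config.n_subtypes):
            shifts[s, j] = base + grad * s * config.mean_shift_scale
    for s in range(config.n_subtypes):
        sig = _SIGNATURES[s % len(_SIGNATURES)]
        for name, coef in sig.items():
            if name in names:
                shifts[s, names.index(name)] += coef * config.mean_shift_scale
    return shifts


# ---------------------------------------------------------------------------
# operations


def generate_reference(config: SimConfig) -> CohortTable:
    """Draw the healthy reference table: complete, continuous indicators from
    a multivariate normal with the ground-truth reference correlation."""
    if config.n_reference < 10:
        raise ValueError("n_reference must be at least 10")
    corr = build_reference_correlation(config)
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("reference correlation is not positive semi-definite")
    rng = np.random.default_rng(config.seed + 10)
    latent = rng.multivariate_normal(
        np.zeros(len(config.schema)), corr, size=config.n_reference,
        method="cholesky",
    )
    cols = {}
    for j, ind in enumerate(config.schema.indicators):
        mu, sd = _UNIT_SCALE.get(ind.name, (0.0, 1.0))
        cols[ind.name] = mu + sd * latent[:, j]
    data = pd.DataFrame(cols)
    data.index = [f"H{i:04d}" for i in range(config.n_reference)]
    return CohortTable(data, config.schema)


def generate_patients(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw the patient cohort and its ground truth.

    Each patient is sampled from the shifted-mean, perturbed-correlation
    multivariate normal of its subtype; binary/ordinal indicators are
    thresholded from the latent Gaussian; missingness is applied completely
    at random at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 20)
    reference = build_reference_correlation(config)
    subtype_corrs = build_subtype_correlations(config, reference)
    shifts = _subtype_mean_shifts(config)

    labels = rng.choice(config.n_subtypes, size=config.n_patients,
                        p=np.asarray(config.mixing_proportions))
    counts = np.bincount(labels, minlength=config.n_subtypes)
    expected = np.asarray(config.mixing_proportions) * config.n_patients
    for s in range(config.n_subtypes):
        if expected[s] < 1 or counts[s] == 0:
            warnings.warn(
                f"subtype {s + 1} has {counts[s]} members "
                f"(expected {expected[s]:.1f}) at n={config.n_patients}",
                stacklevel=2,
            )
    latent = np.empty((config.n_patients, len(config.schema)))
    for s in range(config.n_subtypes):
        rows = np.where(labels == s)[0]
        if rows.size == 0:
            continue
        latent[rows] = rng.multivariate_normal(
            shifts[s], subtype_corrs[s], size=rows.size, method="cholesky"
        )
    data = _latent_to_clinical(latent, config.schema)
    ids = [f"P{i:05d}" for i in range(config.n_patients)]
    data.index = ids

    if config.missing_rate > 0:
        mask = rng.random(data.shape) < config.missing_rate
        data = data.mask(pd.DataFrame(mask, index=data.index, columns=data.columns))

    truth = GroundTruth(
        subtype_labels=pd.Series(labels + 1, index=ids, name="subtype"),
        reference_correlation=reference,
        subtype_correlations=subtype_corrs,
        true_hazard_multipliers=tuple(
            config.subtype_hazard_multipliers[: config.n_subtypes]
        ),
        mean_shifts=pd.DataFrame(shifts, columns=config.schema.names,
                                 index=range(1, config.n_subtypes + 1)),
    )
    return CohortTable(data, config.schema), truth


def generate_survival(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Exponential event times for the composite renal endpoint.

    hazard = baseline x subtype multiplier x treatment multiplier; censoring
    uniform on (0, censor_horizon).  Returns a table with columns
    ``patient_id, time_months, event, treatment``.
    """
    if truth.subtype_labels is None or len(truth.subtype_labels) == 0:
        raise ValueError("ground truth carries no subtype labels")
    rng = np.random.default_rng(config.seed + 30)
    subtype = truth.subtype_labels.to_numpy() - 1
    n = subtype.size

    arms = np.empty(n, dtype=int)
    for s in range(config.n_subtypes):
        rows = np.where(subtype == s)[0]
        if rows.size:
            arms[rows] = rng.choice(4, size=rows.size,
                                    p=np.asarray(config.treatment_probs[s]))

    hazard = (
        config.baseline_hazard
        * np.asarray(config.subtype_hazard_multipliers)[subtype]
        * np.array([config.treatment_hazard_multipliers[s][a]
                    for s, a in zip(subtype, arms)])
    )
    if np.any(hazard <= 0):
        raise ValueError("nonpositive hazard encountered")
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, max(config.censor_horizon, 1e-12), size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    time = np.clip(time, 1e-6, None)
    return pd.DataFrame(
        {
            "patient_id": truth.subtype_labels.index,
            "time_months": time,
            "event": event,
            "treatment": [TREATMENT_ARMS[a] for a in arms],
        }
    ).set_index("patient_id")


def generate_trajectories(
    truth: GroundTruth,
    config: SimConfig,
    visits: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0),
) -> pd.DataFrame:
    """Per-visit serum creatinine and 24 h urine protein, long format.

    Subtype-dependent linear drift plus noise: higher subtypes have steeper
    creatinine rise; urine protein dips at 6 months under treatment then
    rebounds in the high-risk subtypes.
    """
    rng = np.random.default_rng(config.seed + 40)
    subtype = truth.subtype_labels.to_numpy() - 1
    ids = truth.subtype_labels.index.to_numpy()
    cr_mu, cr_sd = _UNIT_SCALE["serum_creatinine"]
    up_mu, up_sd = _UNIT_SCALE["urine_protein_24h"]
    rows = []
    cr_slope = np.array([0.0, 0.1, 0.5, 1.2])[np.clip(subtype, 0, 3)]  # umol/L/month
    up_base = up_mu + up_sd * (1.0 + 0.9 * subtype * config.mean_shift_scale)
    cr_base = cr_mu + cr_sd * 0.8 * subtype * config.mean_shift_scale
    for v in visits:
        rebound = np.where(subtype >= 2, 0.01 * v, -0.002 * v)  # g/24h per month
        dip = np.where(v >= 6, -0.15 * up_sd, 0.0)
        cr = cr_base + cr_slope * v + rng.normal(0, cr_sd * 0.2, size=ids.size)
        up = np.clip(
            up_base + dip + rebound + rng.normal(0, up_sd * 0.3, size=ids.size),
            0.01, None,
        )
        rows.append(pd.DataFrame({
            "patient_id": ids, "visit_month": v,
            "serum_creatinine": cr, "urine_protein_24h": up,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_omics(truth: GroundTruth, config: SimConfig):
    """Risk-group-shifted omics tables.

    Returns ``(metabolites, genera)``: a log-normal serum-metabolite intensity
    table with QC replicate injections whose per-feature CVs straddle the 20%
    quality threshold, and a logistic-normal genus relative-abundance table
    (rows closed to sum 1).  Features in ``truth.shifted_omics_features`` /
    ``truth.shifted_genera`` differ in mean between the high-risk (subtypes
    3..K) and low-risk (1..2) groups.
    """
    from .omics import OmicsTable  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed + 50)
    subtype = truth.subtype_labels.to_numpy()
    high = subtype >= 3
    ids = truth.subtype_labels.index

    p = config.omics_n_features
    feat_names = [f"met_{j:04d}" for j in range(p)]
    n_shift = int(round(config.omics_shifted_fraction * p))
    shifted_idx = rng.choice(p, size=n_shift, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_shift)

    mu = rng.normal(10.0, 1.0, size=p)
    sd = np.full(p, 0.4)
    logx = rng.normal(mu, sd, size=(len(ids), p))
    for idx, sign in zip(shifted_idx, signs):
        logx[high, idx] += sign * config.omics_shift_size * sd[idx]
    metab = pd.DataFrame(np.exp(logx), index=ids, columns=feat_names)

    # QC replicate injections: per-feature CVs drawn to straddle 20%
    target_cv = rng.uniform(0.05, 0.40, size=p)
    qc_sigma = np.sqrt(np.log1p(target_cv**2))
    qc_log = rng.normal(mu, qc_sigma, size=(config.qc_replicates, p))
    qc = pd.DataFrame(
        np.exp(qc_log),
        index=[f"QC_{r + 1}" for r in range(config.qc_replicates)],
        columns=feat_names,
    )

    g = config.omics_n_genera
    genus_names = [f"genus_{j:03d}" for j in range(g)]
    n_gshift = max(1, int(round(config.omics_shifted_fraction * g)))
    gshift_idx = rng.choice(g, size=n_gshift, replace=False)
    gsigns = rng.choice([-1.0, 1.0], size=n_gshift)
    alpha = rng.normal(0.0, 1.0, size=g)
    z = rng.normal(alpha, 0.7, size=(len(ids), g))
    for idx, sign in zip(gshift_idx, gsigns):
        z[high, idx] += sign * 0.8 * config.omics_shift_size
    expz = np.exp(z - z.max(axis=1, keepdims=True))
    genera = pd.DataFrame(expz / expz.sum(axis=1, keepdims=True),
                          index=ids, columns=genus_names)

    truth.shifted_omics_features = {feat_names[j] for j in shifted_idx}
    truth.shifted_genera = {genus_names[j] for j in gshift_idx}
    return (
        OmicsTable(data=metab, qc=qc, modality="metabolite",
                   true_cv=pd.Series(target_cv, index=feat_names)),
        OmicsTable(data=genera, qc=None, modality="genus"),
    )
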