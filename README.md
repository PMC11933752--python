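# nephronet

Network-biomarker risk stratification for IgA nephropathy (IgAN).

IgAN is the most common primary glomerular disease and its course is highly
heterogeneous — roughly 40% of patients progress to kidney failure while
others stay stable for decades. Classical risk tools score isolated renal
indicators (proteinuria, eGFR, Oxford MEST-C). `nephronet` instead
represents each patient by a **sample-specific perturbation network**: how
strongly adding that one patient to a cohort of 50 healthy references
changes every pairwise Pearson correlation among 40 clinical indicators,

    ΔPCC(i,j) = PCC_{ref+patient}(i,j) − PCC_ref(i,j),
    Z(i,j)    = ΔPCC(i,j) / ((1 − PCC_ref(i,j)²)/(n−1)),   p two-sided normal,

keeping edges with p < α (default 0.05). Each network is summarised by a
46-attribute feature vector (40 node degrees; largest-component diameter
and average clustering coefficient; non-isolated node count, edge count,
component count, edge density), and patients are clustered on a UMAP
embedding of these vectors with k-means into k = 4 strata, renumbered so
stratum 1 has the best renal profile (highest mean eGFR) and stratum 4 the
worst. This scheme — **KMN**, k-means on network biomarkers — is evaluated
prognostically (Kaplan–Meier, log-rank, adjusted Cox hazard ratios, the AUC
achievable from the cluster label alone) and interpreted via a surrogate
gradient-boosted classifier with Shapley attribution. Metabolomic and
gut-microbiome tables can be contrasted between the resulting low-risk
(strata 1–2) and high-risk (strata 3–4) groups with QC filtering, sum
normalization, PLS-DA + VIP scoring, fold changes, p-thresholded
correlation networks and Mantel tests.

Because no patient-level data are public, the package includes a
first-class synthetic cohort generator (clinical indicators with four
latent severity subtypes, survival with subtype-proportional hazards and
treatment effects, shifted omics) that retains ground truth for recovery
testing. See `docs/methods.md` for the model, the generator's assumptions
and what passing tests do and do not demonstrate.

Audience: biostatisticians and nephrology researchers who want to fit,
validate, or probe network-biomarker stratifications on their own cohorts,
and methods researchers who need a reproducible testbed for
perturbation-network clustering.

## Worked example

```python
import nephronet as nn

cfg = nn.SimConfig(n_patients=600, seed=1)     # default study conditions
reference = nn.generate_reference(cfg)          # 50 healthy samples
patients, truth = nn.generate_patients(cfg)     # 40 indicators, 5% missing
survival = nn.generate_survival(truth, cfg)

model = nn.fit_scheme(patients, nn.KMN, reference=reference, seed=1)
print(model.training_strata.value_counts().sort_index())
```

```
stratum
1    154
2    155
3    138
4    153
```

Four severity-ordered strata. Their prognostic content:

```python
stat, p = nn.logrank_test(survival.join(patients.data), model.training_strata)
auc = nn.cluster_label_auc(model.training_strata, survival["event"], seed=1)
print(f"log-rank p = {p:.2e}")
print(f"cluster-label AUC (10-fold CV) = {auc.auc_cv:.3f}, "
      f"analytic rank-AUC oracle = {auc.auc_rank_oracle:.3f}")
```

```
log-rank p = 9.97e-17
cluster-label AUC (10-fold CV) = 0.690, analytic rank-AUC oracle = 0.706
```

The strata separate survival strongly, and a boosted model given *only*
the stratum label reaches the analytic ceiling implied by the per-stratum
event rates (the cross-validated AUC sits within 0.02 of the oracle), i.e.
the label itself carries the prognostic signal. Adjusted Cox hazard ratios
versus stratum 1 for this run were 1.49 / 2.53 / 1.57 for strata 2–4
(stratum 4 is compressed by the protective combined-immunosuppression
effect the generator plants in the high-risk subtypes).

The same pipeline runs from the shell:

```bash
nephronet run-all --n-patients 600 --seed 1 --out artifacts/
nephronet simulate --n-patients 200 --seed 9 --out external/
nephronet assign --model artifacts/cluster_model.joblib \
    --patients external/patients.csv --out external/labels.csv
```

`run-all` persists every intermediate (labels, network feature matrix,
frozen models, evaluation tables, attribution ranking, omics VIP/fold
changes) plus a `report.json` with the resolved configuration.

## Layout

- `src/nephronet/simulate.py` — synthetic cohorts with retained ground truth
- `src/nephronet/preprocess.py` — imputation, standardization, reduction (frozen transforms)
- `src/nephronet/networks.py` — reference network and per-patient SSN statistics
- `src/nephronet/features.py` — 46-attribute catalog, ego and cluster-aggregate networks
- `src/nephronet/stratify.py` — six clustering schemes, severity ordering, external assignment
- `src/nephronet/evaluate.py` — KM/log-rank/Cox, cluster-label AUC, scheme comparison, Cohen d, trajectories, treatment contrasts
- `src/nephronet/interpret.py` — surrogate classifier + Shapley attribution
- `src/nephronet/omics.py` — QC/normalization, PLS-DA + VIP, risk regrouping, correlation networks, Mantel
- `src/nephronet/{io,pipeline,cli}.py` — CSV I/O with schema sidecars, end-to-end pipeline, CLI
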