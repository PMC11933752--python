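"""Survival evaluation, cluster-label AUC, effect sizes, contrasts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nephronet.evaluate import (
    cluster_label_auc,
    cohen_d,
    cohen_d_matrix,
    compare_scheme_aucs,
    cox_adjusted,
    km_estimate,
    logrank_test,
    rank_auc_oracle,
    trajectory_summary,
    treatment_contrast,
)
from nephronet.simulate import SimConfig, generate_survival
from nephronet.simulate import GroundTruth


def _records(times, events, index=None, **extra):
    idx = index or [f"p{i}" for i in range(len(times))]
    df = pd.DataFrame({"time_months": times, "event": events}, index=idx)
    for k, v in extra.items():
        df[k] = v
    return df


def _sim_survival(subtypes, seed=0, **cfg_kw):
    labels = pd.Series(subtypes, index=[f"p{i}" for i in range(len(subtypes))],
                       name="subtype")
    cfg = SimConfig(n_patients=len(subtypes), seed=seed, **cfg_kw)
    truth = GroundTruth(
        subtype_labels=labels, reference_correlation=np.eye(2),
        subtype_correlations=[np.eye(2)] * 4,
        true_hazard_multipliers=cfg.subtype_hazard_multipliers,
    )
    return generate_survival(truth, cfg), labels


class TestKaplanMeier:
    def test_no_events_gives_flat_curve(self):
        rec = _records([5, 10, 15.0], [False] * 3)
        km = km_estimate(rec, pd.Series(1, index=rec.index))
        assert np.allclose(km[1].survival, 1.0)

    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rec = _records(times, [True] * 5)
        km = km_estimate(rec, pd.Series(1, index=rec.index))[1]
        for t, s in zip(km.timeline, km.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_survival_non_increasing(self):
        rec = _records([3, 1, 4, 1, 5, 9.0], [True, False, True, True, False, True])
        km = km_estimate(rec, pd.Series(1, index=rec.index))[1]
        assert (np.diff(km.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        rec1 = _records([1, 2, 3, 4, 5.0], [True, False, True, True, False])
        rec = pd.concat([rec1, rec1.set_index(rec1.index + "b")])
        groups = pd.Series([1] * 5 + [2] * 5, index=rec.index)
        stat, p = logrank_test(rec, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        rec = _records([1, 2.0], [True, True])
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(rec, pd.Series(1, index=rec.index))

    def test_strong_hazard_contrast_detected(self):
        surv, labels = _sim_survival([1] * 500 + [4] * 500, seed=1,
                                     subtype_hazard_multipliers=(1, 2, 4, 8))
        strata = labels.rename("stratum")
        _, p = logrank_test(surv, strata)
        assert p < 0.001


class TestCox:
    def test_null_hazards_covered(self):
        # equal hazards: HR estimates near 1 and CIs usually cover 1
        cover = 0
        reps = 40
        for seed in range(reps):
            surv, labels = _sim_survival(
                [1] * 150 + [2] * 150, seed=seed,
                subtype_hazard_multipliers=(1.0, 1.0, 1.0, 1.0),
                baseline_hazard=0.01)
            res = cox_adjusted(surv, labels, covariates=())
            if res.ci_lower.iloc[0] <= 1.0 <= res.ci_upper.iloc[0]:
                cover += 1
        assert cover / reps >= 0.85

    def test_hazard_ratio_recovered(self):
        surv, labels = _sim_survival(
            [1] * 400 + [2] * 400, seed=3,
            subtype_hazard_multipliers=(1.0, 2.0, 1.0, 1.0),
            baseline_hazard=0.01)
        res = cox_adjusted(surv, labels, covariates=())
        assert res.ci_lower.iloc[0] <= 2.0 <= res.ci_upper.iloc[0]
        assert res.hr.iloc[0] == pytest.approx(2.0, rel=0.35)

    def test_zero_events_rejected(self):
        rec = _records([1, 2, 3, 4.0], [False] * 4)
        with pytest.raises(ValueError, match="event"):
            cox_adjusted(rec, pd.Series([1, 1, 2, 2], index=rec.index))


class TestClusterLabelAUC:
    def test_equal_event_rates_uninformative(self):
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(800)]
        strata = pd.Series(rng.integers(1, 5, 800), index=idx)
        outcome = pd.Series(rng.random(800) < 0.3, index=idx)
        res = cluster_label_auc(strata, outcome, seed=0)
        assert abs(res.auc_cv - 0.5) < 0.06

    def test_events_only_in_stratum_4_reach_rank_ceiling(self):
        idx = [f"p{i}" for i in range(400)]
        strata = pd.Series([1, 2, 3, 4] * 100, index=idx)
        outcome = pd.Series([False] * 400, index=idx)
        outcome[strata == 4] = True
        res = cluster_label_auc(strata, outcome, seed=0)
        assert res.auc_rank_oracle == pytest.approx(1.0)
        assert res.auc_cv == pytest.approx(1.0, abs=0.01)

    def test_model_matches_rank_oracle(self):
        surv, labels = _sim_survival(
            list(np.repeat([1, 2, 3, 4], 250)), seed=5,
            treatment_hazard_multipliers=tuple((1.0,) * 4 for _ in range(4)))
        res = cluster_label_auc(labels.rename("stratum"), surv["event"], seed=1)
        # single categorical predictor: the apparent ROC is fully determined
        # by per-stratum event rates, so the boosted model hits the oracle
        assert res.auc_apparent == pytest.approx(res.auc_rank_oracle, abs=1e-9)
        assert abs(res.auc_cv - res.auc_rank_oracle) <= 0.02

    def test_single_class_outcome_rejected(self):
        idx = ["a", "b", "c", "d"]
        with pytest.raises(ValueError, match="single class"):
            cluster_label_auc(pd.Series([1, 2, 1, 2], index=idx),
                              pd.Series([True] * 4, index=idx))


class TestCompareSchemes:
    def test_identical_lists_p_one(self):
        p = compare_scheme_aucs({"a": [0.7] * 10, "b": [0.7] * 10})
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_disjoint_lists_minimal_p(self):
        from scipy.stats import mannwhitneyu

        a, b = [0.9] * 10, [0.5] * 10
        p = compare_scheme_aucs({"a": a, "b": b})
        expected = mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p.loc["a", "b"] == pytest.approx(expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        a = list(rng.random(10))
        b = list(rng.random(10))
        p1 = compare_scheme_aucs({"a": a, "b": b}).loc["a", "b"]
        p2 = compare_scheme_aucs({"a": a[::-1], "b": b[::-1]}).loc["a", "b"]
        assert p1 == p2

    def test_too_few_rounds_rejected(self):
        with pytest.raises(ValueError, match="3 rounds"):
            compare_scheme_aucs({"a": [0.5, 0.6], "b": [0.5, 0.6]})


class TestCohenD:
    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1, 1, 2000)
        b = rng.normal(0, 1, 2000)
        assert cohen_d(a, b) == pytest.approx(1.0, abs=0.1)

    def test_identical_groups_zero(self):
        x = np.arange(10.0)
        assert cohen_d(x, x) == 0.0

    def test_sampling_error_bound(self):
        rng = np.random.default_rng(3)
        d = cohen_d(rng.normal(0.8, 1, 30), rng.normal(0, 1, 30))
        assert abs(d - 0.8) < 0.35

    def test_matrix_antisymmetric(self):
        rng = np.random.default_rng(4)
        idx = [f"p{i}" for i in range(90)]
        table = pd.DataFrame(rng.normal(size=(90, 3)), index=idx,
                             columns=["a", "b", "c"])
        strata = pd.Series([1, 2, 3] * 30, index=idx)
        m = cohen_d_matrix(table, strata)
        for col in table.columns:
            assert np.allclose(m.d[col].to_numpy(), -m.d[col].to_numpy().T)
            assert np.allclose(np.diag(m.d[col]), 0.0)

    def test_zero_pooled_sd_flagged_not_numeric(self):
        assert np.isnan(cohen_d(np.ones(5), np.ones(5)))


class TestTrajectories:
    @staticmethod
    def _long(values_by_patient, visits=(0.0, 6.0)):
        rows = []
        for pid, vals in values_by_patient.items():
            for v, x in zip(visits, vals):
                rows.append({"patient_id": pid, "visit_month": v,
                             "serum_creatinine": x, "urine_protein_24h": x})
        return pd.DataFrame(rows)

    def test_constant_series_flat(self):
        long = self._long({"a": [70, 70], "b": [70, 70]})
        strata = pd.Series({"a": 1, "b": 1})
        out = trajectory_summary(long, strata, visits=(0.0, 6.0))
        assert (out["mean"] == 70).all()

    def test_single_patient_ci_undefined(self):
        long = self._long({"a": [70, 80]})
        out = trajectory_summary(long, pd.Series({"a": 1}), visits=(0.0, 6.0))
        assert out["ci_undefined"].all()
        assert (out["n"] == 1).all()

    def test_rising_series_positive_slope(self):
        long = self._long({f"p{i}": [70 + i, 90 + i] for i in range(5)})
        out = trajectory_summary(long, pd.Series(1, index=[f"p{i}" for i in range(5)]),
                                 visits=(0.0, 6.0))
        cr = out[out["indicator"] == "serum_creatinine"].sort_values("visit_month")
        assert cr["mean"].diff().dropna().gt(0).all()

    def test_unknown_visit_rejected(self):
        long = self._long({"a": [1, 2]})
        with pytest.raises(ValueError, match="visit"):
            trajectory_summary(long, pd.Series({"a": 1}), visits=(0.0, 99.0))


class TestTreatmentContrast:
    def test_identical_arms_nonsignificant(self):
        rng = np.random.default_rng(5)
        n = 200
        rec = _records(rng.exponential(50, n), rng.random(n) < 0.6,
                       treatment=np.where(np.arange(n) % 2 == 0, "SC", "GS+II"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tc = treatment_contrast(rec)
        assert tc.global_logrank[1] > 0.05

    def test_protective_combination_detected(self):
        surv, labels = _sim_survival([3] * 400, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tc = treatment_contrast(surv, stratum=3, covariates=())
        assert tc.combo_vs_sc is not None
        assert tc.combo_vs_sc.hr.iloc[0] < 1.0
        assert tc.combo_vs_sc.ci_upper.iloc[0] < 1.0

    def test_single_arm_rejected(self):
        rec = _records([1, 2, 3.0], [True, True, False], treatment="SC")
        with pytest.raises(ValueError, match="two nonempty arms"):
            treatment_contrast(rec)
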