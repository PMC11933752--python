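"""QC filtering, normalization, PLS-DA/VIP, networks, Mantel tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephronet.omics import (
    OmicsTable,
    compute_vip,
    correlation_network,
    distance_matrix,
    fit_plsda,
    fold_change,
    mantel_test,
    qc_filter,
    regroup_risk,
    sum_normalize,
)


def _table(data, qc=None):
    df = pd.DataFrame(np.asarray(data, dtype=float))
    df.columns = [f"m{i}" for i in range(df.shape[1])]
    df.index = [f"s{i}" for i in range(df.shape[0])]
    qcf = None
    if qc is not None:
        qcf = pd.DataFrame(np.asarray(qc, dtype=float), columns=df.columns,
                           index=[f"QC_{i}" for i in range(len(qc))])
    return OmicsTable(data=df, qc=qcf)


class TestQCFilter:
    def test_constant_qc_kept_variable_qc_removed(self):
        # m0: QC (1,1,1) CV 0 kept; m1: QC (1,2,3) CV ~0.408 removed
        table = _table([[1, 1], [2, 2]], qc=[[1, 1], [1, 2], [1, 3]])
        filtered, removed = qc_filter(table, cv_threshold=0.20)
        assert removed == ["m1"]
        assert filtered.features == ["m0"]
        cv = table.qc_cv()
        assert cv["m1"] == pytest.approx(1.0 / 2.0, abs=1e-9)  # sd=1, mean=2

    def test_infinite_threshold_is_identity(self):
        table = _table([[1, 2]], qc=[[1, 5], [2, 1], [9, 2]])
        filtered, removed = qc_filter(table, cv_threshold=np.inf)
        assert removed == [] and filtered.features == table.features

    def test_missing_qc_rejected(self):
        with pytest.raises(ValueError, match="QC"):
            qc_filter(_table([[1, 2]]))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="3 QC"):
            qc_filter(_table([[1, 2]], qc=[[1, 1], [2, 2]]))


class TestSumNormalize:
    def test_rows_closed(self):
        out = sum_normalize(_table([[2, 2], [1, 3]]))
        assert np.allclose(out.data.to_numpy(), [[0.5, 0.5], [0.25, 0.75]])
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-12)

    def test_already_closed_unchanged(self):
        out = sum_normalize(_table([[0.3, 0.7]]))
        assert np.allclose(out.data.to_numpy(), [[0.3, 0.7]])

    def test_zero_sum_row_named(self):
        with pytest.raises(ValueError, match="s1"):
            sum_normalize(_table([[1, 1], [0, 0]]))


class TestPLSDA:
    @staticmethod
    def _classed(n=200, p=5, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        y = pd.Series(np.repeat(["a", "b"], n // 2))
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"m{i}" for i in range(p)])
        if informative:
            x["m0"] = np.where(y == "b", 1.0, -1.0)
        return x, y

    def test_exact_response_column_dominates_first_weight(self):
        x, y = self._classed()
        model = fit_plsda(x, y, n_components=2)
        assert abs(model.weights[0, 0]) > 0.95

    def test_permuted_labels_explain_little(self):
        rng = np.random.default_rng(1)
        x, y = self._classed(seed=1, informative=False)
        model = fit_plsda(x, y, n_components=2)
        null_fracs = [
            fit_plsda(x, pd.Series(rng.permutation(y.to_numpy())), 2).explained_y_fraction
            for _ in range(20)
        ]
        # observed explained variance is typical of the permutation null
        assert model.explained_y_fraction < np.quantile(null_fracs, 0.99) + 0.05

    def test_single_class_rejected(self):
        x, _ = self._classed()
        with pytest.raises(ValueError, match="two classes"):
            fit_plsda(x, pd.Series(["a"] * len(x)), 1)

    def test_zero_components_rejected(self):
        x, y = self._classed()
        with pytest.raises(ValueError, match="one component"):
            fit_plsda(x, y, 0)

    def test_four_class_one_hot(self):
        rng = np.random.default_rng(2)
        y = pd.Series(np.repeat([1, 2, 3, 4], 20))
        x = pd.DataFrame(rng.normal(size=(80, 6)),
                         columns=[f"m{i}" for i in range(6)])
        x["m0"] += y.to_numpy() * 2.0
        model = fit_plsda(x, y, n_components=2)
        assert model.y_loadings.shape[0] == 4
        assert (model.ssy >= 0).all()


class TestVIP:
    def test_equal_weights_single_component_all_one(self):
        # forced by normalization: one component, equal |w| over p variables
        rng = np.random.default_rng(3)
        n, p = 40, 6
        latent = rng.normal(size=n)
        x = pd.DataFrame(np.tile(latent[:, None], (1, p)) + rng.normal(size=(n, p)) * 1e-9,
                         columns=[f"m{i}" for i in range(p)])
        y = pd.Series(np.where(latent > 0, "a", "b"))
        model = fit_plsda(x, y, n_components=1)
        vip = compute_vip(model)
        assert np.allclose(vip.vip, 1.0, atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 40),
           p=st.integers(3, 8), a=st.integers(1, 2))
    def test_vip_square_sum_equals_p_property(self, seed, n, p, a):
        """Sum of squared VIPs equals the variable count for every fitted
        model, whatever the data."""
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"m{i}" for i in range(p)])
        y = pd.Series(rng.integers(0, 2, n))
        if y.nunique() < 2:
            y.iloc[0] = 1 - y.iloc[0]
        vip = compute_vip(fit_plsda(x, y, n_components=a)).vip
        assert (vip**2).sum() == pytest.approx(p, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_vip_identity_and_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(8, 5)),
                         columns=[f"m{i}" for i in range(5)])
        y = pd.Series(rng.integers(0, 2, 8))
        if y.nunique() < 2:
            y.iloc[0] = 1 - y.iloc[0]
        model = fit_plsda(x, y, n_components=2)
        vip = compute_vip(model)
        p = 5
        assert (vip.vip**2).sum() == pytest.approx(p, abs=1e-8)
        # brute-force evaluation of the formula term by term
        oracle = np.zeros(p)
        denom = model.ssy.sum()
        for j in range(p):
            acc = 0.0
            for a in range(model.n_components):
                w = model.weights[:, a]
                acc += model.ssy[a] * (w[j] / np.linalg.norm(w)) ** 2
            oracle[j] = np.sqrt(p * acc / denom)
        assert np.abs(vip.vip.to_numpy() - oracle).max() <= 1e-10


class TestRiskRegrouping:
    def test_mapping(self):
        strata = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4})
        risk = regroup_risk(strata)
        assert risk.to_dict() == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..4"):
            regroup_risk(pd.Series([1, 5]))


class TestFoldChange:
    def test_ratios_and_flags(self):
        table = _table([[1, 2, 0], [1, 2, 0], [2, 2, 0], [2, 2, 0]])
        groups = pd.Series(["low", "low", "high", "high"], index=table.data.index)
        fc = fold_change(table, groups)
        assert fc.loc["m0", "fold_change"] == pytest.approx(2.0)
        assert fc.loc["m1", "fold_change"] == pytest.approx(1.0)
        assert bool(fc.loc["m2", "undefined"])
        assert fc.loc["m2", "direction"] == "undefined"

    def test_empty_group_rejected(self):
        table = _table([[1, 2]])
        with pytest.raises(ValueError, match="empty"):
            fold_change(table, pd.Series(["low"], index=table.data.index))


class TestCorrelationNetwork:
    def test_perfect_correlation_edge_present(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(0).normal(size=10)})
        net = correlation_network(df, method="pearson")
        edge = net.edges[(net.edges["node_i"] == "a") & (net.edges["node_j"] == "b")]
        assert len(edge) == 1
        assert edge["r"].iloc[0] == pytest.approx(1.0)

    def test_null_edge_fraction_near_alpha(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 80)),
                          columns=[f"f{i}" for i in range(80)])
        net = correlation_network(df, method="pearson", alpha=0.05)
        frac = len(net.edges) / (80 * 79 / 2)
        assert abs(frac - 0.05) < 0.03

    def test_constant_feature_skipped_with_warning(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10),
                           "c": np.arange(10.0)[::-1]})
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(df)
        assert "b" in net.skipped and "b" not in net.nodes

    def test_spearman_supported(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": np.exp(x)})
        net = correlation_network(df, method="spearman")
        assert net.edges["r"].iloc[0] == pytest.approx(1.0)


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(3)
        d = distance_matrix(pd.DataFrame(rng.normal(size=(15, 4))))
        res = mantel_test(d, d, permutations=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_independent_matrices_p_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(20):
            d1 = distance_matrix(pd.DataFrame(rng.normal(size=(20, 3))))
            d2 = distance_matrix(pd.DataFrame(rng.normal(size=(20, 3))))
            ps.append(mantel_test(d1, d2, permutations=199, seed=1).p)
        assert 0.2 < np.mean(ps) < 0.8

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(bad, bad)
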