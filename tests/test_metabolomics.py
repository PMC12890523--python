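"""Imputation, scaling, PLS-DA/VIP identities, volcano, and pathway impact."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccfmtdna.metabolomics import (MetaboliteMatrix, impute_knn,
                                   log2_autoscale, loocv_q2, pathway_impact,
                                   plsda_fit, significant_by_vip, vip_scores,
                                   volcano)
from ccfmtdna.synthdata import make_metabolite_matrix

SEED = 0


def matrix_from(values, groups=None, names=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if groups is None:
        groups = ["a"] * (n // 2) + ["b"] * (n - n // 2)
    idx = [f"s{i}" for i in range(n)]
    names = names or [f"m{j}" for j in range(values.shape[1])]
    return MetaboliteMatrix(pd.DataFrame(values, index=idx, columns=names),
                            pd.Series(groups, index=idx))


class TestImputeKnn:
    def test_complete_matrix_unchanged(self):
        mm = matrix_from(np.arange(1, 17).reshape(4, 4))
        out = impute_knn(mm)
        assert out.data.equals(mm.data)

    def test_identical_neighbor_supplies_value(self):
        # column m1 duplicates m0 except for the missing entry: with k=1 the
        # imputed value is the twin's value at that sample
        vals = np.array([[1.0, 1.0, 9.0],
                         [2.0, 2.0, 8.0],
                         [3.0, np.nan, 7.0],
                         [4.0, 4.0, 6.0]])
        out = impute_knn(matrix_from(vals), k=1)
        assert out.data.iloc[2, 1] == pytest.approx(3.0)

    def test_constant_matrix_imputes_constant(self):
        vals = np.full((4, 3), 5.0)
        vals[1, 2] = np.nan
        out = impute_knn(matrix_from(vals), k=2)
        assert out.data.iloc[1, 2] == pytest.approx(5.0)

    def test_all_missing_column_rejected(self):
        vals = np.ones((4, 3))
        vals[:, 1] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_knn(matrix_from(vals))

    def test_observed_entries_untouched(self):
        mm, _ = make_metabolite_matrix(5, 30, 0, 0.0, missing_rate=0.2, seed=SEED)
        out = impute_knn(mm)
        obs = ~mm.data.isna()
        assert np.allclose(out.data.to_numpy()[obs.to_numpy()],
                           mm.data.to_numpy()[obs.to_numpy()])
        assert not out.data.isna().any().any()


class TestLog2Autoscale:
    def test_two_point_column_scales_to_plus_minus_sqrt_half(self):
        # {2, 8} -> log2 {1, 3} -> centred {-1, +1} -> /sd(n-1)=sqrt(2)
        out = log2_autoscale(pd.DataFrame({"m0": [2.0, 8.0]}))
        assert out["m0"].tolist() == pytest.approx(
            [-0.7071067811865476, 0.7071067811865476])

    def test_columns_centred_and_unit_sd(self):
        mm, _ = make_metabolite_matrix(6, 20, 0, 0.0, seed=SEED)
        out = log2_autoscale(mm)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0)

    def test_non_positive_entry_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            log2_autoscale(pd.DataFrame({"m0": [1.0, 2.0], "m1": [0.0, 3.0]}))

    def test_zero_variance_column_named(self):
        with pytest.raises(ValueError, match="m1"):
            log2_autoscale(pd.DataFrame({"m0": [1.0, 2.0], "m1": [5.0, 5.0]}))


class TestPlsda:
    def test_discriminating_metabolite_gets_largest_weight(self, rng):
        n = 12
        y = np.array([-1.0] * 6 + [1.0] * 6)
        X = rng.normal(size=(n, 8))
        X[:, 3] = y * 2.0 + rng.normal(0, 0.05, n)
        model = plsda_fit(X, y, n_components=1)
        assert np.argmax(np.abs(model.weights[0])) == 3

    def test_scores_orthogonal_across_components(self, rng):
        X = rng.normal(size=(14, 10))
        y = np.array([-1.0] * 7 + [1.0] * 7)
        model = plsda_fit(X, y, n_components=3)
        T = model.x_scores
        g = T.T @ T
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(g)).max()

    def test_weights_unit_norm(self, rng):
        X = rng.normal(size=(10, 6))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        model = plsda_fit(X, y, n_components=2)
        assert np.allclose(np.linalg.norm(model.weights, axis=1), 1.0)

    def test_prediction_correlates_with_planted_effect(self):
        mm, _ = make_metabolite_matrix(10, 50, 10, 2.0, noise_sd=0.2, seed=SEED)
        X = log2_autoscale(mm)
        model = plsda_fit(X, mm.groups, n_components=1)
        yhat = model.predict(X)
        y = np.where(mm.groups == mm.group_labels[1], 1.0, -1.0)
        assert np.corrcoef(yhat, y)[0, 1] > 0.9

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            plsda_fit(X, np.ones(6))

    def test_matches_sklearn_pls1(self, rng):
        # independent cross-check: scikit-learn's PLSRegression implements
        # the same single-response NIPALS model
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(16, 12))
        y = np.array([-1.0] * 8 + [1.0] * 8)
        ours = plsda_fit(X, y, n_components=2).predict(X)
        ref = PLSRegression(n_components=2, scale=False).fit(X, y)
        theirs = ref.predict(X).ravel()
        assert np.allclose(ours, theirs, atol=1e-8)


class TestLoocvQ2:
    def test_perfect_predictor_gives_q2_one(self):
        y = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        X = y.reshape(-1, 1)
        assert loocv_q2(X, y, n_components=1) == pytest.approx(1.0)

    def test_press_equal_tss_gives_zero(self):
        # predictions pinned at the grand mean make PRESS equal TSS
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        press = float(((y - y.mean()) ** 2).sum())
        tss = press
        assert 1.0 - press / tss == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            loocv_q2(np.zeros((2, 3)), np.array([-1.0, 1.0]))

    def test_planted_effect_gives_high_q2(self):
        mm, _ = make_metabolite_matrix(10, 100, 20, 2.0, noise_sd=0.2, seed=SEED)
        q2 = loocv_q2(log2_autoscale(mm), mm.groups, 2)
        assert q2 >= 0.8


class TestVip:
    def test_single_component_closed_form(self):
        # A=1, p=2, w=(1,0): VIP = (sqrt(2), 0)
        X = np.array([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0], [-2.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        model = plsda_fit(X + np.array([0, 1e-12]), y, n_components=1)
        vip = vip_scores(model)
        assert vip.iloc[0] == pytest.approx(np.sqrt(2), abs=1e-6)
        assert vip.iloc[1] == pytest.approx(0.0, abs=1e-6)

    def test_sum_of_squares_identity(self, rng):
        for p in (5, 20, 60):
            X = rng.normal(size=(12, p))
            y = np.array([-1.0] * 6 + [1.0] * 6)
            vip = vip_scores(plsda_fit(X, y, n_components=2))
            assert vip.pow(2).sum() == pytest.approx(p, rel=1e-8)


class TestVolcano:
    def test_identical_groups_nothing_significant(self):
        base = np.array([[10.0, 20.0, 5.0], [11.0, 19.0, 6.0]])
        mm = matrix_from(np.vstack([base, base]), ["a", "a", "b", "b"])
        res = volcano(mm)
        assert res.significant == []

    def test_single_metabolite_q_equals_p(self):
        vals = [[10.0], [11.0], [30.0], [29.0]]
        res = volcano(matrix_from(vals, ["a", "a", "b", "b"]))
        assert res.table["q_value"].iloc[0] == pytest.approx(
            res.table["p_value"].iloc[0])

    def test_fc_gate_is_inclusive_at_1p2(self):
        res = volcano(matrix_from([[10.0], [10.0], [12.0], [12.0]],
                                  ["a", "a", "b", "b"]))
        assert res.table["fold_change"].iloc[0] == pytest.approx(1.2)
        assert res.table["fc_magnitude"].iloc[0] >= res.fc_threshold

    def test_control_label_sets_direction(self):
        mm = matrix_from([[10.0], [10.0], [20.0], [20.0]], ["a", "a", "b", "b"])
        up = volcano(mm, control_label="a").table["fold_change"].iloc[0]
        down = volcano(mm, control_label="b").table["fold_change"].iloc[0]
        assert up == pytest.approx(2.0) and down == pytest.approx(0.5)

    def test_type_one_error_controlled_under_null(self):
        # with no planted effect, expected significant count under BH stays
        # below alpha * m across 50 seeds
        m = 483
        counts = []
        for s in range(50):
            mm, _ = make_metabolite_matrix(5, m, 0, 0.0, seed=s)
            counts.append(len(volcano(mm).significant))
        assert np.mean(counts) <= 0.05 * m

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_bh_adjustment_matches_step_up_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests
        q = multipletests(pvals, method="fdr_bh")[1]
        # brute-force BH step-up
        m = len(pvals)
        order = np.argsort(pvals)
        expected = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, pvals[i] * m / rank)
            expected[i] = prev
        assert np.allclose(q, expected, atol=1e-12)


class TestPathwayImpact:
    def test_all_none_and_half_significant(self):
        vip = pd.Series({"a": 2.0, "b": 1.0, "c": 1.0})
        pw = {"p": ["a", "b", "c"]}
        assert pathway_impact(pw, vip, {"a", "b", "c"}).table["impact"]["p"] == 1.0
        assert pathway_impact(pw, vip, set()).table["impact"]["p"] == 0.0
        assert pathway_impact(pw, vip, {"a"}).table["impact"]["p"] == \
            pytest.approx(0.5)

    def test_total_sums_over_pathways(self):
        vip = pd.Series({"a": 1.0, "b": 1.0, "c": 2.0, "d": 2.0})
        res = pathway_impact({"p1": ["a", "b"], "p2": ["c", "d"]}, vip, {"a", "c"})
        assert res.total == pytest.approx(0.5 + 0.5)

    def test_invariant_to_outside_metabolites(self):
        vip = pd.Series({"a": 2.0, "b": 1.0, "z": 50.0})
        r1 = pathway_impact({"p": ["a", "b"]}, vip, {"a", "z"})
        r2 = pathway_impact({"p": ["a", "b"]}, vip.drop("z"), {"a"})
        assert r1.table["impact"]["p"] == r2.table["impact"]["p"]

    def test_missing_member_rejected(self):
        with pytest.raises(KeyError):
            pathway_impact({"p": ["ghost"]}, pd.Series({"a": 1.0}), set())

    def test_vip_significance_source(self):
        mm, affected = make_metabolite_matrix(10, 40, 8, 2.0, noise_sd=0.2,
                                              seed=SEED)
        vip = vip_scores(plsda_fit(log2_autoscale(mm), mm.groups, 2))
        sig = significant_by_vip(vip, 1.5)
        assert set(sig) == set(affected)

    def test_zero_vip_pathway_rejected(self):
        with pytest.raises(ValueError, match="zero total VIP"):
            pathway_impact({"p": ["a"]}, pd.Series({"a": 0.0}), set())


class TestQ2Recovery:
    def test_planted_separation_vs_null_over_seeds(self):
        # mean LOOCV Q2 over 20 seeded matrices: high with a planted effect,
        # near zero (or negative) without one
        planted, null = [], []
        for s in range(20):
            mm, _ = make_metabolite_matrix(10, 100, 20, 2.0, noise_sd=0.2, seed=s)
            planted.append(loocv_q2(log2_autoscale(mm), mm.groups, 2))
            m0, _ = make_metabolite_matrix(10, 100, 0, 0.0, seed=1000 + s)
            null.append(loocv_q2(log2_autoscale(m0), m0.groups, 2))
        assert np.mean(planted) >= 0.8
        assert np.mean(null) <= 0.2
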