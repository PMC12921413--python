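import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chronometab.dataio import AnalysisConfig
from chronometab.screening import (GroupSummary, fold_change_screen,
                                   mannwhitney_with_r, normality_route,
                                   pca_scores, permutation_validate, plsda_fit,
                                   qc_correlation, rank_biserial_from_u,
                                   rank_biserial_simple,
                                   relative_expression_ddct, routed_test,
                                   shared_by_exactly, timepoint_screen,
                                   timepoint_union, ttest_with_d, venn_counts,
                                   vip_scores)


class TestNormalityRoute:
    def test_gaussian_goes_parametric(self):
        rng = np.random.default_rng(0)
        route, _ = normality_route(rng.normal(size=50), rng.normal(size=50))
        assert route == "parametric"

    def test_lognormal_goes_nonparametric(self):
        rng = np.random.default_rng(0)
        route, _ = normality_route(rng.lognormal(0, 1.5, 50),
                                   rng.lognormal(0, 1.5, 50))
        assert route == "nonparametric"

    def test_tiny_sample_warns_nonparametric(self):
        route, flag = normality_route([1.0, 2.0], [3.0, 4.0, 5.0])
        assert route == "nonparametric"
        assert "n<3" in flag


class TestTtestWithD:
    # printed-summary worked examples: behavioral recognition index and
    # CA3 Nissl body counts
    def test_recognition_index_summary(self):
        res = ttest_with_d((0.596, 0.104, 10), (0.475, 0.074, 10))
        assert res.df == 18
        assert res.statistic == pytest.approx(2.994, abs=0.01)
        assert res.effect == pytest.approx(1.34, abs=0.01)
        assert res.p == pytest.approx(0.008, abs=0.002)

    def test_nissl_counts_summary(self):
        res = ttest_with_d((201.67, 4.51, 3), (173.00, 2.00, 3))
        assert res.df == 4
        assert res.statistic == pytest.approx(10.066, abs=0.01)
        assert res.effect == pytest.approx(8.22, abs=0.01)

    def test_identical_groups(self):
        res = ttest_with_d((5.0, 1.0, 10), (5.0, 1.0, 10))
        assert res.statistic == 0 and res.effect == 0

    def test_raw_and_summary_paths_agree(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        raw = ttest_with_d(x, y)
        summ = ttest_with_d(GroupSummary(x.mean(), x.std(ddof=1), x.size),
                            GroupSummary(y.mean(), y.std(ddof=1), y.size))
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.effect == pytest.approx(summ.effect, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)

    def test_zero_pooled_sd_flagged(self):
        res = ttest_with_d((1.0, 0.0, 5), (2.0, 0.0, 5))
        assert "zero pooled SD" in res.flag
        assert np.isnan(res.statistic)


class TestMannWhitney:
    def test_printed_rank_biserial_convention(self):
        # published latency comparison: U = 17.5 at n = 10 vs 10
        z, p, r = rank_biserial_from_u(17.5, 10, 10)
        assert round(r, 2) == -0.55
        assert p == pytest.approx(0.014, abs=0.001)

    def test_complete_separation(self):
        res = mannwhitney_with_r(np.arange(10, 20.0), np.arange(10.0))
        assert res.statistic == 100  # U1 = n1*n2
        assert res.effect > 0.8

    def test_all_tied(self):
        res = mannwhitney_with_r(np.ones(5), np.ones(6))
        assert res.p == 1.0 and res.effect == 0.0
        assert res.statistic == 15.0  # n1*n2/2

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        rej = sum(mannwhitney_with_r(rng.normal(size=12), rng.normal(size=12)).p < 0.05
                  for _ in range(2000))
        assert 0.03 <= rej / 2000 <= 0.07

    def test_alternative_rank_biserial_form(self):
        assert rank_biserial_simple(0, 5, 5) == 1.0
        assert rank_biserial_simple(25, 5, 10) == 0.0


def test_relative_expression_ddct():
    assert relative_expression_ddct(25.0, 20.0, 5.0) == 1.0     # matches calibrator
    assert relative_expression_ddct(24.0, 20.0, 5.0) == 2.0     # one cycle earlier
    assert relative_expression_ddct(23.321928, 20.0, 0.0) == pytest.approx(0.1, abs=1e-6)


class TestFoldChangeScreen:
    def test_threshold_arithmetic(self, study_dataset, default_config):
        table, gt = study_dataset
        res = fold_change_screen(table, default_config)
        # recomputable flags
        recomputed = (np.maximum(res["fc"], 1 / res["fc"]) > 1.2) & (res["p_uni"] < 0.05)
        assert (res["passes_global"] == recomputed.fillna(False)).all()

    def test_recovers_planted_global_effects(self, study_dataset, default_config):
        table, gt = study_dataset
        res = fold_change_screen(table, default_config)
        assert res.loc[gt.fc_effect_ids, "passes_global"].sum() >= 35

    def test_label_swap_inverts_fc_but_not_flags(self, small_dataset, default_config):
        table, _ = small_dataset
        res = fold_change_screen(table, default_config)
        swapped_meta = table.meta.copy()
        swapped_meta["group"] = swapped_meta["group"].map({"LD": "LL", "LL": "LD"})
        from chronometab.dataio import MetaboliteTable
        swapped = MetaboliteTable(table.abundance, swapped_meta)
        res2 = fold_change_screen(swapped, default_config)
        np.testing.assert_allclose(res2["fc"], 1 / res["fc"], rtol=1e-12)
        assert (res["passes_global"] == res2["passes_global"]).all()


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(3)
        direction = rng.normal(size=5)
        X = np.outer(rng.normal(size=10), direction)
        _, evr = pca_scores(X, n_components=3, scale=False)
        assert evr[0] == pytest.approx(1.0)

    def test_rotation_invariance_of_spectrum(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        _, evr1 = pca_scores(X, 5, scale=False)
        _, evr2 = pca_scores(X @ Q, 5, scale=False)
        np.testing.assert_allclose(evr1, evr2, atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 5))
        Xc = X - X.mean(0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        np.testing.assert_allclose(U @ np.diag(s) @ Vt, Xc, atol=1e-8)
        scores, evr = pca_scores(X, 5, scale=False)
        assert evr.sum() == pytest.approx(1.0)
        assert np.all(np.diff(evr) <= 1e-12)


class TestPlsDa:
    def test_single_driver_variable(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 8)) * 0.05
        X[:10, 2] += 5
        labels = ["A"] * 10 + ["B"] * 10
        model = plsda_fit(X, labels, n_components=2, scale=False)
        assert model.r2y > 0.99
        vip = vip_scores(model)
        assert vip.argmax() == 2
        # first-component weight concentrated on the driver variable
        assert abs(model.weights[2, 0]) > 0.99

    def test_vip_normalization_identity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(16, 12))
        labels = ["A"] * 8 + ["B"] * 8
        model = plsda_fit(X, labels, n_components=3)
        vip = vip_scores(model)
        assert (vip ** 2).sum() == pytest.approx(12.0, rel=1e-9)

    def test_one_component_matches_nipals_oracle(self):
        # first PLS weight = dominant direction of X'y; scores = X w
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        labels = ["A"] * 5 + ["B"] * 5
        model = plsda_fit(X, labels, n_components=1, scale=False)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        sign = np.sign(w @ model.weights[:, 0])
        np.testing.assert_allclose(model.weights[:, 0], sign * w, atol=1e-6)
        np.testing.assert_allclose(model.x_scores[:, 0], sign * t, atol=1e-6)

    def test_vip_against_hand_computation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(14, 5))
        labels = ["A"] * 7 + ["B"] * 7
        model = plsda_fit(X, labels, n_components=2)
        W = model.weights / np.linalg.norm(model.weights, axis=0)
        ssy = model.ssy
        hand = np.sqrt(5 * (W ** 2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip_scores(model), hand, atol=1e-10)

    def test_label_permutation_degrades_q2(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 10))
        X[:10] += 2
        labels = np.array(["A"] * 10 + ["B"] * 10)
        model = plsda_fit(X, labels, n_components=2)
        q2_perm = [plsda_fit(X, rng.permutation(labels), n_components=2).q2
                   for _ in range(10)]
        assert model.q2 > 0.5
        assert np.mean(q2_perm) < 0.1  # permuted labels are unpredictable


class TestPermutationValidation:
    def test_separated_classes_significant(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(16, 20))
        X[:8] += 3
        labels = ["A"] * 8 + ["B"] * 8
        p, obs, perms = permutation_validate(X, labels, n_perm=199, seed=0)
        assert p <= 0.01
        assert obs > perms.max()

    def test_worst_case_p_is_one(self):
        # constant response to labels: observed never exceeds permuted
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 5))
        labels = ["A"] * 6 + ["B"] * 6
        p, obs, perms = permutation_validate(X, labels, n_perm=199, seed=1)
        assert 0 < p <= 1
        # null data: p should not be extreme
        assert p > 0.01

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_validate(np.zeros((4, 2)), ["A", "A", "B", "B"], n_perm=10)


class TestTimepointScreen:
    def test_flags_recomputable(self, study_dataset, default_config):
        table, _ = study_dataset
        res = timepoint_screen(table, 12.0, default_config)
        recomputed = (res["vip"] > 1.5) & (res["p_uni"] < 0.05)
        assert (res["passes_timepoint"] == recomputed).all()

    def test_planted_effects_enriched_in_hits(self, study_dataset, default_config):
        table, gt = study_dataset
        screens = {zt: timepoint_screen(table, zt, default_config)
                   for zt in (0.0, 6.0, 12.0, 18.0)}
        union = timepoint_union(screens)
        hit_rate_planted = np.mean([m in union for m in gt.fc_effect_ids])
        flat = [m for m in gt.table.index
                if gt.table.loc[m, "role"] == "arrhythmic"]
        hit_rate_flat = np.mean([m in union for m in flat])
        assert hit_rate_planted > 0.8
        assert hit_rate_flat < 0.3

    def test_missing_timepoint_skipped(self, study_dataset, default_config):
        table, _ = study_dataset
        with pytest.warns(UserWarning, match="absent"):
            assert timepoint_screen(table, 3.0, default_config) is None


class TestVenn:
    def test_identical_sets(self):
        sets = [set("abc")] * 4
        counts = venn_counts(sets)
        assert counts[(1, 1, 1, 1)] == 3
        assert shared_by_exactly(counts, 1) == 0

    def test_disjoint_sets(self):
        counts = venn_counts([{1}, {2}, {3}, {4}])
        assert shared_by_exactly(counts, 1) == 4
        assert shared_by_exactly(counts, 4) == 0

    @given(st.integers(0, 200))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = list(range(30))
        sets = [set(rng.choice(universe, size=rng.integers(0, 15), replace=False))
                for _ in range(4)]
        if not any(sets):
            return
        counts = venn_counts(sets)
        for key, c in counts.items():
            members = [x for x in universe
                       if all((x in sets[i]) == bool(key[i]) for i in range(4))]
            assert len(members) == c


class TestQcCorrelation:
    def test_duplicate_sample_r_one(self):
        x = np.random.default_rng(13).normal(size=50)
        corr, min_r = qc_correlation(pd.DataFrame({"q1": x, "q2": x}))
        assert min_r == pytest.approx(1.0)

    def test_negated_sample(self):
        x = np.random.default_rng(14).normal(size=50)
        _, min_r = qc_correlation(pd.DataFrame({"q1": x, "q2": -x}))
        assert min_r == pytest.approx(-1.0)

    def test_low_noise_replicates_highly_correlated(self):
        rng = np.random.default_rng(15)
        base = rng.lognormal(3, 1, size=398)
        qc = pd.DataFrame({f"q{i}": base * (1 + rng.normal(0, 0.01, 398))
                           for i in range(5)})
        _, min_r = qc_correlation(qc)
        assert min_r > 0.99

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            qc_correlation(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))


def test_routed_test_uses_nonparametric_for_skewed_data():
    rng = np.random.default_rng(16)
    res = routed_test(rng.lognormal(0, 2, 30), rng.lognormal(0, 2, 30))
    assert res.route == "nonparametric"
    assert res.statistic_name == "U"
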