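"""Ranking, cross-validation schemes, pruning, MFO sweep and Welch tests."""

import json

import numpy as np
import pandas as pd
import pytest

from turngait.features import FeatureMatrix
from turngait.modeling import METRIC_NAMES, ClassifierSpec, SelectorSpec
from turngait.protocol import (
    CVSummary,
    ProtocolConfig,
    RankTable,
    ci_halfwidth,
    combine_matrices,
    competition_ranks,
    default_combos,
    derive_seed,
    five_fold_cv,
    mfo_features,
    mfo_subsets,
    prune_after_test1,
    rank_combinations,
    rss_cv,
    run_protocol,
    welch_t,
)


class TestRanking:
    def test_printed_tie_example(self):
        assert competition_ranks([9, 8, 7, 7, 7, 6, 5]).tolist() == \
            [1, 2, 3, 3, 3, 6, 7]

    def test_strictly_decreasing_scores(self):
        assert competition_ranks([5, 4, 3, 2, 1]).tolist() == [1, 2, 3, 4, 5]

    def test_all_equal_scores_all_rank_one(self):
        assert competition_ranks([2, 2, 2]).tolist() == [1, 1, 1]

    def test_rank_sums_invariant_under_combo_shuffle(self):
        rng = np.random.default_rng(0)
        combos = [f"m{i}|S5B" for i in range(6)]
        per_iter = {c: {m: rng.uniform(size=4) for m in METRIC_NAMES}
                    for c in combos}
        s1 = CVSummary(4, per_iter, {c: {} for c in combos})
        shuffled = {c: per_iter[c] for c in reversed(combos)}
        s2 = CVSummary(4, shuffled, {c: {} for c in combos})
        r1 = rank_combinations(s1).rank_sum.sort_index()
        r2 = rank_combinations(s2).rank_sum.sort_index()
        pd.testing.assert_series_equal(r1, r2)


class TestSeedsAndCI:
    def test_derive_seed_is_deterministic_and_bounded(self):
        assert derive_seed(7, 1, 2) == derive_seed(7, 1, 2)
        assert derive_seed(7, 1, 2) != derive_seed(7, 1, 3)
        assert 0 <= derive_seed(2**40, 999) < 2**31

    def test_ci_halfwidth_formula(self):
        assert ci_halfwidth(10.6, 2500) == pytest.approx(1.96 * 10.6 / 50.0)


def _cheap_combos():
    return default_combos(models=("kNN3",), methods=("S5B",))


class TestRssCv:
    def test_ci_matches_formula_for_every_metric(self, weak_matrix):
        s = rss_cv(weak_matrix, _cheap_combos(), n_iter=20, seed=1)
        for m in METRIC_NAMES:
            vals = s.per_iteration["kNN3|S5B"][m]
            assert s.ci("kNN3|S5B", m) == pytest.approx(
                1.96 * np.std(vals, ddof=1) / np.sqrt(20))

    def test_single_iteration_has_zero_sd_and_ci(self, weak_matrix):
        s = rss_cv(weak_matrix, _cheap_combos(), n_iter=1, seed=1)
        assert s.sd("kNN3|S5B", "ACC") == 0.0
        assert s.ci("kNN3|S5B", "ACC") == 0.0

    def test_selection_count_conservation(self, weak_matrix):
        n_iter, k = 15, 5
        s = rss_cv(weak_matrix, _cheap_combos(), n_iter=n_iter, seed=2)
        assert sum(s.selection_counts["kNN3|S5B"].values()) == k * n_iter

    def test_seeded_determinism(self, weak_matrix):
        a = rss_cv(weak_matrix, _cheap_combos(), n_iter=10, seed=3)
        b = rss_cv(weak_matrix, _cheap_combos(), n_iter=10, seed=3)
        for m in METRIC_NAMES:
            assert np.array_equal(a.per_iteration["kNN3|S5B"][m],
                                  b.per_iteration["kNN3|S5B"][m])

    def test_null_cohort_fixed_features_mcc_centred_on_zero(self, null_matrix):
        # with a pinned feature set there is no selection winner's curse, so
        # label-independent features must give MCC centred on zero
        s = rss_cv(null_matrix, _cheap_combos(), n_iter=100, seed=4,
                   fixed_features=["f000", "f001", "f002", "f003", "f004"])
        mcc = s.per_iteration["kNN3|S5B"]["MCC"]
        assert abs(np.mean(mcc)) <= 3 * np.std(mcc, ddof=1) / np.sqrt(100)

    def test_fixed_features_bypass_selection(self, weak_matrix):
        s = rss_cv(weak_matrix, _cheap_combos(), n_iter=5, seed=5,
                   fixed_features=["f000", "f001"])
        assert set(s.selection_counts["kNN3|S5B"]) == {"f000", "f001"}


class TestFiveFold:
    def test_separable_cohort_is_perfect_for_rf_s5b(self, separable_matrix):
        combos = default_combos(models=("RF",), methods=("S5B",))
        s = five_fold_cv(separable_matrix, combos, seed=0)
        assert s.n_iterations == 5
        assert s.mean("RF|S5B", "ACC") == 1.0

    def test_small_class_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(8, 4)),
                         index=[f"P{i}" for i in range(8)])
        X.columns = [f"f{i}" for i in range(4)]
        labels = pd.Series(["NF"] * 4 + ["PF"] * 4, index=X.index)
        fm = FeatureMatrix(X=X, labels=labels)
        with pytest.raises(ValueError, match="5 samples"):
            five_fold_cv(fm, _cheap_combos(), seed=0)


def _rank_table(order, sums=None):
    sums = sums or list(range(10, 10 + len(order)))
    rs = pd.Series(sums, index=order).sort_values(kind="stable")
    ranks = pd.DataFrame(0, index=order, columns=list(METRIC_NAMES))
    return RankTable(ranks=ranks, rank_sum=rs)


class TestPrune:
    def test_planted_weakest_model_and_selector_removed(self):
        combos = [f"{m}|{s}" for m in ("kNN3", "kNN5", "SVM_linear",
                                       "SVM_poly3", "SVM_poly5", "RF")
                  for s in ("S5B", "SEL", "RFE")]
        # order both tables so SVM_poly5 and RFE sink below the top nine
        good = [c for c in combos
                if not (c.startswith("SVM_poly5") or c.endswith("RFE"))]
        bad = [c for c in combos if c not in good]
        table = _rank_table(good + bad)
        kept_cls, kept_sel = prune_after_test1(table, table)
        assert "SVM_poly5" not in kept_cls and len(kept_cls) == 5
        assert kept_sel == ["S5B", "SEL"]

    def test_outputs_ten_remaining_combinations(self):
        combos = [f"{m}|{s}" for m in ("kNN3", "kNN5", "SVM_linear",
                                       "SVM_poly3", "SVM_poly5", "RF")
                  for s in ("S5B", "SEL", "RFE")]
        table = _rank_table(combos)
        kept_cls, kept_sel = prune_after_test1(table, table)
        assert len(kept_cls) * len(kept_sel) == 10


class TestMfo:
    def _summary(self, counts):
        per_iter = {"RF|S5B": {m: np.zeros(4) for m in METRIC_NAMES}}
        return CVSummary(4, per_iter, {"RF|S5B": counts})

    def test_threshold_and_alphabetical_tie_break(self):
        s = self._summary({"b": 300, "a": 300, "c": 500, "d": 100})
        assert mfo_features(s, "RF|S5B", threshold=250) == ["c", "a", "b"]

    def test_max_features_cap_keeps_most_frequent(self):
        s = self._summary({"b": 300, "a": 300, "c": 500, "d": 260})
        assert mfo_features(s, "RF|S5B", threshold=250, max_features=2) == \
            ["c", "a"]

    def test_subsets_are_nested_down_to_one(self):
        subsets = mfo_subsets(["c", "a", "b"])
        assert [len(x) for x in subsets] == [3, 2, 1]
        for big, small in zip(subsets, subsets[1:]):
            assert set(small) < set(big)
        assert subsets[-1] == ["c"]

    def test_empty_mfo_list_rejected(self):
        with pytest.raises(ValueError):
            mfo_subsets([])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_equal_variance_case(self):
        # equal variances 5/3, se^2 = 2*(5/3)/4 -> t = -1/sqrt(5/6), df = 6
        t, df, p = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954451, rel=1e-6)
        assert df == pytest.approx(6.0)
        from scipy import stats as sps
        ref = sps.ttest_ind([1, 2, 3, 4], [2, 3, 4, 5], equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_separated_means_are_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=30)
        t, df, p = welch_t(a, a + 1.0)
        assert p < 1e-3

    def test_double_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestCombineMatrices:
    def test_prefixes_and_width(self, weak_matrix, null_matrix):
        fm = weak_matrix
        combined = combine_matrices(fm, fm)
        assert combined.X.shape[1] == 2 * fm.X.shape[1]
        assert all(c.startswith(("straight|", "turn|"))
                   for c in combined.X.columns)

    def test_mismatched_participants_rejected(self, weak_matrix, null_matrix):
        with pytest.raises(ValueError):
            combine_matrices(weak_matrix, null_matrix)


class TestRunProtocol:
    @pytest.fixture(scope="class")
    def report(self, weak_matrix, separable_matrix):
        cfg = ProtocolConfig(n_iter=6, seed=0, mfo_frac=0.34)
        return run_protocol(weak_matrix, separable_matrix, cfg)

    def test_report_shapes_follow_the_four_tests(self, report):
        assert len(report.test1["straight"].combos) == 18
        assert len(report.test2["turn"].combos) == 10
        assert len(report.test4.combos) == 8
        assert len(report.kept_classifiers) == 5
        assert len(report.kept_selectors) == 2

    def test_welch_covers_all_non_degenerate_metrics(self, report):
        # metrics constant in both best combos are skipped with a warning;
        # everything else gets a Welch comparison
        assert set(report.welch) <= set(METRIC_NAMES)
        for m in METRIC_NAMES:
            a = report.test2["turn"].per_iteration[report.ranks2["turn"].best][m]
            b = report.test2["straight"].per_iteration[
                report.ranks2["straight"].best][m]
            if np.var(a) > 0 or np.var(b) > 0:
                assert m in report.welch

    def test_mfo_sweeps_are_nested(self, report):
        for cond, sweeps in report.test3.items():
            sizes = sorted(sweeps)
            assert sizes == list(range(1, len(sizes) + 1))

    def test_report_serializes_to_json(self, report):
        payload = json.dumps(report.to_dict())
        assert "kept_classifiers" in payload

    def test_turn_signal_beats_null_straight(self, report):
        best_turn = report.ranks2["turn"].best
        best_straight = report.ranks2["straight"].best
        acc_turn = report.test2["turn"].mean(best_turn, "ACC")
        acc_straight = report.test2["straight"].mean(best_straight, "ACC")
        assert acc_turn > acc_straight
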