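import numpy as np
import pandas as pd
import pytest

from mddmarker.metrics import ClassificationMetrics
from mddmarker.selection import (
    ClassifierConfig,
    SelectionCriterion,
    enumerate_combinations,
    loo_select,
    resubstitution_metrics,
    select_per_fold,
)


def metrics(sens, spec, acc=None, f1=None):
    return ClassificationMetrics(
        accuracy=acc if acc is not None else (sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        precision=sens,
        f1=f1 if f1 is not None else sens,
    )


class TestEnumerate:
    def test_eight_choose_two_is_twenty_eight(self):
        combos = enumerate_combinations([f"m{i}" for i in range(8)], 2)
        assert len(combos) == 28
        assert combos == sorted(combos)

    def test_eight_choose_three_is_fifty_six(self):
        assert len(enumerate_combinations([f"m{i}" for i in range(8)], 3)) == 56

    def test_three_choose_three_single(self):
        assert enumerate_combinations(["c", "a", "b"], 3) == [("a", "b", "c")]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_combinations(["a", "b"], 3)


class TestResubstitution:
    def test_perfectly_separated_pair_scores_one(self):
        idx = [f"s{i}" for i in range(12)]
        values = pd.DataFrame(
            {
                "mA": [1, 2, 3, 1.5, 2.5, 3.5, 10, 11, 12, 10.5, 11.5, 12.5],
                "mB": [5, 6, 4, 5.5, 6.5, 4.5, 20, 21, 22, 20.5, 21.5, 22.5],
            },
            index=idx,
        )
        labels = pd.Series(["RES"] * 6 + ["NRES"] * 6, index=idx)
        m = resubstitution_metrics(values, labels, ("mA", "mB"), ClassifierConfig(epsilon=0.0))
        assert m.accuracy == 1.0

    def test_uninformative_markers_near_chance(self):
        accs = []
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            idx = [f"s{i}" for i in range(20)]
            values = pd.DataFrame(rng.normal(size=(20, 2)), index=idx, columns=["mA", "mB"])
            labels = pd.Series(rng.permutation(["RES"] * 10 + ["NRES"] * 10), index=idx)
            accs.append(resubstitution_metrics(values, labels, ("mA", "mB")).accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_hand_constructed_six_samples(self):
        # one marker, two divisions: RES at {1, 2, 8}, NRES at {3, 9, 10};
        # median cut 5.5 -> divisions RES (1,1,2), NRES (1,2,2); counts
        # div1: RES 2, NRES 1; div2: RES 1, NRES 2 -> each sample classified
        # by its division's majority: confusion (tp 2, fn 1, fp 1, tn 2)
        idx = list("abcdef")
        values = pd.DataFrame({"m": [1.0, 2.0, 8.0, 3.0, 9.0, 10.0]}, index=idx)
        labels = pd.Series(["RES"] * 3 + ["NRES"] * 3, index=idx)
        m = resubstitution_metrics(
            values, labels, ("m",), ClassifierConfig(epsilon=0.0, conditional="per_marker")
        )
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(2 / 3)


class TestSelectPerFold:
    def test_sensitivity_with_floor_rule(self):
        cands = [
            (("A", "x"), metrics(0.9, 0.4)),
            (("B", "x"), metrics(0.8, 0.6)),
            (("C", "x"), metrics(0.7, 0.9)),
        ]
        combo, _, fallback = select_per_fold(cands, SelectionCriterion())
        assert combo == ("B", "x") and not fallback

    def test_floor_fallback_to_max_specificity(self):
        cands = [(("A",), metrics(0.9, 0.2)), (("B",), metrics(0.5, 0.4))]
        combo, _, fallback = select_per_fold(
            cands, SelectionCriterion(specificity_floor=0.5)
        )
        assert combo == ("B",) and fallback

    def test_f1_tie_breaks_by_accuracy_then_name(self):
        cands = [
            (("A",), metrics(0.7, 0.7, acc=0.70, f1=0.70)),
            (("B",), metrics(0.8, 0.8, acc=0.80, f1=0.85)),
            (("C",), metrics(0.8, 0.9, acc=0.85, f1=0.85)),
        ]
        combo, _, _ = select_per_fold(cands, SelectionCriterion(mode="f1"))
        assert combo == ("C",)
        # equal accuracy too -> lexicographically smaller wins
        cands = [
            (("B",), metrics(0.8, 0.8, acc=0.85, f1=0.85)),
            (("A",), metrics(0.8, 0.9, acc=0.85, f1=0.85)),
        ]
        combo, _, _ = select_per_fold(cands, SelectionCriterion(mode="f1"))
        assert combo == ("A",)

    def test_single_candidate_returned(self):
        combo, _, _ = select_per_fold([(("Z",), metrics(0.1, 0.1))], SelectionCriterion())
        assert combo == ("Z",)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="no candidate"):
            select_per_fold([], SelectionCriterion())


class TestLooSelect:
    @staticmethod
    def separable_data(n_extra_markers=2, n_per_class=8, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(2 * n_per_class)]
        labels = pd.Series(["RES"] * n_per_class + ["NRES"] * n_per_class, index=idx)
        cols = {
            "inf1": np.r_[rng.normal(0, 0.1, n_per_class), rng.normal(5, 0.1, n_per_class)],
            "inf2": np.r_[rng.normal(0, 0.1, n_per_class), rng.normal(5, 0.1, n_per_class)],
        }
        for j in range(n_extra_markers):
            cols[f"x{j}"] = rng.normal(size=2 * n_per_class)
        return pd.DataFrame(cols, index=idx), labels

    def test_unanimous_folds_select_that_pair(self):
        values, labels = self.separable_data()
        res = loo_select(values, labels, k=2, criterion=SelectionCriterion(mode="f1"))
        assert sum(res.frequencies.values()) == len(values)
        if len(res.frequencies) == 1:
            (combo,) = res.frequencies
            assert res.winner == combo

    def test_vote_tallies_and_evaluation_count(self):
        values, labels = self.separable_data(n_extra_markers=3)
        res = loo_select(values, labels, k=2)
        n, m = len(values), values.shape[1]
        assert sum(res.frequencies.values()) == n
        assert res.evaluations == n * (m * (m - 1) // 2)
        assert len(res.folds) == n
        assert res.winner in res.frequencies

    def test_permutation_invariance(self):
        values, labels = self.separable_data(seed=3)
        res1 = loo_select(values, labels, k=2)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(values))
        res2 = loo_select(values.iloc[perm], labels.iloc[perm], k=2)
        assert res1.winner == res2.winner
        assert res1.frequencies == res2.frequencies

    def test_k3_runs_the_same_loop(self):
        values, labels = self.separable_data(n_extra_markers=2)
        res = loo_select(values, labels, k=3, criterion=SelectionCriterion(mode="f1"))
        assert all(len(f.combination) == 3 for f in res.folds)
        assert res.evaluations == len(values) * 4  # C(4,3) = 4

    def test_needs_three_per_class(self):
        idx = list("abcdef")
        values = pd.DataFrame({"m1": range(6), "m2": range(6)}, index=idx, dtype=float)
        labels = pd.Series(["RES"] * 2 + ["NRES"] * 4, index=idx)
        with pytest.raises(ValueError, match="at least 3"):
            loo_select(values, labels, k=2)

    def test_fast_path_agrees_with_public_resubstitution(self, marker_table):
        # every fold's recorded metrics must equal an independent
        # resubstitution run on the same 15-sample subsets
        values, labels = marker_table
        res = loo_select(values, labels, k=2, config=ClassifierConfig(divisions=2))
        for fold in res.folds:
            sub = values.drop(index=fold.left_out)
            sub_labels = labels.drop(index=fold.left_out)
            m = resubstitution_metrics(sub, sub_labels, fold.combination)
            assert m.sensitivity == pytest.approx(fold.metrics.sensitivity)
            assert m.specificity == pytest.approx(fold.metrics.specificity)
            assert m.f1 == pytest.approx(fold.metrics.f1)
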