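import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mddmarker import bayes
from mddmarker.bayes import (
    DiscreteBayesModel,
    DiscretizationScheme,
    classify,
    classify_frame,
    discretize,
    discretize_frame,
    fit_discretization,
    fit_model,
    posterior,
)


def model_from_counts(counts_res, counts_nres, epsilon=0.0, conditional="cross_marker"):
    """Build a model directly from per-marker, per-division count lists."""
    n_markers = len(counts_res)
    max_d = max(len(c) for c in counts_res)
    cuts = {f"m{j}": np.arange(1, len(counts_res[j]), dtype=float) for j in range(n_markers)}
    counts = np.zeros((2, n_markers, max_d), dtype=int)
    for j in range(n_markers):
        counts[0, j, : len(counts_res[j])] = counts_res[j]
        counts[1, j, : len(counts_nres[j])] = counts_nres[j]
    return DiscreteBayesModel(
        scheme=DiscretizationScheme(cuts),
        counts=counts,
        epsilon=epsilon,
        conditional=conditional,
    )


class TestFitDiscretization:
    def test_median_cut_of_four_values(self):
        scheme = fit_discretization(pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), 2)
        assert scheme.cuts["x"] == pytest.approx([2.5])
        assert [discretize(scheme, {"x": v})["x"] for v in (1, 2, 3, 4)] == [1, 1, 2, 2]

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_discretization(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), 2)

    def test_monotone_transform_preserves_training_assignments(self):
        rng = np.random.default_rng(0)
        v = pd.DataFrame({"x": rng.lognormal(0, 1, 40)})
        for d in (2, 3, 4):
            a = discretize_frame(fit_discretization(v, d), v)
            b = discretize_frame(fit_discretization(np.log(v), d), np.log(v))
            assert (a["x"] == b["x"]).all()

    def test_too_many_divisions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_discretization(pd.DataFrame({"x": [1.0, 2.0]}), 3)


class TestDiscretize:
    def test_boundary_and_end_divisions(self):
        scheme = DiscretizationScheme({"x": np.array([1.0, 2.0])})
        assert discretize(scheme, {"x": 0.5})["x"] == 1
        assert discretize(scheme, {"x": 1.0})["x"] == 1  # at cut -> lower division
        assert discretize(scheme, {"x": 2.0})["x"] == 2
        assert discretize(scheme, {"x": 99.0})["x"] == 3

    def test_missing_marker_value_rejected(self):
        scheme = DiscretizationScheme({"x": np.array([0.0])})
        with pytest.raises(ValueError, match="missing"):
            discretize(scheme, {})


class TestFitModel:
    def test_counts_tally(self):
        scheme = DiscretizationScheme({"A": np.array([0.0])})
        disc = pd.DataFrame({"A": [1, 1, 1]}, index=list("abc"))
        labels = pd.Series(["RES", "RES", "RES"], index=list("abc"))
        with pytest.raises(ValueError, match="both classes"):
            fit_model(disc, labels, scheme)
        disc = pd.DataFrame({"A": [1, 1, 1, 2]}, index=list("abcd"))
        labels = pd.Series(["RES", "RES", "RES", "NRES"], index=list("abcd"))
        model = fit_model(disc, labels, scheme)
        assert model.counts[0, 0].tolist() == [3, 0]
        assert model.counts[1, 0].tolist() == [0, 1]

    def test_count_sums_equal_class_sizes_and_order_invariance(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(30)]
        disc = pd.DataFrame(
            {"A": rng.integers(1, 3, 30), "B": rng.integers(1, 4, 30)}, index=idx
        )
        labels = pd.Series(rng.choice(["RES", "NRES"], 30, p=[0.5, 0.5]), index=idx)
        if labels.nunique() < 2:
            labels.iloc[0] = "RES" if labels.iloc[0] == "NRES" else "NRES"
        scheme = DiscretizationScheme({"A": np.array([0.0]), "B": np.array([0.0, 1.0])})
        model = fit_model(disc, labels, scheme)
        for i, cls in enumerate(("RES", "NRES")):
            n_cls = int((labels == cls).sum())
            for j in range(2):
                assert model.counts[i, j].sum() == n_cls
        perm = rng.permutation(30)
        shuffled = fit_model(disc.iloc[perm], labels.iloc[perm], scheme)
        assert np.array_equal(model.counts, shuffled.counts)


class TestPosterior:
    def test_hand_worked_two_marker_example(self):
        # class-1 counts (4, 4) and class-2 counts (1, 3) at the observed
        # divisions; cross-marker rule: (1/2)(1/2)=1/4 vs (1/4)(3/4)=3/16
        model = model_from_counts([[4, 0], [4, 0]], [[1, 0], [3, 0]], epsilon=0.0)
        p = posterior(model, {"m0": 1, "m1": 1})
        assert p.p_res == pytest.approx(4 / 7, abs=1e-12)
        label, tie = classify(model, {"m0": 1, "m1": 1})
        assert label == "RES" and not tie

    def test_unseen_in_one_class_gives_certainty(self):
        model = model_from_counts([[3, 1], [2, 2]], [[0, 4], [0, 4]], epsilon=0.0)
        p = posterior(model, {"m0": 1, "m1": 1})
        assert p.p_res == 1.0 and p.p_nres == 0.0

    def test_identical_counts_give_even_posterior_and_tie_flag(self):
        model = model_from_counts([[2, 2], [3, 1]], [[2, 2], [3, 1]], epsilon=0.0)
        p = posterior(model, {"m0": 1, "m1": 2})
        assert p.p_res == pytest.approx(0.5)
        label, tie = classify(model, {"m0": 1, "m1": 2})
        assert label == "RES" and tie

    def test_zero_likelihood_both_classes_instructs_smoothing(self):
        model = model_from_counts([[0, 4]], [[0, 4]], epsilon=0.0)
        with pytest.raises(ValueError, match="epsilon > 0"):
            posterior(model, {"m0": 1})

    def test_single_marker_behaviour_of_both_normalizations(self):
        # cross-marker rule at m=1: the denominator equals the numerator, so
        # every conditional is 1 and the posterior is degenerate at (1/2, 1/2)
        model = model_from_counts([[3, 5]], [[1, 7]], epsilon=0.0)
        p = posterior(model, {"m0": 1})
        assert p.p_res == pytest.approx(0.5)
        # per-marker rule with equal class sizes reduces to comparing the
        # training counts n(d)1 vs n(d)2 of the observed division
        for a, b in [(3, 1), (2, 5), (4, 4), (1, 0)]:
            model = model_from_counts(
                [[a, 8 - a]], [[b, 8 - b]], epsilon=0.0, conditional="per_marker"
            )
            p = posterior(model, {"m0": 1})
            assert p.p_res == pytest.approx(a / (a + b), abs=1e-12)

    @settings(deadline=None)
    @given(st.data())
    def test_posteriors_sum_to_one(self, data):
        m = data.draw(st.integers(1, 3))
        divs = [data.draw(st.integers(2, 3)) for _ in range(m)]
        cr = [[data.draw(st.integers(0, 5)) for _ in range(d)] for d in divs]
        cn = [[data.draw(st.integers(0, 5)) for _ in range(d)] for d in divs]
        model = model_from_counts(cr, cn, epsilon=0.5)
        sample = {f"m{j}": data.draw(st.integers(1, divs[j])) for j in range(m)}
        p = posterior(model, sample)
        assert p.p_res + p.p_nres == pytest.approx(1.0, abs=1e-12)

    def test_per_marker_conditional_normalizes_within_marker(self):
        # per-marker rule: P = (n+eps) / (sum_d n_j(d) + eps*D_j)
        model = model_from_counts([[3, 1]], [[1, 3]], epsilon=0.0, conditional="per_marker")
        p = posterior(model, {"m0": 1})
        assert p.p_res == pytest.approx((3 / 4) / (3 / 4 + 1 / 4))


class TestBatchAndSerialization:
    def test_classify_frame_matches_scalar_classify(self, marker_table):
        values, labels = marker_table
        scheme = fit_discretization(values, 2)
        disc = discretize_frame(scheme, values)
        model = fit_model(disc, labels, scheme, epsilon=0.5)
        batch = classify_frame(model, disc)
        for sid in values.index:
            label, tie = classify(model, disc.loc[sid].to_dict())
            assert batch.loc[sid, "label"] == label
            assert batch.loc[sid, "tie_flag"] == tie
            p = posterior(model, disc.loc[sid].to_dict())
            assert batch.loc[sid, "p_res"] == pytest.approx(p.p_res, abs=1e-12)

    def test_json_round_trip_preserves_posteriors(self, marker_table):
        values, labels = marker_table
        scheme = fit_discretization(values, 3)
        disc = discretize_frame(scheme, values)
        model = fit_model(disc, labels, scheme, epsilon=0.5)
        restored = DiscreteBayesModel.from_json(model.to_json())
        a = classify_frame(model, disc)
        b = classify_frame(restored, disc)
        pd.testing.assert_frame_equal(a, b)
        json.loads(model.to_json())  # valid JSON
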