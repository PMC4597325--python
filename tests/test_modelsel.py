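"""Perplexity, RPC, change-point and minimum-perplexity selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpcselect import (
    Corpus,
    PerplexityCurve,
    RPCSeries,
    RPCTopicSelector,
    compute_rpc,
    cross_validate_perplexity,
    held_out_perplexity,
    select_change_point,
    select_min_perplexity,
)
from rpcselect.modelsel import make_folds
from rpcselect.synthetic import generate_separable_corpus


class TestHeldOutPerplexity:
    def test_uniform_model_closed_form(self):
        V, N = 7, 13
        assert held_out_perplexity([-N * np.log(V)], [N]) == pytest.approx(V, abs=1e-9)

    def test_perfect_model_has_perplexity_one(self):
        assert held_out_perplexity([0.0, 0.0], [3, 4]) == pytest.approx(1.0, abs=1e-12)

    def test_direct_substitution(self):
        assert held_out_perplexity([-2.0, -3.0], [2, 3]) == pytest.approx(
            np.e, abs=1e-9)

    def test_empty_heldout_set_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            held_out_perplexity([0.0], [0])

    def test_empty_documents_contribute_nothing(self):
        with_empty = held_out_perplexity([-2.0, 0.0, -3.0], [2, 0, 3])
        without = held_out_perplexity([-2.0, -3.0], [2, 3])
        assert with_empty == pytest.approx(without, abs=1e-12)


class TestRPC:
    def test_constant_curve_gives_zero(self):
        curve = PerplexityCurve(candidates=[10, 20, 30],
                                fold_perplexities=[[100.0], [100.0], [100.0]])
        assert compute_rpc(curve).values.tolist() == [0.0, 0.0]

    def test_hand_computed_difference_quotients(self):
        curve = PerplexityCurve(candidates=[5, 10, 20],
                                fold_perplexities=[[1000.0], [800.0], [700.0]])
        rpc = compute_rpc(curve)
        assert rpc.topic_numbers.tolist() == [10, 20]
        assert rpc.values == pytest.approx([40.0, 10.0], abs=1e-9)

    def test_rise_taken_in_absolute_value(self):
        curve = PerplexityCurve(candidates=[10, 20],
                                fold_perplexities=[[500.0], [600.0]])
        assert compute_rpc(curve).values == pytest.approx([10.0], abs=1e-9)

    def test_single_candidate_insufficient(self):
        curve = PerplexityCurve(candidates=[10], fold_perplexities=[[5.0]])
        with pytest.raises(ValueError):
            compute_rpc(curve)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1.0, 1e4), min_size=3, max_size=8),
           st.floats(0.1, 1e3))
    def test_shift_invariance(self, perps, shift):
        t = np.arange(5, 5 + 10 * len(perps), 10)
        a = compute_rpc(PerplexityCurve(t, np.array(perps)[:, None]))
        b = compute_rpc(PerplexityCurve(t, (np.array(perps) + shift)[:, None]))
        assert np.allclose(a.values, b.values, rtol=0, atol=1e-6)


class TestChangePointRule:
    def test_first_rise_selected(self):
        curve = PerplexityCurve(candidates=[5, 10, 20, 30],
                                fold_perplexities=np.array(
                                    [[1000.0], [800.0], [760.0], [700.0]]))
        rpc = compute_rpc(curve)
        assert rpc.values == pytest.approx([40.0, 4.0, 6.0], abs=1e-9)
        res = select_change_point(rpc)
        assert res.chosen == 20 and res.found

    def test_monotone_series_has_no_change_point(self):
        rpc = RPCSeries(topic_numbers=[10, 20, 30], values=[40.0, 30.0, 20.0])
        res = select_change_point(rpc)
        assert not res.found
        assert res.chosen == 30  # fallback: last candidate, flagged

    def test_immediate_rise_selects_first(self):
        rpc = RPCSeries(topic_numbers=[10, 20, 30], values=[5.0, 7.0, 6.0])
        res = select_change_point(rpc)
        assert res.chosen == 10 and res.found

    def test_tie_is_not_a_change_point(self):
        rpc = RPCSeries(topic_numbers=[10, 20, 30], values=[5.0, 5.0, 4.0])
        assert not select_change_point(rpc).found

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_change_point(RPCSeries(topic_numbers=[10], values=[1.0]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=10))
    def test_agrees_with_brute_force_scan(self, values):
        t = np.arange(10, 10 * (len(values) + 1), 10)
        res = select_change_point(RPCSeries(topic_numbers=t, values=values))
        hits = [t[j] for j in range(len(values) - 1) if values[j] < values[j + 1]]
        if hits:
            assert res.found and res.chosen == hits[0]
        else:
            assert not res.found and res.chosen == t[-1]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=8),
           st.floats(0.01, 100.0))
    def test_invariant_to_positive_rescaling(self, values, scale):
        t = np.arange(10, 10 * (len(values) + 1), 10)
        a = select_change_point(RPCSeries(t, np.array(values)))
        b = select_change_point(RPCSeries(t, np.array(values) * scale))
        assert (a.chosen, a.found) == (b.chosen, b.found)


class TestMinPerplexityRule:
    def test_argmin(self):
        curve = PerplexityCurve([10, 20, 30], np.array([[3.0], [1.0], [2.0]]))
        assert select_min_perplexity(curve).chosen == 20

    def test_tie_goes_to_smallest_candidate(self):
        curve = PerplexityCurve([10, 20, 30], np.array([[2.0], [2.0], [3.0]]))
        assert select_min_perplexity(curve).chosen == 10

    def test_single_candidate(self):
        curve = PerplexityCurve([10], np.array([[2.0]]))
        assert select_min_perplexity(curve).chosen == 10


class TestFolds:
    def test_balanced_partition(self):
        folds = make_folds(11, 3, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [3, 4, 4]
        assert sorted(np.concatenate(folds).tolist()) == list(range(11))

    def test_leave_one_out(self):
        folds = make_folds(6, 6, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_more_folds_than_documents_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, 4, seed=0)

    def test_deterministic(self):
        a = make_folds(20, 5, seed=3)
        b = make_folds(20, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestCrossValidation:
    def test_curve_is_deterministic_under_seed(self):
        corpus, _ = generate_separable_corpus(n_docs=18, n_topics=2, doc_len=20,
                                              seed=2)
        kw = dict(candidates=[2, 3], m_folds=3, seed=5, n_iter=40, burn_in=20)
        a = cross_validate_perplexity(corpus, **kw)
        b = cross_validate_perplexity(corpus, **kw)
        assert np.array_equal(a.fold_perplexities, b.fold_perplexities)

    def test_identical_documents_give_symmetric_folds(self):
        # all docs identical -> every fold is exchangeable -> tight spread
        doc = np.array([0, 1, 2, 0, 1, 2, 3, 3], dtype=int)
        corpus = Corpus(documents=[doc.copy() for _ in range(30)],
                        vocabulary=["a", "b", "c", "d"],
                        doc_ids=[f"d{i}" for i in range(30)])
        curve = cross_validate_perplexity(corpus, candidates=[2, 3], m_folds=3,
                                          seed=1, n_iter=60, burn_in=30)
        spread = np.ptp(curve.fold_perplexities, axis=1) / curve.mean_perplexity
        assert (spread < 0.05).all()

    def test_mean_is_arithmetic_fold_mean(self):
        curve = PerplexityCurve([5, 10], np.array([[2.0, 4.0], [3.0, 5.0]]))
        assert curve.mean_perplexity == pytest.approx([3.0, 4.0], abs=1e-9)

    def test_selector_estimator_end_to_end(self):
        corpus, _ = generate_separable_corpus(n_docs=18, n_topics=2, doc_len=20,
                                              seed=2)
        sel = RPCTopicSelector(candidates=[2, 3, 4], m_folds=3, n_iter=40,
                               burn_in=20, random_state=0).fit(corpus)
        assert sel.n_topics_ in (2, 3, 4)
        assert sel.rpc_.values.shape == (2,)
        assert sel.get_params()["m_folds"] == 3
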