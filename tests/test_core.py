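"""The reading loop: STM buffer, activation, decay, and ranking."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import readtopics as rt
from conftest import random_toy_fixture


def make_buffer(capacity, words=()):
    buf = rt.STMBuffer(capacity)
    for w in words:
        rt.stm_update(buf, w)
    return buf


class TestSTMBuffer:
    def test_full_buffer_evicts_least_recently_rehearsed(self):
        buf = make_buffer(2, ["a", "b"])
        assert rt.stm_update(buf, "c") == "a"
        assert buf.slots == ("b", "c")

    def test_rehearsal_moves_word_to_most_recent_without_eviction(self):
        buf = make_buffer(2, ["a", "b"])
        assert rt.stm_update(buf, "a") is None
        assert buf.slots == ("b", "a")

    def test_zero_capacity_never_stores(self):
        buf = make_buffer(0)
        assert rt.stm_update(buf, "a") is None
        assert buf.slots == ()

    @given(st.lists(st.sampled_from("abcdefgh"), max_size=60), st.integers(0, 5))
    def test_bounded_unique_and_recency_ordered(self, words, capacity):
        buf = rt.STMBuffer(capacity)
        for w in words:
            rt.stm_update(buf, w)
            assert len(buf.slots) <= capacity
            assert len(set(buf.slots)) == len(buf.slots)
        if capacity and words:
            assert buf.slots[-1] == words[-1]


class TestDecayStep:
    def test_zero_delta_is_identity(self):
        state = rt.ActivationState(activation={"x": 2.0}, first_seen={"x": 0})
        rt.decay_step(state, set(), 0.0)
        assert state.activation == {"x": 2.0}

    def test_floors_at_resting_value(self):
        state = rt.ActivationState(activation={"x": 0.3}, first_seen={"x": 0})
        rt.decay_step(state, set(), 0.5)
        assert state.activation["x"] == 0.0

    def test_protected_items_do_not_decay(self):
        state = rt.ActivationState(activation={"x": 2.0, "y": 2.0}, first_seen={"x": 0, "y": 1})
        rt.decay_step(state, {"x"}, 1.0)
        assert state.activation == {"x": 2.0, "y": 1.0}
        assert state.first_seen == {"x": 0, "y": 1}


class TestRankTopics:
    def test_orders_by_decreasing_activation(self):
        state = rt.ActivationState(activation={"a": 3.0, "b": 1.0}, first_seen={"a": 0, "b": 1})
        assert rt.rank_topics(state, 10) == [("a", 3.0), ("b", 1.0)]

    def test_ties_broken_by_earlier_first_activation(self):
        state = rt.ActivationState(activation={"a": 2.0, "b": 2.0}, first_seen={"a": 5, "b": 1})
        assert rt.rank_topics(state, 1) == [("b", 2.0)]

    def test_remaining_ties_broken_lexicographically(self):
        state = rt.ActivationState(activation={"b": 2.0, "a": 2.0}, first_seen={"a": 3, "b": 3})
        assert [i for i, _ in rt.rank_topics(state)] == ["a", "b"]

    def test_empty_state_and_zero_activation_excluded(self):
        assert rt.rank_topics(rt.ActivationState()) == []
        state = rt.ActivationState(activation={"a": 0.0}, first_seen={"a": 0})
        assert rt.rank_topics(state) == []


class TestReadParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stm_capacity": -1},
            {"decay_rate": -0.5},
            {"activation_increment": 0},
            {"decay_law": "quadratic"},
            {"top_k": (10, 5)},
            {"top_k": ()},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rt.ReadParams(**kwargs)

    def test_linear_delta_is_inverse_decay_rate(self):
        assert rt.ReadParams(decay_rate=0).delta == 0.0
        assert rt.ReadParams(decay_rate=4).delta == 0.25


class TestProcessDocument:
    def test_three_disjoint_words_under_rapid_decay_all_return_to_rest(self):
        """With no STM and delta=1, each item gains 1 then decays on the same
        step: after three disjoint words nothing retains activation."""
        toy = rt.ToyLexicon(entries={"w1": ["i1"], "w2": ["i2"], "w3": ["i3"]})
        params = rt.ReadParams(stm_capacity=0, decay_rate=1.0)
        assert rt.process_document(["w1", "w2", "w3"], params, toy) == []

    def test_empty_document(self):
        assert rt.process_document([], rt.ReadParams(), rt.ToyLexicon()) == []

    def test_matches_frequency_baseline_without_decay_or_stm(self):
        """Dual-route oracle: the full loop at stm=0, eta=0 must reproduce the
        independent counting baseline exactly (items, scores, order)."""
        for seed in range(20):
            lexicon, docs = random_toy_fixture(seed, n_docs=1)
            loop = rt.process_document(docs[0], rt.ReadParams(), lexicon)
            counting = rt.baseline_frequency(docs[0], lexicon)
            assert loop == counting

    @pytest.mark.parametrize("eta", [1.0, 5.0, 25.0])
    def test_saturated_stm_suppresses_all_decay(self, eta):
        """A buffer holding every distinct word protects every item, so any
        decay rate reproduces the no-decay ranking exactly."""
        for seed in range(5):
            lexicon, docs = random_toy_fixture(seed, n_docs=1)
            capacity = len(set(docs[0]))
            params = rt.ReadParams(stm_capacity=capacity, decay_rate=eta)
            assert rt.process_document(docs[0], params, lexicon) == rt.baseline_frequency(docs[0], lexicon)

    def test_final_activation_nondecreasing_in_decay_rate(self):
        """Slower decay (larger eta) never loses more activation per item."""
        for seed in range(5):
            lexicon, docs = random_toy_fixture(seed, n_docs=1)
            previous = None
            for eta in (1.0, 2.0, 5.0, 10.0, 25.0):
                ranking = rt.process_document(
                    docs[0], rt.ReadParams(stm_capacity=0, decay_rate=eta), lexicon
                )
                levels = dict(ranking)
                if previous is not None:
                    for item, value in previous.items():
                        assert levels.get(item, 0.0) >= value
                previous = levels

    def test_activation_nonnegative_and_bounded_by_retrieval_count(self):
        lexicon, docs = random_toy_fixture(3, n_docs=1)
        retrievals = {}
        for word in docs[0]:
            for item in lexicon.entries[word]:
                retrievals[item] = retrievals.get(item, 0) + 1
        for stm, eta in [(0, 1.0), (2, 3.0), (4, 0.0)]:
            ranking = rt.process_document(
                docs[0], rt.ReadParams(stm_capacity=stm, decay_rate=eta), lexicon
            )
            for item, value in ranking:
                assert 0.0 < value <= retrievals[item]

    def test_identical_inputs_give_identical_rankings(self):
        lexicon, docs = random_toy_fixture(11, n_docs=1)
        params = rt.ReadParams(stm_capacity=3, decay_rate=2.0)
        first = rt.process_document(docs[0], params, lexicon)
        assert first == rt.process_document(docs[0], params, lexicon)

    def test_stm_protection_preserves_recurring_shared_item(self):
        """A word kept in STM shields its items from decay: a shared item of
        adjacent words survives rapid decay while isolated ones vanish."""
        toy = rt.ToyLexicon(entries={"w1": ["shared"], "w2": ["shared"], "w3": ["lone"]})
        doc = ["w1", "w2", "w1", "w2", "w3", "w1", "w2"]
        no_stm = rt.process_document(doc, rt.ReadParams(stm_capacity=0, decay_rate=1.0), toy)
        with_stm = rt.process_document(doc, rt.ReadParams(stm_capacity=2, decay_rate=1.0), toy)
        assert dict(no_stm).get("shared", 0.0) < dict(with_stm)["shared"]
        assert "lone" not in dict(with_stm)

    def test_exponential_law_decays_unprotected_items_multiplicatively(self):
        toy = rt.ToyLexicon(entries={"w1": ["i1"], "w2": ["i2"]})
        params = rt.ReadParams(stm_capacity=0, decay_rate=2.0, decay_law="exponential")
        levels = dict(rt.process_document(["w1", "w2"], params, toy))
        import math

        f = math.exp(-0.5)
        assert levels["i1"] == pytest.approx(f * f)
        assert levels["i2"] == pytest.approx(f)


class TestBaselineFrequency:
    def test_dominant_item_ranks_first(self):
        toy = rt.ToyLexicon(
            entries={
                "crude": ["oil", "petroleum"],
                "barrel": ["oil", "container"],
                "opec": ["oil", "cartel"],
                "tree": ["plant"],
                "sky": ["air"],
            }
        )
        doc = ["crude", "barrel", "opec", "tree", "sky"]
        ranking = rt.baseline_frequency(doc, toy)
        assert ranking[0] == ("oil", 3.0)

    def test_empty_document(self):
        assert rt.baseline_frequency([], rt.ToyLexicon()) == []

    def test_tie_break_matches_rank_topics_convention(self):
        toy = rt.ToyLexicon(entries={"w1": ["b"], "w2": ["a"]})
        # both items appear once; w1's item was retrieved first
        assert rt.baseline_frequency(["w1", "w2"], toy) == [("b", 1.0), ("a", 1.0)]
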