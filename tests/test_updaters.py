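"""Successor policies: deterministic, non-deterministic, stochastic."""
import random

import pytest

import mvlogic as mv

def states(model, *digit_strings):
    return [mv.parse_state(model, s) for s in digit_strings]


# ---------------------------------------------------------------------------
# deterministic policies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "state, successor",
    [("1210", "0220"), ("1011", "1010"), ("0011", None)],
)
def test_synchronous_successor_p53(p53, state, successor):
    got = mv.synchronous_successor(p53, mv.parse_state(p53, state))
    expected = None if successor is None else mv.parse_state(p53, successor)
    assert got == expected


def test_sequential_successor_p53_declaration_order(p53):
    # DNAdam drops first, then Mdm2cyt rises on the updated state, then Mdm2nuc
    order = list(range(4))
    got = mv.sequential_successor(p53, mv.parse_state(p53, "1210"), order)
    assert got == mv.parse_state(p53, "0221")
    assert mv.sequential_successor(p53, mv.parse_state(p53, "0011"), order) is None


def test_sequential_with_single_call_placed_last_is_synchronous(small_models):
    # a lone called component updates nothing before its own turn, so any
    # order ending with it reproduces the synchronous step; earlier
    # positions may trigger further calls within the same pass
    for m in small_models:
        for s in m.all_states():
            called = mv.called_components(m, s)
            if len(called) == 1:
                (i,) = called
                order = [j for j in range(len(m.components)) if j != i] + [i]
                assert mv.sequential_successor(m, s, order) == mv.synchronous_successor(m, s)


def test_block_sequential_reductions(small_models):
    for m in small_models:
        n = len(m.components)
        one_block = [list(range(n))]
        singletons = [[i] for i in range(n)]
        for s in m.all_states():
            assert mv.block_sequential_successor(m, s, one_block) == mv.synchronous_successor(m, s)
            assert mv.block_sequential_successor(m, s, singletons) == mv.sequential_successor(m, s, list(range(n)))


def test_block_sequential_p53_two_blocks(p53):
    # block 1: DNAdam drops (p53 stays at its target).  Block 2 sees 0210;
    # within the block Mdm2cyt and Mdm2nuc evaluate synchronously, so
    # Mdm2nuc still sees Mdm2cyt = 1 and stays off.
    blocks = [[p53.index("DNAdam"), p53.index("p53")], [p53.index("Mdm2cyt"), p53.index("Mdm2nuc")]]
    got = mv.block_sequential_successor(p53, mv.parse_state(p53, "1210"), blocks)
    assert got == mv.parse_state(p53, "0220")


def test_synchronous_priority_p53(p53):
    # p53 is not called in 1210: the second class fires synchronously
    classes = [[p53.index("p53")], [p53.index("DNAdam"), p53.index("Mdm2cyt"), p53.index("Mdm2nuc")]]
    got = mv.synchronous_priority_successor(p53, mv.parse_state(p53, "1210"), classes)
    assert got == mv.parse_state(p53, "0220")


def test_synchronous_priority_single_class_is_synchronous(small_models):
    for m in small_models:
        classes = [list(range(len(m.components)))]
        for s in m.all_states():
            assert mv.synchronous_priority_successor(m, s, classes) == mv.synchronous_successor(m, s)


def test_partition_is_validated(p53):
    s = mv.parse_state(p53, "1210")
    with pytest.raises(mv.ModelError, match="cover"):
        mv.sequential_successor(p53, s, [0, 1])
    with pytest.raises(mv.ModelError, match="cover"):
        mv.block_sequential_successor(p53, s, [[0, 1], [1, 2, 3]])


# ---------------------------------------------------------------------------
# non-deterministic policies
# ---------------------------------------------------------------------------

def test_asynchronous_successors_p53(p53):
    assert set(mv.asynchronous_successors(p53, mv.parse_state(p53, "1210"))) == set(
        states(p53, "0210", "1220")
    )
    assert mv.asynchronous_successors(p53, mv.parse_state(p53, "1011")) == states(p53, "1010")
    assert mv.asynchronous_successors(p53, mv.parse_state(p53, "0011")) == []


def test_complete_successors_p53(p53):
    assert set(mv.complete_successors(p53, mv.parse_state(p53, "1210"))) == set(
        states(p53, "0210", "1220", "0220")
    )


def test_complete_contains_asynchronous_and_synchronous(small_models):
    for m in small_models:
        for s in m.all_states():
            complete = set(mv.complete_successors(m, s))
            called = mv.called_components(m, s)
            assert set(mv.asynchronous_successors(m, s)) <= complete
            if called:
                assert mv.synchronous_successor(m, s) in complete
                assert len(complete) <= 2 ** len(called) - 1
            else:
                assert not complete


def test_every_successor_unit_steps(small_models):
    for m in small_models:
        for s in m.all_states():
            for succ in mv.complete_successors(m, s):
                diffs = [abs(a - b) for a, b in zip(s, succ)]
                assert succ != s and max(diffs) == 1


def test_stable_states_have_no_successor_under_any_policy(small_models):
    for m in small_models:
        n = len(m.components)
        for s in m.all_states():
            if mv.called_components(m, s):
                continue
            assert mv.synchronous_successor(m, s) is None
            assert mv.sequential_successor(m, s, list(range(n))) is None
            assert mv.asynchronous_successors(m, s) == []
            assert mv.complete_successors(m, s) == []
            assert mv.priority_successors(m, s, [(list(range(n)), "asynchronous")]) == []


def test_priority_successors_p53(p53):
    classes = [
        ([p53.index("DNAdam")], "asynchronous"),
        ([p53.index("p53"), p53.index("Mdm2cyt"), p53.index("Mdm2nuc")], "asynchronous"),
    ]
    got = mv.priority_successors(p53, mv.parse_state(p53, "1210"), classes)
    assert got == states(p53, "0210")


def test_priority_single_class_reductions(small_models):
    for m in small_models:
        everyone = list(range(len(m.components)))
        for s in m.all_states():
            assert mv.priority_successors(m, s, [(everyone, "asynchronous")]) == mv.asynchronous_successors(m, s)
            sync = mv.synchronous_successor(m, s)
            expected = [] if sync is None else [sync]
            assert mv.priority_successors(m, s, [(everyone, "synchronous")]) == expected


# ---------------------------------------------------------------------------
# stochastic updating
# ---------------------------------------------------------------------------

def test_random_successor_stable_and_forced(p53):
    rng = random.Random(0)
    upd = mv.Stochastic()
    assert mv.random_successor(p53, mv.parse_state(p53, "0011"), upd, rng) is None
    assert mv.random_successor(p53, mv.parse_state(p53, "1011"), upd, rng) == mv.parse_state(p53, "1010")


def test_random_successor_uniform_frequencies(p53):
    rng = random.Random(12345)
    upd = mv.Stochastic()
    s = mv.parse_state(p53, "1210")
    draws = 10_000
    counts = {}
    for _ in range(draws):
        succ = mv.random_successor(p53, s, upd, rng)
        counts[succ] = counts.get(succ, 0) + 1
    assert set(counts) == set(states(p53, "0210", "1220"))
    # binomial(n=10000, p=0.5): 3 sigma = 150
    assert abs(counts[mv.parse_state(p53, "0210")] - draws / 2) <= 3 * (draws * 0.25) ** 0.5


def test_weighted_random_successor_biases_component_choice(p53):
    rng = random.Random(9)
    upd = mv.Stochastic(weights={"DNAdam": 9.0, "Mdm2cyt": 1.0})
    s = mv.parse_state(p53, "1210")
    hits = sum(
        mv.random_successor(p53, s, upd, rng) == mv.parse_state(p53, "0210")
        for _ in range(2000)
    )
    assert abs(hits - 1800) <= 3 * (2000 * 0.9 * 0.1) ** 0.5


def test_stochastic_validation():
    with pytest.raises(mv.ModelError, match="positive"):
        mv.Stochastic(weights={"a": 0.0})
    with pytest.raises(mv.ModelError, match="asynchronous base"):
        mv.Stochastic(base=mv.Complete(), weights={"a": 1.0})


# ---------------------------------------------------------------------------
# updater selection strings
# ---------------------------------------------------------------------------

def test_parse_updater_strings(p53):
    assert isinstance(mv.parse_updater(p53, "synchronous", True), mv.Synchronous)
    seq = mv.parse_updater(p53, "sequential:p53,DNAdam,Mdm2cyt,Mdm2nuc", True)
    assert seq.order == (1, 0, 2, 3)
    pri = mv.parse_updater(p53, "priority:[p53][DNAdam,Mdm2cyt,Mdm2nuc]", True)
    assert pri.classes == ((1,), (0, 2, 3))
    assert isinstance(mv.parse_updater(p53, "asynchronous", False), mv.Asynchronous)
    assert isinstance(mv.parse_updater(p53, "complete", False), mv.Complete)
    with pytest.raises(mv.ModelError, match="unknown"):
        mv.parse_updater(p53, "gillespie", True)
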