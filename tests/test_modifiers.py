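"""Perturbations, booleanization, and model reduction."""
import pytest

import mvlogic as mv
from mvlogic.modifiers import FixAtom, RangeAtom, RemoveInteractionAtom

from conftest import make_models


def digit_states(states):
    return [mv.format_state(s) for s in states]


def same_dynamics(a, b):
    assert a.names == b.names
    return all(mv.target_state(a, s) == mv.target_state(b, s) for s in a.all_states())


# ---------------------------------------------------------------------------
# perturbation parsing
# ---------------------------------------------------------------------------

def test_parse_perturbation_tokens(p53):
    assert mv.parse_perturbation(p53, ["p53%0"]).atoms == (FixAtom("p53", 0),)
    assert mv.parse_perturbation(p53, ["p53:DNAdam%0"]).atoms == (
        RemoveInteractionAtom("p53", "DNAdam"),
    )
    assert mv.parse_perturbation(p53, ["Mdm2cyt%0:1"]).atoms == (
        RangeAtom("Mdm2cyt", 0, 1),
    )
    multiple = mv.parse_perturbation(p53, ["p53%0", "Mdm2cyt%0:1"])
    assert len(multiple.atoms) == 2


@pytest.mark.parametrize(
    "token, message",
    [
        ("ghost%0", "unknown component"),
        ("p53%3", "outside the range"),
        ("Mdm2cyt%2:1", "invalid range"),
        ("p53", "malformed"),
        ("p53%%0", "malformed"),
    ],
)
def test_parse_perturbation_errors(p53, token, message):
    with pytest.raises(mv.ModelError, match=message):
        mv.parse_perturbation(p53, [token])


def test_parse_perturbation_rejects_duplicates(p53):
    with pytest.raises(mv.ModelError, match="duplicate"):
        mv.parse_perturbation(p53, ["p53%0", "p53%1"])


# ---------------------------------------------------------------------------
# fix / range / interaction removal
# ---------------------------------------------------------------------------

def test_apply_fix_p53_knockout(p53):
    ko = mv.apply_fix(p53, "p53", 0)
    assert digit_states(mv.fixpoints(ko)) == ["0011", "1010"]
    assert mv.infer_regulators(ko, ko.index("p53")) == set()


def test_apply_fix_preserves_consistent_stable_state(p53):
    fixed = mv.apply_fix(p53, "Mdm2nuc", 1)
    assert mv.parse_state(p53, "0011") in mv.fixpoints(fixed)


def test_apply_fix_matches_brute_force(p53):
    m = mv.apply_fix(p53, "Mdm2cyt", 2)
    assert mv.fixpoints(m) == mv.fixpoints_bruteforce(m)


def test_apply_range_clamps_targets(p53):
    m = mv.apply_range(p53, "p53", 0, 1)
    i = p53.index("p53")
    for s in p53.all_states():
        expected = min(mv.target_value(p53, s, i), 1)
        assert mv.target_value(m, s, i) == expected


def test_apply_range_identity_and_fix_equivalence(p53):
    assert same_dynamics(mv.apply_range(p53, "Mdm2cyt", 0, 2), p53)
    assert same_dynamics(
        mv.apply_range(p53, "Mdm2cyt", 1, 1), mv.apply_fix(p53, "Mdm2cyt", 1)
    )


def test_apply_range_minimum_level_lifts_default(p53):
    m = mv.apply_range(p53, "Mdm2cyt", 1, 2)
    i = p53.index("Mdm2cyt")
    for s in p53.all_states():
        assert mv.target_value(m, s, i) == max(1, mv.target_value(p53, s, i))


def test_remove_interaction_p53_to_dnadam(p53):
    m = mv.remove_interaction(p53, "p53", "DNAdam")
    # the repair input is gone: DNAdam's rule reduces to its own persistence
    i = m.index("DNAdam")
    regs = {m.names[r] for r, _ in mv.infer_regulators(m, i)}
    assert regs == {"DNAdam"}
    assert digit_states(mv.fixpoints(m)) == ["0011"]


def test_remove_interaction_idempotent(p53):
    once = mv.remove_interaction(p53, "p53", "DNAdam")
    twice = mv.remove_interaction(once, "p53", "DNAdam")
    assert same_dynamics(once, twice)


def test_remove_interaction_non_regulator_is_noop(p53):
    m = mv.remove_interaction(p53, "DNAdam", "Mdm2cyt")
    assert same_dynamics(m, p53)


# ---------------------------------------------------------------------------
# booleanization
# ---------------------------------------------------------------------------

def test_booleanize_p53_component_names(p53):
    bm, bmap = mv.booleanize(p53)
    assert bm.names == [
        "DNAdam",
        "p53_b1",
        "p53_b2",
        "Mdm2cyt_b1",
        "Mdm2cyt_b2",
        "Mdm2nuc",
    ]
    assert bm.is_boolean()


def test_booleanize_boolean_model_is_identity():
    m = mv.parse_mnet("a <- b\nb <- a\n")
    bm, bmap = mv.booleanize(m)
    assert bm is m and bmap.names == ["a", "b"]


def test_booleanization_bijection_on_admissible_states(p53):
    bm, bmap = mv.booleanize(p53)
    admissible = [s for s in bm.all_states() if bmap.is_admissible(s)]
    assert len(admissible) == p53.state_count()
    for s in p53.all_states():
        e = bmap.encode(s)
        assert bmap.is_admissible(e) and bmap.decode(e) == tuple(s)


def test_booleanization_transition_correspondence(p53):
    bm, bmap = mv.booleanize(p53)
    for s in p53.all_states():
        e = bmap.encode(s)
        sync = mv.synchronous_successor(p53, s)
        bsync = mv.synchronous_successor(bm, e)
        assert bsync == (None if sync is None else bmap.encode(sync))
        got = {tuple(x) for x in mv.asynchronous_successors(bm, e)}
        want = {bmap.encode(x) for x in mv.asynchronous_successors(p53, s)}
        assert got == want


def _booleanization_stg_checks(m):
    import networkx as nx

    bm, bmap = mv.booleanize(m)
    g = mv.build_stg(bm, mv.Asynchronous())
    admissible = {s for s in g.nodes if bmap.is_admissible(s)}
    # every non-admissible state can asynchronously reach an admissible one
    reaches = set(admissible)
    reversed_g = g.reverse(copy=False)
    for a in admissible:
        reaches |= nx.descendants(reversed_g, a)
    assert reaches == set(g.nodes)
    # no attractor contains a non-admissible state
    for scc in mv.terminal_sccs(g):
        assert scc <= admissible
    # arcs between admissible states mirror the multi-valued dynamics
    mg = mv.build_stg(m, mv.Asynchronous())
    mapped = {(bmap.encode(a), bmap.encode(b)) for a, b in mg.edges}
    restricted = {
        (a, b) for a, b in g.edges if a in admissible and b in admissible
    }
    assert mapped == restricted


def test_booleanization_dynamics_on_fixtures(p53):
    _booleanization_stg_checks(p53)
    for m in make_models(2024, 6, n_range=(2, 3), max_level=3):
        _booleanization_stg_checks(m)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def test_reduce_removes_mdm2cyt(p53):
    rr = mv.reduce(p53, ["Mdm2cyt"])
    assert rr.reduced_model.names == ["DNAdam", "p53", "Mdm2nuc"]
    assert mv.fixpoints(rr.reduced_model) == [(0, 0, 1)]
    assert mv.fixpoints(rr.reduced_model) == mv.fixpoints_bruteforce(rr.reduced_model)
    assert set(rr.derived_functions) == {"Mdm2cyt"}


def test_reduce_rejects_self_regulated_component(p53):
    with pytest.raises(mv.ReductionError, match="regulates itself"):
        mv.reduce(p53, ["DNAdam"])


def test_reduce_component_without_targets_keeps_other_rules():
    m = mv.parse_mnet("a <- a\nb <- a\n")
    rr = mv.reduce(m, ["b"])
    assert rr.reduced_model.names == ["a"]
    assert same_dynamics(rr.reduced_model, mv.parse_mnet("a <- a\n"))


def test_reduce_preserves_projected_stable_states(small_models):
    for m in small_models:
        originals = mv.fixpoints(m)
        for i, comp in enumerate(m.components):
            if i in {r for r, _ in mv.infer_regulators(m, i)}:
                continue  # self-regulated: elimination undefined
            rr = mv.reduce(m, [comp.name])
            projected = sorted(
                {tuple(lv for j, lv in enumerate(s) if j != i) for s in originals}
            )
            assert mv.fixpoints(rr.reduced_model) == projected


def test_reduce_outputs_p53_is_identity(p53):
    rr = mv.reduce_outputs(p53)
    assert rr.reduced_model.names == p53.names and rr.derived_functions == {}


def test_reduce_outputs_simple_and_chained():
    rr = mv.reduce_outputs(mv.parse_mnet("a <- a\nb <- a\n"))
    assert rr.reduced_model.names == ["a"] and set(rr.derived_functions) == {"b"}
    rr = mv.reduce_outputs(mv.parse_mnet("a <- a\nb <- a\nc <- b\n"))
    assert rr.reduced_model.names == ["a"]
    assert set(rr.derived_functions) == {"b", "c"}


def test_propagate_fixed_after_knockout(p53):
    rr = mv.propagate_fixed(mv.apply_fix(p53, "p53", 0))
    from mvlogic.formats import expr_text

    reduced = rr.reduced_model
    i = reduced.index("DNAdam")
    assert expr_text(reduced.functions[i].rows[0][1]) == "DNAdam"
    # the projected stable states survive propagation
    kept = [j for j, c in enumerate(p53.components) if c.name in reduced.names]
    ko = mv.apply_fix(p53, "p53", 0)
    projected = sorted({tuple(s[j] for j in kept) for s in mv.fixpoints(ko)})
    assert mv.fixpoints(reduced) == projected


def test_propagate_fixed_without_constants_is_identity(p53):
    rr = mv.propagate_fixed(p53)
    assert rr.reduced_model.names == p53.names and rr.derived_functions == {}


def test_propagate_fixed_resolves_constant_cascade():
    rr = mv.propagate_fixed(mv.parse_mnet("a <- 1\nb <- a\nc <- b\n"))
    assert rr.reduced_model.names == []
    assert set(rr.derived_functions) == {"a", "b", "c"}


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def test_chain_matches_manual_application(p53):
    chained = mv.chain(
        p53, [mv.parse_perturbation(p53, ["p53%0"]), mv.booleanized]
    )
    manual = mv.booleanize(mv.apply_fix(p53, "p53", 0))[0]
    assert same_dynamics(chained, manual)


def test_chain_empty_is_identity(p53):
    assert mv.chain(p53, []) is p53


def test_chain_reports_failing_modifier_index(p53):
    with pytest.raises(mv.ModelError, match="modifier 1"):
        mv.chain(p53, [mv.booleanized, lambda m: mv.apply_fix(m, "ghost", 0)])


def test_chain_then_trapspaces_reproduces_interaction_removal(p53):
    m = mv.chain(p53, [mv.parse_perturbation(p53, ["p53:DNAdam%0"])])
    assert [str(p) for p in mv.trapspaces(m)] == ["000101", "1--1--"]
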