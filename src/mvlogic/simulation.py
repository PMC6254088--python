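"""Deterministic traces, random walks, and a small STG builder.

The state-transition-graph builder enumerates explicit dynamics for
small models; it serves as the exhaustive cross-check for the static
analyses and for the updating-mode invariants.  Attractors are the
terminal strongly connected components of the STG.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from .model import LogicalModel, ModelError, State
from .updaters import (
    DeterministicUpdater,
    MultiSuccessorUpdater,
    Stochastic,
    random_successor,
)

STABLE = "stable"
CYCLE = "cycle"
STEP_LIMIT = "step_limit"

DEFAULT_TRACE_STEPS = 1000
DEFAULT_WALK_STEPS = 10_000
DEFAULT_STG_CAP = 1 << 16


@dataclass
class Trace:
    """An ordered list of visited states plus the reason the run stopped.

    ``termination`` is ``stable`` (the last state has no successor),
    ``cycle`` (the last state's successor is ``states[cycle_entry]``;
    the cycle length is ``len(states) - cycle_entry``) or ``step_limit``.
    """

    states: list[State]
    termination: str
    cycle_entry: int | None = None

    def __len__(self) -> int:
        return len(self.states)


def trace(
    model: LogicalModel,
    updater: DeterministicUpdater,
    initial,
    max_steps: int = DEFAULT_TRACE_STEPS,
) -> Trace:
    """Deterministic simulation from an initial state.

    Stops at a stable state, on the first revisit of a previous state
    (recording the cycle entry point, without re-appending the repeated
    state), or after ``max_steps`` transitions.
    """
    if max_steps < 1:
        raise ModelError("max_steps must be at least 1")
    state = model.check_state(initial)
    states = [state]
    seen = {state: 0}
    for _ in range(max_steps):
        succ = updater.successor(model, state)
        if succ is None:
            return Trace(states, STABLE)
        if succ in seen:
            return Trace(states, CYCLE, cycle_entry=seen[succ])
        seen[succ] = len(states)
        states.append(succ)
        state = succ
    # classify the state reached after max_steps transitions
    succ = updater.successor(model, state)
    if succ is None:
        return Trace(states, STABLE)
    if succ in seen:
        return Trace(states, CYCLE, cycle_entry=seen[succ])
    return Trace(states, STEP_LIMIT)


def random_walk(
    model: LogicalModel,
    initial,
    seed: int = 0,
    max_steps: int = DEFAULT_WALK_STEPS,
    updater: Stochastic | None = None,
) -> Trace:
    """Single stochastic trajectory; identical seeds give identical traces."""
    if max_steps < 1:
        raise ModelError("max_steps must be at least 1")
    if updater is None:
        updater = Stochastic()
    rng = random.Random(seed)
    state = model.check_state(initial)
    states = [state]
    for _ in range(max_steps):
        succ = random_successor(model, state, updater, rng)
        if succ is None:
            return Trace(states, STABLE)
        states.append(succ)
        state = succ
    return Trace(states, STEP_LIMIT)


ALL = "ALL"


def build_stg(
    model: LogicalModel,
    updater: MultiSuccessorUpdater,
    initial=ALL,
    cap: int = DEFAULT_STG_CAP,
) -> nx.DiGraph:
    """State transition graph: reachable closure of an initial state set.

    ``initial=ALL`` covers the full state space (subject to ``cap``).
    """
    g = nx.DiGraph()
    if initial is ALL or initial == ALL:
        if model.state_count() > cap:
            raise ModelError(
                f"state space of {model.state_count()} states exceeds the "
                f"cap of {cap}"
            )
        frontier = [tuple(s) for s in model.all_states()]
        g.add_nodes_from(frontier)
    else:
        frontier = [model.check_state(s) for s in initial]
        g.add_nodes_from(frontier)
    seen = set(g.nodes)
    while frontier:
        state = frontier.pop()
        for succ in updater.successors(model, state):
            if succ not in seen:
                if len(seen) >= cap:
                    raise ModelError(f"reachable state count exceeds the cap of {cap}")
                seen.add(succ)
                frontier.append(succ)
            g.add_edge(state, succ)
    return g


def terminal_sccs(g: nx.DiGraph) -> list[frozenset]:
    """Attractors: strongly connected components without outgoing arcs."""
    out = []
    for scc in nx.strongly_connected_components(g):
        if all(succ in scc for node in scc for succ in g.successors(node)):
            out.append(frozenset(scc))
    return out
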