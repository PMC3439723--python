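"""Shared fixtures: reference semantics oracle and solved example models."""

from __future__ import annotations

import numpy as np
import pytest

from cpepa import (
    aggregate,
    build_generator,
    explore_state_space,
    generate_fixture,
    simple_pathway_model,
    solve_steady_state,
)
from cpepa.model import Cooperation, Instance, Replication, enabled_transitions
from cpepa.pathway import build_model


# ---------------------------------------------------------------------------
# Independent reference implementation of the cooperation semantics.
#
# States are nested tuples mirroring the system tree (component names at
# the leaves), moves are computed by direct recursion without any
# compilation or memoisation.  This is deliberately naive and distinct
# from the engine so structural bugs cannot cancel out.
# ---------------------------------------------------------------------------


def initial_nested(model, node):
    if isinstance(node, (Instance, Replication)):
        copies = node.copies if isinstance(node, Replication) else 1
        return tuple([node.name] * copies)
    return (initial_nested(model, node.left), initial_nested(model, node.right))


def nested_moves(model, node, st):
    """dict action -> (apparent rate, [(rate, successor state)])."""
    if isinstance(node, (Instance, Replication)):
        raw = {}
        for i, local in enumerate(st):
            for act, tgt in enabled_transitions(model, local):
                ns = st[:i] + (tgt,) + st[i + 1:]
                raw.setdefault(act.action, []).append((act.rate, ns))
        return {a: (sum(r for r, _ in v), v) for a, v in raw.items()}
    lm = nested_moves(model, node.left, st[0])
    rm = nested_moves(model, node.right, st[1])
    out = {}
    for a in set(lm) | set(rm):
        if a in node.sync:
            if a in lm and a in rm:
                la, lv = lm[a]
                ra, rv = rm[a]
                tot = min(la, ra)
                moves = [
                    ((lr / la) * (rr / ra) * tot, (ls, rs))
                    for lr, ls in lv
                    for rr, rs in rv
                ]
                out[a] = (tot, moves)
        else:
            app, moves = 0.0, []
            if a in lm:
                la, lv = lm[a]
                app += la
                moves += [(r, (ns, st[1])) for r, ns in lv]
            if a in rm:
                ra, rv = rm[a]
                app += ra
                moves += [(r, (st[0], ns)) for r, ns in rv]
            out[a] = (app, moves)
    return out


def naive_explore(model, max_states=50_000):
    """BFS closure under the reference semantics.

    Returns (states keyed by flattened name tuples, edge-rate dict keyed
    by (src names, tgt names, action)).
    """

    def flatten(nst, node):
        if isinstance(node, (Instance, Replication)):
            return tuple(nst)
        return flatten(nst[0], node.left) + flatten(nst[1], node.right)

    root = model.system
    init = initial_nested(model, root)
    seen = {init}
    states = [init]
    edges = {}
    queue = [init]
    while queue:
        s = queue.pop(0)
        key_s = flatten(s, root)
        for a, (_app, moves) in nested_moves(model, root, s).items():
            for r, ns in moves:
                if ns not in seen:
                    if len(states) >= max_states:
                        raise RuntimeError("oracle state budget exceeded")
                    seen.add(ns)
                    states.append(ns)
                    queue.append(ns)
                key = (key_s, flatten(ns, root), a)
                edges[key] = edges.get(key, 0.0) + r
    return {flatten(s, root) for s in states}, edges


def engine_edges(ts):
    """Engine transitions re-keyed by flattened name tuples, rates summed."""

    def names_of(state):
        out = []
        for g in ts.groups:
            out.extend(g.local_states[v] for v in state[g.slice])
        return tuple(out)

    keys = [names_of(s) for s in ts.states]
    edges = {}
    for s, t, a, r in zip(
        ts.transitions_src, ts.transitions_tgt, ts.transitions_action, ts.transitions_rate
    ):
        key = (keys[int(s)], keys[int(t)], ts.actions[int(a)])
        edges[key] = edges.get(key, 0.0) + float(r)
    return set(keys), edges


# ---------------------------------------------------------------------------
# Solved example models (session-scoped: reused across test modules)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def simple_model():
    return simple_pathway_model()


@pytest.fixture(scope="session")
def simple_ts(simple_model):
    return explore_state_space(simple_model)


@pytest.fixture(scope="session")
def simple_pi(simple_ts):
    return solve_steady_state(build_generator(simple_ts))


@pytest.fixture(scope="session")
def simple_agg(simple_ts):
    return aggregate(simple_ts)


FIXTURE_SEEDS = list(range(20))


@pytest.fixture(scope="session")
def fixture_models():
    """Small random pathway models with their exact transition systems."""
    out = []
    for seed in FIXTURE_SEEDS:
        config = generate_fixture(seed)
        model = build_model(config)
        ts = explore_state_space(model, max_states=50_000)
        out.append((seed, config, model, ts))
    return out
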