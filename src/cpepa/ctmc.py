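"""Labelled transition system derivation, generator assembly, steady state, lumping.

The flattened system is a sequence of *replica groups* (one per leaf of
the cooperation tree); a global state is the tuple of local-state
indices of every instance.  Breadth-first exploration from the initial
state under the minimum-apparent-rate cooperation semantics yields the
finite CTMC; replica-symmetric states are lumped by the counting
abstraction (states that agree on per-group local-state counts form a
class, and the lumped chain is exactly Markov for true replicas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .model import (
    CPPModel,
    Cooperation,
    Instance,
    ModelSemanticsError,
    Replication,
    SystemExpr,
    derivative_set,
    enabled_transitions,
    system_leaves,
)

logger = logging.getLogger("cpepa")

__all__ = [
    "GroupInfo",
    "TransitionSystem",
    "GeneratorMatrix",
    "SteadyState",
    "AggregatedSystem",
    "StateSpaceError",
    "ReducibleChainError",
    "explore_state_space",
    "build_generator",
    "solve_steady_state",
    "aggregate",
    "sample_occupancy",
    "sample_counts",
]


class StateSpaceError(Exception):
    """Raised when exploration would exceed the configured state budget."""


class ReducibleChainError(Exception):
    """Raised when the chain is not irreducible; carries the SCC partition."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


@dataclass(frozen=True)
class GroupInfo:
    """One replica group: ``count`` copies of a sequential component."""

    name: str  # initial component name
    count: int
    local_states: tuple  # derivative names, index == local-state id
    offset: int  # first leaf index in the global tuple

    @property
    def slice(self):
        return slice(self.offset, self.offset + self.count)


@dataclass
class TransitionSystem:
    """Finite labelled transition system of a closed model."""

    states: list  # list of global-state tuples, BFS order
    transitions_src: np.ndarray
    transitions_tgt: np.ndarray
    transitions_action: np.ndarray
    transitions_rate: np.ndarray
    actions: list  # action id -> label
    groups: list  # list[GroupInfo]
    initial: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions_src)

    def action_id(self, label: str) -> int:
        return self.actions.index(label)

    def group(self, name: str) -> GroupInfo:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    # -- exports -------------------------------------------------------
    def to_edge_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "source": self.transitions_src,
                "target": self.transitions_tgt,
                "action": [self.actions[a] for a in self.transitions_action],
                "rate": self.transitions_rate,
            }
        )

    def to_dot(self, state_labels: bool = True) -> str:
        lines = ["digraph transitions {", "  rankdir=LR;"]
        for i, s in enumerate(self.states):
            label = f"S{i + 1}"
            if state_labels:
                label += "\\n" + ",".join(self._short_local(j, v) for j, v in enumerate(s))
            lines.append(f'  n{i} [label="{label}"];')
        for s, t, a, r in zip(
            self.transitions_src,
            self.transitions_tgt,
            self.transitions_action,
            self.transitions_rate,
        ):
            lines.append(f'  n{s} -> n{t} [label="({self.actions[a]}, {r:g})"];')
        lines.append("}")
        return "\n".join(lines)

    def _short_local(self, leaf: int, value: int) -> str:
        for g in self.groups:
            if g.offset <= leaf < g.offset + g.count:
                return g.local_states[value].rsplit("_", 1)[-1]
        raise IndexError(leaf)

    def state_counts(self, index: int) -> tuple:
        """Per-group local-state count vectors of one global state."""
        s = self.states[index]
        out = []
        for g in self.groups:
            counts = [0] * len(g.local_states)
            for v in s[g.slice]:
                counts[v] += 1
            out.append(tuple(counts))
        return tuple(out)


# ---------------------------------------------------------------------------
# Engine compilation
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("memo", "memo_enabled", "sl")

    def moves(self, sub):
        raise NotImplementedError


class _GroupNode(_Node):
    """A replication block of identical sequential instances."""

    __slots__ = ("info", "local_moves", "key_space")

    def __init__(self, info: GroupInfo, local_moves):
        self.info = info
        # local_moves[s] = list of (action_id, rate, new_local)
        self.local_moves = local_moves
        self.sl = (info.offset, info.offset + info.count)
        self.key_space = len(info.local_states) ** info.count
        self.memo = {}
        self.memo_enabled = self.key_space <= 65536

    def moves(self, sub):
        if self.memo_enabled:
            cached = self.memo.get(sub)
            if cached is not None:
                return cached
        out = {}
        base = self.info.offset
        for i, local in enumerate(sub):
            for aid, rate, new in self.local_moves[local]:
                app, lst = out.get(aid, (0.0, None))
                if lst is None:
                    lst = []
                    out[aid] = (rate, lst)
                else:
                    out[aid] = (app + rate, lst)
                lst.append((rate, ((base + i, new),)))
        if self.memo_enabled:
            self.memo[sub] = out
        return out


class _CoopNode(_Node):
    __slots__ = ("left", "right", "sync", "split", "key_space")

    def __init__(self, left, right, sync, action_names):
        self.left = left
        self.right = right
        self.sync = frozenset(sync)
        self.sl = (left.sl[0], right.sl[1])
        self.split = left.sl[1] - left.sl[0]
        self.key_space = left.key_space * right.key_space
        self.memo = {}
        self.memo_enabled = self.key_space <= 65536

    def moves(self, sub):
        if self.memo_enabled:
            cached = self.memo.get(sub)
            if cached is not None:
                return cached
        lmoves = self.left.moves(sub[: self.split])
        rmoves = self.right.moves(sub[self.split :])
        out = {}
        for aid, (lapp, llist) in lmoves.items():
            if aid in self.sync:
                pair = rmoves.get(aid)
                if pair is None:
                    continue
                rapp, rlist = pair
                total = min(lapp, rapp)
                scale = total / (lapp * rapp)
                moves = [
                    (lr * rr * scale, lu + ru)
                    for lr, lu in llist
                    for rr, ru in rlist
                ]
                out[aid] = (total, moves)
            else:
                out[aid] = (lapp, list(llist))
        for aid, (rapp, rlist) in rmoves.items():
            if aid in self.sync:
                continue
            if aid in out:
                app, lst = out[aid]
                out[aid] = (app + rapp, lst + list(rlist))
            else:
                out[aid] = (rapp, list(rlist))
        if self.memo_enabled:
            self.memo[sub] = out
        return out


def compile_engine(model: CPPModel):
    """Flatten the system tree into groups and an executable move tree."""
    actions: list[str] = []
    action_ids: dict[str, int] = {}

    def aid_of(label):
        if label not in action_ids:
            action_ids[label] = len(actions)
            actions.append(label)
        return action_ids[label]

    groups: list[GroupInfo] = []
    offset = 0
    name_counts: dict[str, int] = {}

    def build(node: SystemExpr):
        nonlocal offset
        if isinstance(node, (Instance, Replication)):
            count = node.copies if isinstance(node, Replication) else 1
            locals_ = tuple(derivative_set(model, node.name))
            index = {n: i for i, n in enumerate(locals_)}
            local_moves = []
            for local in locals_:
                moves = [
                    (aid_of(act.action), act.rate, index[target])
                    for act, target in enabled_transitions(model, local)
                ]
                local_moves.append(moves)
            name = node.name
            if name in name_counts:
                name_counts[name] += 1
                name = f"{name}#{name_counts[node.name]}"
            else:
                name_counts[name] = 1
            info = GroupInfo(name, count, locals_, offset)
            offset += count
            groups.append(info)
            return _GroupNode(info, local_moves)
        left = build(node.left)
        right = build(node.right)
        return _CoopNode(left, right, {aid_of(a) for a in node.sync}, actions)

    root = build(model.system)
    return root, groups, actions


# ---------------------------------------------------------------------------
# State-space exploration
# ---------------------------------------------------------------------------


def explore_state_space(
    model: CPPModel, max_states: int = 2_000_000
) -> TransitionSystem:
    """Breadth-first closure of the global state space.

    States are indexed in deterministic BFS order with lexicographic
    tie-breaking among the successors of each state, so matrices and
    reports are reproducible run to run.  Exceeding ``max_states``
    raises :class:`StateSpaceError` rather than truncating silently.
    """
    root, groups, actions = compile_engine(model)
    initial = tuple(0 for g in groups for _ in range(g.count))
    index = {initial: 0}
    states = [initial]
    src, tgt, act, rate = [], [], [], []
    frontier = [initial]
    while frontier:
        next_frontier = []
        for state in frontier:
            si = index[state]
            moves = root.moves(state)
            successors = []
            for aid in moves:
                for r, updates in moves[aid][1]:
                    new = list(state)
                    for leaf, value in updates:
                        new[leaf] = value
                    successors.append((tuple(new), aid, r))
            successors.sort(key=lambda item: (item[0], item[1]))
            for new_state, aid, r in successors:
                ti = index.get(new_state)
                if ti is None:
                    ti = len(states)
                    if ti >= max_states:
                        raise StateSpaceError(
                            f"state budget of {max_states} states exceeded"
                        )
                    index[new_state] = ti
                    states.append(new_state)
                    next_frontier.append(new_state)
                src.append(si)
                tgt.append(ti)
                act.append(aid)
                rate.append(r)
        frontier = next_frontier
    logger.info("explored %d states, %d transitions", len(states), len(src))
    return TransitionSystem(
        states=states,
        transitions_src=np.asarray(src, dtype=np.int64),
        transitions_tgt=np.asarray(tgt, dtype=np.int64),
        transitions_action=np.asarray(act, dtype=np.int32),
        transitions_rate=np.asarray(rate, dtype=float),
        actions=actions,
        groups=groups,
        metadata=dict(model.metadata),
    )


# ---------------------------------------------------------------------------
# Generator matrix and steady state
# ---------------------------------------------------------------------------


@dataclass
class GeneratorMatrix:
    """Infinitesimal generator Q (sparse, 1/day); rows sum to zero."""

    Q: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def to_dense(self) -> np.ndarray:
        return self.Q.toarray()

    def to_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), sp.coo_matrix(self.Q))


@dataclass
class SteadyState:
    """Equilibrium distribution pi over the states of a transition system."""

    pi: np.ndarray
    residual: float

    def __getitem__(self, i):
        return self.pi[i]


def build_generator(ts: TransitionSystem) -> GeneratorMatrix:
    """Assemble Q: off-diagonal (i, j) sums the rates of every i->j
    transition; the diagonal is the negative row sum."""
    n = ts.n_states
    Q = sp.coo_matrix(
        (ts.transitions_rate, (ts.transitions_src, ts.transitions_tgt)), shape=(n, n)
    ).tocsr()
    Q.sum_duplicates()
    diag = -np.asarray(Q.sum(axis=1)).ravel()
    Q = Q + sp.diags(diag)
    return GeneratorMatrix(Q.tocsr())


def _check_irreducible(Q: sp.csr_matrix) -> None:
    off = Q.copy()
    off.setdiag(0)
    n_comp, labels = csgraph.connected_components(off, directed=True, connection="strong")
    if n_comp > 1:
        members: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            members.setdefault(int(lab), []).append(i)
        detail = "; ".join(
            f"component {lab}: states {m[:5]}{'...' if len(m) > 5 else ''}"
            for lab, m in sorted(members.items())
        )
        raise ReducibleChainError(
            f"chain is reducible ({n_comp} strongly connected components): {detail}",
            components=list(members.values()),
        )


def solve_steady_state(
    Q: GeneratorMatrix | sp.spmatrix | np.ndarray, tol: float = 1e-10
) -> SteadyState:
    """Solve the global balance equations pi Q = 0 with sum(pi) = 1.

    The chain must be irreducible (checked by strongly-connected-component
    analysis).  One balance equation is replaced by the normalisation
    condition and the resulting square sparse system is solved directly;
    dense least squares is used as a fallback for ill-conditioned cases.
    """
    if isinstance(Q, GeneratorMatrix):
        Qm = Q.Q
    else:
        Qm = sp.csr_matrix(Q)
    n = Qm.shape[0]
    if n == 1:
        return SteadyState(np.array([1.0]), 0.0)
    _check_irreducible(Qm)
    A = Qm.T.tolil()
    A[n - 1, :] = 1.0
    b = np.zeros(n)
    b[n - 1] = 1.0
    try:
        pi = spla.spsolve(A.tocsr(), b)
    except Exception:  # pragma: no cover - rare numerical fallback
        pi = None
    if pi is None or not np.all(np.isfinite(pi)):
        dense = np.vstack([Qm.T.toarray(), np.ones(n)])
        rhs = np.zeros(n + 1)
        rhs[-1] = 1.0
        pi, *_ = np.linalg.lstsq(dense, rhs, rcond=None)
    pi = np.where(np.abs(pi) < 1e-14, 0.0, pi)
    if pi.min() < -1e-9:
        raise ReducibleChainError("steady-state solve produced negative probabilities")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = float(np.abs(pi @ Qm).max())
    if residual > tol:
        raise ReducibleChainError(
            f"steady-state residual {residual:.2e} exceeds tolerance {tol:.0e}"
        )
    return SteadyState(pi, residual)


# ---------------------------------------------------------------------------
# Counting-abstraction aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregatedSystem:
    """Lumped chain over classes of replica-symmetric global states."""

    ts: TransitionSystem  # the underlying full system
    class_keys: list  # class id -> per-group count-vector tuple
    class_of_state: np.ndarray  # full state id -> class id
    member_counts: np.ndarray
    lumped: TransitionSystem  # classes as states

    @property
    def n_classes(self) -> int:
        return len(self.class_keys)

    def project(self, pi_full: np.ndarray) -> np.ndarray:
        """Sum a full-chain distribution over classes."""
        out = np.zeros(self.n_classes)
        np.add.at(out, self.class_of_state, pi_full)
        return out


def aggregate(
    ts: TransitionSystem,
    replica_groups: Optional[Sequence[str]] = None,
    check_lumpability: bool = True,
    rtol: float = 1e-9,
) -> AggregatedSystem:
    """Merge global states with identical per-group local-state counts.

    ``replica_groups`` names the groups to abstract by counting (default:
    all).  The lumped rate from a class is read off any one member;
    lumpability (equal class-outflow vectors for every member) is
    asserted unless ``check_lumpability`` is disabled.
    """
    if replica_groups is None:
        group_set = {g.name for g in ts.groups}
    else:
        group_set = set(replica_groups)
        known = {g.name for g in ts.groups}
        unknown = group_set - known
        if unknown:
            raise KeyError(f"unknown replica groups: {sorted(unknown)}")

    keys = []
    class_index: dict[tuple, int] = {}
    class_of_state = np.empty(ts.n_states, dtype=np.int64)
    for i in range(ts.n_states):
        s = ts.states[i]
        key_parts = []
        for g in ts.groups:
            part = s[g.slice]
            if g.name in group_set:
                counts = [0] * len(g.local_states)
                for v in part:
                    counts[v] += 1
                key_parts.append(tuple(counts))
            else:
                key_parts.append(tuple(part))
        key = tuple(key_parts)
        ci = class_index.get(key)
        if ci is None:
            ci = len(keys)
            class_index[key] = ci
            keys.append(key)
        class_of_state[i] = ci

    member_counts = np.bincount(class_of_state, minlength=len(keys))

    # per-state outflow vectors into classes
    n_classes = len(keys)
    tgt_class = class_of_state[ts.transitions_tgt]
    flat = ts.transitions_src * n_classes + tgt_class
    # lumped rates from the first member of each class
    reps = np.zeros(n_classes, dtype=np.int64)
    seen = np.zeros(n_classes, dtype=bool)
    for i in range(ts.n_states):
        ci = class_of_state[i]
        if not seen[ci]:
            seen[ci] = True
            reps[ci] = i

    if check_lumpability:
        import collections

        outflow: dict[int, dict[int, float]] = collections.defaultdict(dict)
        for s, fc, r in zip(ts.transitions_src, tgt_class, ts.transitions_rate):
            d = outflow[int(s)]
            d[int(fc)] = d.get(int(fc), 0.0) + float(r)
        for ci in range(n_classes):
            ref = outflow.get(int(reps[ci]), {})
            for member in np.nonzero(class_of_state == ci)[0]:
                got = outflow.get(int(member), {})
                if set(got) != set(ref) or any(
                    abs(got[k] - ref[k]) > rtol * max(1.0, abs(ref[k])) for k in ref
                ):
                    raise ModelSemanticsError(
                        f"lumpability violated in class {ci}: state {member} "
                        f"disagrees with representative {reps[ci]}"
                    )

    # build lumped transitions from representatives, keeping actions distinct
    rep_set = set(int(r) for r in reps)
    lsrc, ltgt, lact, lrate = [], [], [], []
    agg_rates: dict[tuple, float] = {}
    for s, t, a, r in zip(
        ts.transitions_src, ts.transitions_tgt, ts.transitions_action, ts.transitions_rate
    ):
        s = int(s)
        if s in rep_set:
            key = (int(class_of_state[s]), int(class_of_state[t]), int(a))
            agg_rates[key] = agg_rates.get(key, 0.0) + float(r)
    for (cs, ct, a), r in sorted(agg_rates.items()):
        lsrc.append(cs)
        ltgt.append(ct)
        lact.append(a)
        lrate.append(r)

    lumped = TransitionSystem(
        states=[keys[i] for i in range(n_classes)],
        transitions_src=np.asarray(lsrc, dtype=np.int64),
        transitions_tgt=np.asarray(ltgt, dtype=np.int64),
        transitions_action=np.asarray(lact, dtype=np.int32),
        transitions_rate=np.asarray(lrate, dtype=float),
        actions=ts.actions,
        groups=ts.groups,
        initial=int(class_of_state[ts.initial]),
        metadata=dict(ts.metadata, aggregated=True, abstracted_groups=sorted(group_set)),
    )
    logger.info("aggregated %d states into %d classes", ts.n_states, n_classes)
    return AggregatedSystem(ts, keys, class_of_state, member_counts, lumped)


# ---------------------------------------------------------------------------
# Stochastic simulation (validation oracle)
# ---------------------------------------------------------------------------


def _rate_table(ts: TransitionSystem):
    order = np.argsort(ts.transitions_src, kind="stable")
    src = ts.transitions_src[order]
    starts = np.searchsorted(src, np.arange(ts.n_states + 1))
    return order, starts


def sample_occupancy(
    ts: TransitionSystem, n_events: int, rng: np.random.Generator
) -> np.ndarray:
    """Fraction of time spent in each state along one jump path."""
    order, starts = _rate_table(ts)
    tgt = ts.transitions_tgt[order]
    rate = ts.transitions_rate[order]
    time_in = np.zeros(ts.n_states)
    state = ts.initial
    for _ in range(n_events):
        lo, hi = starts[state], starts[state + 1]
        local_rates = rate[lo:hi]
        total = local_rates.sum()
        time_in[state] += rng.exponential(1.0 / total)
        choice = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(local_rates), choice))
        state = int(tgt[lo + min(idx, hi - lo - 1)])
    return time_in / time_in.sum()


def sample_counts(
    ts: TransitionSystem,
    checkpoints: Sequence[float],
    n_paths: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo mean per-group local-state counts at given times.

    Returns an array of shape (len(checkpoints), n_vars) where variables
    are ordered (group, local_state) as in the fluid engine.
    """
    order, starts = _rate_table(ts)
    tgt = ts.transitions_tgt[order]
    rate = ts.transitions_rate[order]
    n_vars = sum(len(g.local_states) for g in ts.groups)
    var_offset = []
    acc = 0
    for g in ts.groups:
        var_offset.append(acc)
        acc += len(g.local_states)

    def counts_of(state_idx):
        s = ts.states[state_idx]
        v = np.zeros(n_vars)
        for gi, g in enumerate(ts.groups):
            for val in s[g.slice]:
                v[var_offset[gi] + val] += 1
        return v

    checkpoints = np.asarray(checkpoints, dtype=float)
    means = np.zeros((len(checkpoints), n_vars))
    for _ in range(n_paths):
        state = ts.initial
        t = 0.0
        ci = 0
        while ci < len(checkpoints):
            lo, hi = starts[state], starts[state + 1]
            local_rates = rate[lo:hi]
            total = local_rates.sum()
            dwell = rng.exponential(1.0 / total) if total > 0 else np.inf
            while ci < len(checkpoints) and t + dwell > checkpoints[ci]:
                means[ci] += counts_of(state)
                ci += 1
            if not np.isfinite(dwell):
                break
            t += dwell
            choice = rng.random() * total
            idx = int(np.searchsorted(np.cumsum(local_rates), choice))
            state = int(tgt[lo + min(idx, hi - lo - 1)])
    return means / n_paths
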