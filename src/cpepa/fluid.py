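"""Mean-field fluid approximation: count ODEs, fixed points, passage-time probes.

Each replica group's local states become continuous count variables
N(P_i)(t).  The drift of a count is the signed sum of action fluxes:
a shared action's flux is its rate times the minimum of the apparent
counts of the participating groups (the fluid image of the
minimum-apparent-rate cooperation rule), a private action's flux is
rate times count.  Group totals are conserved exactly along any
trajectory.

Passage times are estimated with a stochastic probe: a two-state
observer (NotFinished -> Finished on the trigger action, Finished
absorbing) composed in product with the observed patient component.
The fraction of probed patients in a Finished-tagged state over time
approximates the passage-time CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    Activity,
    ComponentDef,
    ConstantRef,
    Choice,
    CPPModel,
    Cooperation,
    Instance,
    ModelSemanticsError,
    Prefix,
    Replication,
    SystemExpr,
    derivative_set,
    enabled_transitions,
)

logger = logging.getLogger("cpepa")

__all__ = [
    "ODESystem",
    "Trajectories",
    "PassageCDF",
    "derive_odes",
    "integrate",
    "fluid_steady_state",
    "attach_probe",
    "passage_time_cdf",
    "FluidSteadyState",
]

PROBE_NOT_FINISHED = "NotFinished"
PROBE_FINISHED = "Finished"
_PROBE_SEP = "__"


# ---------------------------------------------------------------------------
# ODE derivation
# ---------------------------------------------------------------------------


@dataclass
class _FluidGroup:
    name: str
    component: str
    copies: int
    local_states: tuple
    var_offset: int
    # action id -> list of (local id, rate, target local id)
    transitions: dict

    def apparent(self, aid: int, y: np.ndarray) -> float:
        total = 0.0
        for s, r, _t in self.transitions.get(aid, ()):
            total += r * y[self.var_offset + s]
        return total


class _FluidNode:
    __slots__ = ("group", "left", "right", "sync", "alphabet")

    def __init__(self, group=None, left=None, right=None, sync=frozenset()):
        self.group = group
        self.left = left
        self.right = right
        self.sync = sync
        if group is not None:
            self.alphabet = set(group.transitions)
        else:
            self.alphabet = left.alphabet | right.alphabet

    def apparent(self, aid, y):
        if self.group is not None:
            return self.group.apparent(aid, y)
        in_left = aid in self.left.alphabet
        in_right = aid in self.right.alphabet
        if aid in self.sync:
            if not (in_left and in_right):
                return 0.0
            return min(self.left.apparent(aid, y), self.right.apparent(aid, y))
        total = 0.0
        if in_left:
            total += self.left.apparent(aid, y)
        if in_right:
            total += self.right.apparent(aid, y)
        return total

    def distribute(self, aid, flux, y, dydt):
        """Top-down allocation of realised action flux to state changes."""
        if flux <= 0.0:
            return
        if self.group is not None:
            g = self.group
            apparent = g.apparent(aid, y)
            if apparent <= 0.0:
                return
            for s, r, t in g.transitions.get(aid, ()):
                share = flux * (r * y[g.var_offset + s]) / apparent
                dydt[g.var_offset + s] -= share
                dydt[g.var_offset + t] += share
            return
        in_left = aid in self.left.alphabet
        in_right = aid in self.right.alphabet
        if aid in self.sync:
            # both sides realise the full synchronised flux
            self.left.distribute(aid, flux, y, dydt)
            self.right.distribute(aid, flux, y, dydt)
            return
        if in_left and in_right:
            la = self.left.apparent(aid, y)
            ra = self.right.apparent(aid, y)
            total = la + ra
            if total <= 0.0:
                return
            self.left.distribute(aid, flux * la / total, y, dydt)
            self.right.distribute(aid, flux * ra / total, y, dydt)
        elif in_left:
            self.left.distribute(aid, flux, y, dydt)
        elif in_right:
            self.right.distribute(aid, flux, y, dydt)


@dataclass
class ODESystem:
    """Fluid count ODEs dN/dt = f(N) for a closed pathway model."""

    model: CPPModel
    var_names: list
    y0: np.ndarray
    groups: list  # list[_FluidGroup]
    actions: list
    _root: _FluidNode

    _compiled: Optional[Callable] = None

    def __post_init__(self):
        plan = _build_fast_plan(self._root, len(self.actions))
        if plan is not None:
            self._compiled = _codegen_rhs(plan, len(self.var_names))

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def var_index(self, name: str) -> int:
        return self.var_names.index(name)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if self._compiled is not None:
            return np.asarray(self._compiled(t, y))
        return self.rhs_reference(t, y)

    def rhs_reference(self, t: float, y: np.ndarray) -> np.ndarray:
        """Drift evaluated by direct recursion over the cooperation tree.

        Semantically identical to the compiled fast path; kept as the
        reference implementation and as the fallback for models whose
        shared labels do not all synchronise.
        """
        dydt = np.zeros_like(y)
        for aid in range(len(self.actions)):
            flux = self._root.apparent(aid, y)
            if flux > 0.0:
                self._root.distribute(aid, flux, y, dydt)
        return dydt

    def group_totals(self) -> list:
        return [
            (g.name, float(self.y0[g.var_offset : g.var_offset + len(g.local_states)].sum()))
            for g in self.groups
        ]

    def action_flux(self, action: str, y: np.ndarray) -> float:
        return self._root.apparent(self.actions.index(action), y)

    def equations_text(self) -> str:
        """Render the drift equations in min-of-counts form.

        Requires every action to carry a single rate per participating
        group (true for all pathway-built models); raises otherwise.
        """
        # per action: rate and the min() argument list of enabling variables
        flux_repr: dict[int, tuple[float, list]] = {}
        for aid, label in enumerate(self.actions):
            participants = _min_participants(self._root, aid)
            if participants is None:
                raise ModelSemanticsError(
                    f"action {label!r} has no single-rate min() form"
                )
            rate, varlists = participants
            flux_repr[aid] = (rate, varlists)
        lines = []
        for gi, g in enumerate(self.groups):
            for s, name in enumerate(g.local_states):
                terms = []
                for aid in range(len(self.actions)):
                    if aid not in flux_repr:
                        continue
                    rate, varlists = flux_repr[aid]
                    for ls, _r, lt in g.transitions.get(aid, ()):
                        if ls == s:
                            terms.append((-rate, varlists))
                        if lt == s:
                            terms.append((+rate, varlists))
                if not terms:
                    continue
                rendered = []
                for coef, varlists in terms:
                    if len(varlists) == 1:
                        body = f"N({varlists[0]})"
                    else:
                        body = "min(" + ",".join(f"N({v})" for v in varlists) + ")"
                    sign = "-" if coef < 0 else "+"
                    rendered.append(f"{sign}{abs(coef):g}*{body}")
                lines.append(f"N({name})' = " + " ".join(rendered))
        return "\n".join(lines)


def _build_fast_plan(root: _FluidNode, n_actions: int):
    """Vectorised evaluation plan when every shared label synchronises.

    For each action, collect one block per participating group
    (source-variable indices, rates, target indices); the action's flux
    is then the minimum of the blocks' apparent rates, realised in full
    by every block and split within a block proportionally to r*N.
    Returns None when any cooperation node interleaves a label present
    on both sides, in which case the generic tree recursion is used.
    """
    plan = []
    for aid in range(n_actions):
        blocks: list = []

        def collect(node: _FluidNode) -> bool:
            if node.group is not None:
                trans = node.group.transitions.get(aid)
                if trans:
                    off = node.group.var_offset
                    src = np.array([off + s for s, _r, _t in trans], dtype=np.intp)
                    rates = np.array([r for _s, r, _t in trans], dtype=float)
                    tgt = np.array([off + t for _s, _r, t in trans], dtype=np.intp)
                    blocks.append((src, rates, tgt))
                return True
            in_left = aid in node.left.alphabet
            in_right = aid in node.right.alphabet
            if in_left and in_right and aid not in node.sync:
                return False
            if in_left and not collect(node.left):
                return False
            if in_right and not collect(node.right):
                return False
            return True

        if not collect(root):
            return None
        plan.append(blocks)
    return [b for b in plan if b]


def _codegen_rhs(plan, n_vars: int):
    """Compile the evaluation plan into a straight-line Python function.

    The fluid drift is evaluated hundreds of thousands of times per
    stiff integration; a generated function with scalar arithmetic is
    an order of magnitude faster than recursing over the tree.
    """
    lines = ["def _rhs(t, y):"]
    if n_vars:
        unpack = ", ".join(f"y{i}" for i in range(n_vars))
        source = ", ".join(f"y[{i}]" for i in range(n_vars))
        lines.append(f"    {unpack} = {source}" if n_vars > 1 else f"    {unpack}, = y")
    terms: list[list[str]] = [[] for _ in range(n_vars)]
    for k, blocks in enumerate(plan):
        apps = []
        for j, (src, rates, _tgt) in enumerate(blocks):
            expr = " + ".join(f"{float(r)!r}*y{s}" for s, r in zip(src, rates))
            lines.append(f"    a{k}_{j} = {expr}")
            apps.append(f"a{k}_{j}")
        body = apps[0] if len(apps) == 1 else f"min({', '.join(apps)})"
        lines.append(f"    f{k} = {body}")
        lines.append(f"    if f{k} < 0.0: f{k} = 0.0")
        for j, (src, rates, tgt) in enumerate(blocks):
            if len(src) == 1:
                terms[src[0]].append(f"- f{k}")
                terms[tgt[0]].append(f"+ f{k}")
            else:
                lines.append(
                    f"    w{k}_{j} = f{k}/a{k}_{j} if a{k}_{j} > 0.0 else 0.0"
                )
                for s, r, tg in zip(src, rates, tgt):
                    lines.append(f"    s{k}_{j}_{s} = w{k}_{j}*{float(r)!r}*y{s}")
                    terms[s].append(f"- s{k}_{j}_{s}")
                    terms[tg].append(f"+ s{k}_{j}_{s}")
    out = ", ".join(" ".join(t) if t else "0.0" for t in terms)
    lines.append(f"    return ({out},)" if n_vars == 1 else f"    return ({out})")
    namespace: dict = {}
    exec("\n".join(lines), namespace)
    return namespace["_rhs"]


def _min_participants(node: _FluidNode, aid: int):
    """Rate and per-group enabling variables when the flux is rate*min(...)."""
    if node.group is not None:
        trans = node.group.transitions.get(aid)
        if not trans:
            return None
        rates = {r for _s, r, _t in trans}
        if len(rates) != 1:
            return None
        states = [node.group.local_states[s] for s, _r, _t in trans]
        if len(states) == 1:
            return rates.pop(), [states[0]]
        return None  # several enabling states: not a single-variable form
    in_left = aid in node.left.alphabet
    in_right = aid in node.right.alphabet
    if aid in node.sync and in_left and in_right:
        left = _min_participants(node.left, aid)
        right = _min_participants(node.right, aid)
        if left is None or right is None or abs(left[0] - right[0]) > 1e-12:
            return None
        return left[0], left[1] + right[1]
    if in_left and not in_right:
        return _min_participants(node.left, aid)
    if in_right and not in_left:
        return _min_participants(node.right, aid)
    return None


def derive_odes(model: CPPModel, initial_counts: Optional[dict] = None) -> ODESystem:
    """Build the fluid ODE system of a model.

    Initial counts place every instance of a group in its initial local
    state (the replication count), unless overridden per variable via
    ``initial_counts`` (mapping local-state name -> count).
    """
    actions: list[str] = []
    action_ids: dict[str, int] = {}

    def aid_of(label):
        if label not in action_ids:
            action_ids[label] = len(actions)
            actions.append(label)
        return action_ids[label]

    groups: list[_FluidGroup] = []
    var_names: list[str] = []
    name_counts: dict[str, int] = {}

    def build(node: SystemExpr) -> _FluidNode:
        if isinstance(node, (Instance, Replication)):
            copies = node.copies if isinstance(node, Replication) else 1
            locals_ = tuple(derivative_set(model, node.name))
            index = {n: i for i, n in enumerate(locals_)}
            transitions: dict[int, list] = {}
            for local in locals_:
                for act, target in enabled_transitions(model, local):
                    transitions.setdefault(aid_of(act.action), []).append(
                        (index[local], act.rate, index[target])
                    )
            name = node.name
            if name in name_counts:
                name_counts[node.name] += 1
                name = f"{name}#{name_counts[node.name]}"
            else:
                name_counts[name] = 1
            g = _FluidGroup(name, node.name, copies, locals_, len(var_names), transitions)
            groups.append(g)
            var_names.extend(locals_ if name == node.name else [f"{name}:{s}" for s in locals_])
            return _FluidNode(group=g)
        left = build(node.left)
        right = build(node.right)
        return _FluidNode(left=left, right=right, sync=frozenset(aid_of(a) for a in node.sync))

    root = build(model.system)
    y0 = np.zeros(len(var_names))
    for g in groups:
        y0[g.var_offset] = g.copies
    if initial_counts:
        for name, value in initial_counts.items():
            idx = var_names.index(name)
            y0[idx] = float(value)
    return ODESystem(model, var_names, y0, groups, actions, root)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


@dataclass
class Trajectories:
    """Dense fluid trajectories on a user grid."""

    t: np.ndarray
    y: np.ndarray  # shape (n_vars, len(t))
    var_names: list
    odes: ODESystem

    def series(self, name: str) -> np.ndarray:
        return self.y[self.var_names.index(name)]

    def conservation_error(self) -> float:
        worst = 0.0
        for g in self.odes.groups:
            block = self.y[g.var_offset : g.var_offset + len(g.local_states)]
            worst = max(worst, float(np.abs(block.sum(axis=0) - g.copies).max()))
        return worst

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(dict({"time": self.t}, **{n: self.y[i] for i, n in enumerate(self.var_names)}))


def integrate(
    odes: ODESystem,
    horizon: float,
    grid: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectories:
    """Integrate the fluid ODEs with a stiff-capable solver.

    The models mix rates from 0.004 to 1000 per day, so a stiff method
    is the default.  Raises with the solver diagnostics on failure.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t_eval = np.asarray(grid, dtype=float) if grid is not None else None
    sol = solve_ivp(
        odes.rhs,
        (0.0, float(horizon)),
        odes.y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=t_eval is None,
    )
    if not sol.success:
        raise RuntimeError(f"fluid integration failed: {sol.message}")
    return Trajectories(sol.t, sol.y, list(odes.var_names), odes)


@dataclass
class FluidSteadyState:
    counts: np.ndarray
    converged: bool
    residual: float
    t_final: float
    odes: ODESystem

    def __getitem__(self, name: str) -> float:
        return float(self.counts[self.odes.var_index(name)])


def fluid_steady_state(
    odes: ODESystem,
    tol: float = 1e-8,
    horizon_cap: float = 50_000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FluidSteadyState:
    """Find the fluid fixed point: integrate, then Newton-polish.

    Windows of increasing length are integrated until the drift
    vanishes (max |dN/dt| < tol); after every window a Newton solve of
    the balance equations (with one equation per replica group replaced
    by its conservation constraint) is attempted from the current
    point, which cuts through the slow final transient of saturated
    configurations.  A polished root is accepted only if it is
    nonnegative and its true drift is below ``tol``.  Non-convergence
    is reported through the ``converged`` flag rather than an
    exception, so sweeps can proceed and flag the offending grid
    points.
    """
    group_rows = [
        (g.var_offset, len(g.local_states),
         float(odes.y0[g.var_offset : g.var_offset + len(g.local_states)].sum()))
        for g in odes.groups
    ]
    n = odes.n_vars

    def balance(z):
        f = np.array(odes.rhs(0.0, z), dtype=float)
        for off, m, total in group_rows:
            f[off] = z[off : off + m].sum() - total
        return f

    def jacobian(fun, z, f):
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(1.0, abs(z[j]))
            zp = z.copy()
            zp[j] += h
            J[:, j] = (fun(zp) - f) / h
        return J

    def try_polish(y):
        # damped least-squares Newton on the balance system; the drift is
        # piecewise linear, so each step solves one linear piece exactly
        z = np.clip(y, 0.0, None)
        for _ in range(60):
            f = balance(z)
            nf = float(np.abs(f).max())
            if nf < tol * 1e-1:
                break
            step, *_ = np.linalg.lstsq(jacobian(balance, z, f), -f, rcond=None)
            lam = 1.0
            while lam > 1e-6:
                zn = np.clip(z + lam * step, 0.0, None)
                if np.abs(balance(zn)).max() < nf * (1 - 1e-4 * lam):
                    break
                lam *= 0.5
            z = np.clip(z + lam * step, 0.0, None)
        residual = float(np.abs(odes.rhs(0.0, z)).max())
        if not (residual < tol and np.abs(balance(z)).max() < 1e-6):
            return None
        # reject dynamically unstable roots (spurious boundary fixed
        # points the trajectory would never reach)
        drift = lambda w: np.array(odes.rhs(0.0, w), dtype=float)
        eigs = np.linalg.eigvals(jacobian(drift, z, drift(z)))
        if eigs.real.max() > 1e-6:
            return None
        return z, residual

    y = odes.y0.copy()
    t = 0.0
    window = 50.0
    while t < horizon_cap:
        t_end = min(t + window, horizon_cap)
        sol = solve_ivp(
            odes.rhs, (t, t_end), y, method="LSODA", rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"fluid integration failed: {sol.message}")
        y = sol.y[:, -1]
        t = t_end
        residual = float(np.abs(odes.rhs(t, y)).max())
        if residual < tol:
            return FluidSteadyState(y, True, residual, t, odes)
        polished = try_polish(y)
        if polished is not None:
            return FluidSteadyState(polished[0], True, polished[1], t, odes)
        window = min(window * 2, 10_000.0)
    residual = float(np.abs(odes.rhs(t, y)).max())
    logger.warning("fluid fixed point not reached by t=%g (residual %.2e)", t, residual)
    return FluidSteadyState(y, False, residual, t, odes)


# ---------------------------------------------------------------------------
# Stochastic probes and passage time
# ---------------------------------------------------------------------------


def probed_name(local: str, probe_state: str) -> str:
    return f"{local}{_PROBE_SEP}{probe_state}"


def attach_probe(model: CPPModel, start: str, trigger: str) -> CPPModel:
    """Compose a NotFinished/Finished observer with the ``start`` component.

    The probe synchronises on ``trigger`` at the trigger's own rate, so
    the product component has exactly the dynamics of the original one;
    the probe state flips to Finished on the first trigger completion
    and is absorbing thereafter.  Returns a new model whose system
    expression replaces the ``start`` group by the probed component.
    """
    if start not in model.definitions:
        raise ModelSemanticsError(f"unknown component {start!r}")
    derivatives = derivative_set(model, start)
    reachable_actions = {
        act.action for d in derivatives for act, _ in enabled_transitions(model, d)
    }
    if trigger not in reachable_actions:
        raise ModelSemanticsError(
            f"trigger action {trigger!r} is not reachable from {start!r}"
        )

    new_defs = dict(model.definitions)
    for d in derivatives:
        for probe_state in (PROBE_NOT_FINISHED, PROBE_FINISHED):
            terms = []
            for act, target in enabled_transitions(model, d):
                next_probe = (
                    PROBE_FINISHED if act.action == trigger else probe_state
                )
                terms.append(
                    Prefix(act, ConstantRef(probed_name(target, next_probe)))
                )
            body = terms[0]
            for term in terms[1:]:
                body = Choice(body, term)
            name = probed_name(d, probe_state)
            new_defs[name] = ComponentDef(name, body, model.definitions[d].kind)

    start_probed = probed_name(start, PROBE_NOT_FINISHED)

    def rewrite(node: SystemExpr) -> SystemExpr:
        if isinstance(node, Instance):
            return Instance(start_probed) if node.name == start else node
        if isinstance(node, Replication):
            if node.name == start:
                return Replication(start_probed, node.copies)
            return node
        return Cooperation(rewrite(node.left), rewrite(node.right), node.sync)

    new_system = rewrite(model.system)
    metadata = dict(model.metadata)
    metadata["probe"] = {
        "start": start,
        "trigger": trigger,
        "finished_suffix": _PROBE_SEP + PROBE_FINISHED,
        "group_component": start_probed,
    }
    probed = CPPModel(new_defs, new_system, dict(model.rate_constants), metadata)
    probed.validate()
    return probed


@dataclass
class PassageCDF:
    """Cumulative passage-time distribution on a time grid (days)."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_days": self.times, "cdf": self.values})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def passage_time_cdf(
    probed: CPPModel,
    grid: Sequence[float],
    initial_counts: Optional[dict] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PassageCDF:
    """Finished-fraction fluid CDF of the probed model.

    CDF(t) = (count of probed patients in Finished-tagged states at t)
    divided by the probed population.  The grid must start at or after 0;
    monotonicity is enforced up to integration tolerance.
    """
    probe = probed.metadata.get("probe")
    if probe is None:
        raise ModelSemanticsError("model has no probe; call attach_probe first")
    grid = np.asarray(sorted(grid), dtype=float)
    if grid[0] < 0:
        raise ValueError("time grid must be nonnegative")
    odes = derive_odes(probed, initial_counts=initial_counts)
    suffix = probe["finished_suffix"]
    probed_group = None
    for g in odes.groups:
        if g.component == probe["group_component"]:
            probed_group = g
            break
    if probed_group is None:
        raise ModelSemanticsError("probed component missing from the system")
    total = float(
        odes.y0[probed_group.var_offset : probed_group.var_offset + len(probed_group.local_states)].sum()
    )
    finished_idx = [
        probed_group.var_offset + i
        for i, s in enumerate(probed_group.local_states)
        if s.endswith(suffix)
    ]
    eval_grid = grid if grid[0] == 0.0 else np.concatenate([[0.0], grid])
    traj = integrate(odes, float(eval_grid[-1]) if eval_grid[-1] > 0 else 1e-6,
                     grid=eval_grid, rtol=rtol, atol=atol)
    finished = traj.y[finished_idx].sum(axis=0) / total
    if grid[0] != 0.0:
        finished = finished[1:]
    values = np.minimum(np.maximum.accumulate(np.clip(finished, 0.0, 1.0)), 1.0)
    return PassageCDF(grid, values)
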