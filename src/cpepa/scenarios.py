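"""The three stroke-pathway analysis scenarios plus the fixture generator.

Scenario 1 sweeps resource allocations and reports the throughput grid
and the minimal allocation attaining the maximum.  Scenario 2 estimates
the passage-time distribution from treatment entry to discharge with a
stochastic probe on a single tagged patient.  Scenario 3 raises the
admission rate and traces the saturation of throughput against the
capacity bound of the final resource.

Small models are solved exactly on the aggregated Markov chain; large
ones fall back to the fluid approximation.  The choice is logged.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import ctmc, performance
from .fluid import (
    PROBE_NOT_FINISHED,
    PassageCDF,
    attach_probe,
    derive_odes,
    fluid_steady_state,
    passage_time_cdf,
    probed_name,
)
from .model import CPPModel, ModelSemanticsError, Replication, derivative_set, system_leaves
from .pathway import DepartmentSpec, PathwayConfig, build_model

logger = logging.getLogger("cpepa")

__all__ = [
    "SweepResult",
    "SaturationCurve",
    "scenario_resource_sweep",
    "scenario_passage_time",
    "scenario_max_input",
    "generate_fixture",
    "solve_throughput",
    "serialize_config",
]

#: exact aggregated-chain solve is attempted below this full-state bound
EXACT_STATE_LIMIT = 200_000


# ---------------------------------------------------------------------------
# Throughput of one configuration
# ---------------------------------------------------------------------------


def _state_space_bound(model: CPPModel) -> float:
    """Cheap upper bound on the full state count: prod |locals|^copies."""
    bound = 1.0
    for leaf in system_leaves(model.system):
        copies = leaf.copies if isinstance(leaf, Replication) else 1
        n_local = len(derivative_set(model, leaf.name))
        if copies * math.log(max(n_local, 1)) > math.log(1e30):
            return math.inf
        bound *= float(n_local) ** copies
        if bound > 1e30:
            return math.inf
    return bound


def _discharge_throughput_ctmc(model: CPPModel) -> float:
    ts = ctmc.explore_state_space(model, max_states=EXACT_STATE_LIMIT)
    agg = ctmc.aggregate(ts, check_lumpability=False)
    pi = ctmc.solve_steady_state(ctmc.build_generator(agg.lumped))
    meta = model.metadata
    final = meta.get("final_resource")
    if final is not None:
        return performance.throughput(
            pi, agg.lumped, meta["discharge_action"], meta["discharge_rate"], final
        )
    return performance.action_flux(pi, agg.lumped, meta["discharge_action"])


def _discharge_throughput_fluid(model: CPPModel) -> tuple[float, bool]:
    odes = derive_odes(model)
    ss = fluid_steady_state(odes)
    meta = model.metadata
    final = meta.get("final_resource")
    if final is not None:
        busy = ss[f"{final}_busy"]
        return meta["discharge_rate"] * busy, ss.converged
    return odes.action_flux(meta["discharge_action"], ss.counts), ss.converged


def solve_throughput(model: CPPModel) -> tuple[float, str, bool]:
    """Steady-state discharge throughput; returns (value, method, converged).

    Uses the exact aggregated chain when the state-space bound permits,
    the fluid fixed point otherwise; the selection is logged.
    """
    bound = _state_space_bound(model)
    if bound <= EXACT_STATE_LIMIT:
        try:
            value = _discharge_throughput_ctmc(model)
            logger.info("throughput via aggregated CTMC (bound %g states)", bound)
            return value, "ctmc", True
        except ctmc.StateSpaceError:
            logger.info("state budget exceeded; falling back to fluid")
    value, converged = _discharge_throughput_fluid(model)
    logger.info("throughput via fluid fixed point (bound %g states)", bound)
    return value, "fluid", converged


def _with_resource_counts(config: PathwayConfig, counts: dict) -> PathwayConfig:
    departments = []
    unknown = set(counts)
    for d in config.departments:
        if d.resource in counts:
            departments.append(replace(d, copies=int(counts[d.resource])))
            unknown.discard(d.resource)
        else:
            departments.append(d)
    if unknown:
        raise KeyError(f"unknown resources in sweep ranges: {sorted(unknown)}")
    return replace(config, departments=departments)


# ---------------------------------------------------------------------------
# Scenario 1: resource sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Throughput grid over resource allocations.

    ``optimal`` is the smallest allocation whose throughput lies within
    1% of the grid maximum (smallest by total resource count, then by
    the count tuple itself).
    """

    resources: list  # resource names, grid column order
    grid: "object"  # pandas DataFrame: one column per resource + throughput
    optimal: tuple
    optimal_throughput: float
    max_throughput: float
    config: PathwayConfig

    def to_csv(self, path) -> None:
        self.grid.to_csv(path, index=False)


def scenario_resource_sweep(
    config: PathwayConfig, ranges: dict[str, Sequence[int]]
) -> SweepResult:
    """Sweep resource counts and locate the minimal near-optimal allocation."""
    import pandas as pd

    if not ranges or any(len(v) == 0 for v in ranges.values()):
        raise ValueError("sweep ranges must be nonempty")
    names = list(ranges)
    rows = []
    for combo in itertools.product(*(sorted(ranges[n]) for n in names)):
        counts = dict(zip(names, combo))
        model = build_model(_with_resource_counts(config, counts))
        value, method, converged = solve_throughput(model)
        rows.append({**counts, "throughput": value, "method": method, "converged": converged})
        logger.info("sweep %s -> throughput %.4f (%s)", counts, value, method)
    grid = pd.DataFrame(rows)
    max_tp = float(grid["throughput"].max())
    near = grid[grid["throughput"] >= max_tp * (1 - 0.01)]
    ranked = sorted(
        near.itertuples(index=False),
        key=lambda r: (sum(getattr(r, n) for n in names), tuple(getattr(r, n) for n in names)),
    )
    best = ranked[0]
    optimal = tuple(int(getattr(best, n)) for n in names)
    return SweepResult(
        resources=names,
        grid=grid,
        optimal=optimal,
        optimal_throughput=float(best.throughput),
        max_throughput=max_tp,
        config=config,
    )


# ---------------------------------------------------------------------------
# Scenario 2: passage time
# ---------------------------------------------------------------------------


def scenario_passage_time(
    config: PathwayConfig, grid: Sequence[float]
) -> PassageCDF:
    """Passage-time CDF from treatment entry to discharge.

    A single tagged patient is placed at the first department with the
    full resource set idle; the probe triggers on the discharge
    activity.  With one tagged patient the resources are never
    contended, so the distribution is invariant to the resource counts
    (which the fluid model reproduces).
    """
    if not config.departments:
        raise ModelSemanticsError("passage-time scenario needs at least one department")
    tagged = replace(config, num_patients=1, num_wait_rooms=None)
    model = build_model(tagged)
    home = f"{config.patient_prefix}_{config.home_place}"
    first = f"{config.patient_prefix}_{config.departments[0].name}"
    discharge = model.metadata["discharge_action"]
    probed = attach_probe(model, home, discharge)
    initial = {
        probed_name(home, PROBE_NOT_FINISHED): 0.0,
        probed_name(first, PROBE_NOT_FINISHED): 1.0,
    }
    return passage_time_cdf(probed, grid, initial_counts=initial)


# ---------------------------------------------------------------------------
# Scenario 3: maximum input
# ---------------------------------------------------------------------------


@dataclass
class SaturationCurve:
    """Throughput as a function of the mean admission input (patients/day)."""

    inputs: np.ndarray
    throughputs: np.ndarray
    capacity_bound: Optional[float]
    config: PathwayConfig

    @property
    def max_throughput(self) -> float:
        return float(self.throughputs.max())

    def throughput_at(self, x: float) -> float:
        return float(np.interp(x, self.inputs, self.throughputs))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"input_per_day": self.inputs, "throughput": self.throughputs})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def scenario_max_input(
    config: PathwayConfig, inputs: Sequence[float]
) -> SaturationCurve:
    """Raise the mean admission input and record the saturating throughput.

    An input of x patients/day corresponds to a per-patient incidence
    of x / num_patients.  The capacity bound is the final resource's
    copies times the discharge rate.
    """
    inputs = np.asarray(sorted(inputs), dtype=float)
    if (inputs <= 0).any():
        raise ValueError("inputs must be positive")
    values = []
    for x in inputs:
        cfg = replace(config, r_income=float(x) / config.num_patients)
        model = build_model(cfg)
        value, method, _converged = solve_throughput(model)
        values.append(value)
        logger.info("input %.3f/day -> throughput %.4f (%s)", x, value, method)
    probe_model = build_model(config)
    meta = probe_model.metadata
    capacity = None
    final = meta.get("final_resource")
    if final is not None:
        copies = next(
            d.copies for d in config.departments if d.resource == final
        )
        capacity = copies * meta["discharge_rate"]
    return SaturationCurve(inputs, np.asarray(values), capacity, config)


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------


def generate_fixture(
    seed: int,
    max_departments: int = 4,
    max_patients: int = 3,
    rate_range: tuple[float, float] = (0.1, 50.0),
) -> PathwayConfig:
    """A random small pathway configuration, reproducible from the seed.

    Departments are either unconstrained or queued behind a 1-2 copy
    resource with a waiting room sized to the population, so every
    generated model is deadlock-free and its chain irreducible.
    """
    rng = np.random.default_rng(seed)
    n_depts = int(rng.integers(1, max_departments + 1))
    n_patients = int(rng.integers(1, max_patients + 1))

    def rate():
        lo, hi = rate_range
        return float(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi))), 3))

    departments = []
    for i in range(n_depts):
        if rng.random() < 0.6:
            departments.append(
                DepartmentSpec(
                    name=f"dept{i}",
                    activity=f"act{i}",
                    rate=rate(),
                    resource=f"Res{i}",
                    copies=int(rng.integers(1, 3)),
                    waiting_room=True,
                    coupling=f"wait_res{i}",
                )
            )
        else:
            departments.append(
                DepartmentSpec(name=f"dept{i}", activity=f"act{i}", rate=rate())
            )
    return PathwayConfig(
        departments=departments,
        num_patients=n_patients,
        r_income=float(np.round(rng.uniform(0.1, 5.0), 3)),
        admission_activity="admit",
        r_wait=100.0,
    )


def serialize_config(config: PathwayConfig) -> dict:
    """Plain-dict form of a configuration (stable for comparison/storage)."""
    return dataclasses.asdict(config)
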