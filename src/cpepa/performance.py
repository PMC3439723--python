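"""Resource utilisation and throughput from a steady-state distribution.

Utilisation of a resource is the steady-state expected number of busy
copies divided by the copy count; throughput is the discharge-activity
rate times the expected number of busy copies of the final resource,
which equals the steady-state probability flux of the discharge action.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .ctmc import SteadyState, TransitionSystem

logger = logging.getLogger("cpepa")

__all__ = [
    "PerformanceReport",
    "resource_utilisation",
    "expected_busy",
    "throughput",
    "action_flux",
]


def _resolve_resource(ts: TransitionSystem, resource: str):
    """Find the replica group and busy local-state id for ``resource``.

    The busy state is taken from the model metadata (``busy_states``)
    when present, else from the ``_busy`` naming convention.
    """
    busy_map = ts.metadata.get("busy_states", {})
    for g in ts.groups:
        names = set(g.local_states)
        if g.name == resource or resource in names or any(
            n in (f"{resource}_busy", f"{resource}_idle") for n in names
        ):
            busy_name = busy_map.get(resource)
            if busy_name is None:
                candidates = [n for n in g.local_states if n.endswith("_busy")]
                if len(candidates) != 1:
                    raise KeyError(
                        f"resource {resource!r} has no unambiguous busy state; "
                        "declare it in model metadata['busy_states']"
                    )
                busy_name = candidates[0]
            if busy_name not in g.local_states:
                raise KeyError(
                    f"busy state {busy_name!r} is not a derivative of {resource!r}"
                )
            return g, g.local_states.index(busy_name)
    raise KeyError(f"unknown resource {resource!r}")


def expected_busy(pi: SteadyState | np.ndarray, ts: TransitionSystem, resource: str) -> float:
    """Steady-state expected number of busy copies of ``resource``.

    Accepts both full transition systems (states are tuples of local-state
    ids) and aggregated ones (states are per-group count-vector tuples).
    """
    p = pi.pi if isinstance(pi, SteadyState) else np.asarray(pi)
    group, busy_id = _resolve_resource(ts, resource)
    gi = ts.groups.index(group)
    aggregated = ts.metadata.get("aggregated", False)
    total = 0.0
    for i, state in enumerate(ts.states):
        if p[i] == 0.0:
            continue
        if aggregated:
            part = state[gi]
            if group.name in ts.metadata.get("abstracted_groups", ()):
                busy = part[busy_id]  # class key stores the count vector
            else:
                busy = sum(1 for v in part if v == busy_id)
        else:
            busy = sum(1 for v in state[group.slice] if v == busy_id)
        total += p[i] * busy
    return total


def resource_utilisation(
    pi: SteadyState | np.ndarray, ts: TransitionSystem, resource: str
) -> float:
    """Average utilisation: expected busy copies over total copies.

    Works on both full and aggregated transition systems; aggregation
    leaves the value unchanged because class count vectors carry the
    per-class busy-copy numbers exactly.
    """
    group, _ = _resolve_resource(ts, resource)
    return expected_busy(pi, ts, resource) / group.count


def throughput(
    pi: SteadyState | np.ndarray,
    ts: TransitionSystem,
    discharge_action: str,
    discharge_rate: float,
    final_resource: str,
) -> float:
    """System throughput T = discharge rate x expected busy final-resource copies."""
    if discharge_action not in ts.actions:
        raise KeyError(f"action {discharge_action!r} not present in the model")
    return discharge_rate * expected_busy(pi, ts, final_resource)


def action_flux(pi: SteadyState | np.ndarray, ts: TransitionSystem, action: str) -> float:
    """Steady-state probability flux of ``action``: sum_i pi_i q_i(action)."""
    p = pi.pi if isinstance(pi, SteadyState) else np.asarray(pi)
    aid = ts.action_id(action)
    mask = ts.transitions_action == aid
    return float(np.sum(p[ts.transitions_src[mask]] * ts.transitions_rate[mask]))


@dataclass
class PerformanceReport:
    """Per-resource utilisations plus system throughput."""

    utilisations: dict  # resource -> fraction in [0, 1]
    throughput: float  # patients/day
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"measure": "utilisation", "resource": r, "value": u}
            for r, u in self.utilisations.items()
        ]
        rows.append({"measure": "throughput", "resource": "", "value": self.throughput})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "utilisations": self.utilisations,
            "throughput": self.throughput,
            "metadata": self.metadata,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def report(
    pi: SteadyState | np.ndarray,
    ts: TransitionSystem,
    resources: list[str],
    discharge_action: str,
    discharge_rate: float,
    final_resource: str,
    **metadata,
) -> PerformanceReport:
    utils = {r: resource_utilisation(pi, ts, r) for r in resources}
    T = throughput(pi, ts, discharge_action, discharge_rate, final_resource)
    meta = dict(metadata)
    meta.setdefault("n_states", ts.n_states)
    return PerformanceReport(utils, T, meta)
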