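"""Pathway builder: assemble closed patient/resource models from department tables.

A pathway is an ordered list of departments, each with a care activity,
a mean duration, and optionally a finite resource pool.  The builder
turns this into a process-algebra model:

* a cyclic patient component visiting one place per department and
  returning home on discharge;
* an idle/busy pair per resource pool.  A pool either follows the
  *held* pattern (seized by its department's activity and released by a
  later activity, like a stroke team that stays with the patient
  through assessment) or the *queued* pattern (an explicit waiting room
  seized by the activity delivering the patient, handing over to the
  resource through a fast coupling action ``wait_<resource>``);
* a right-nested cooperation tree whose synchronisation sets are the
  alphabet intersections of the two sides, so every shared activity is
  a constraint.

Branch probabilities (e.g. referral of stroke mimics out of the
pathway) are folded into activity rates as ``rho * r``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    Activity,
    Choice,
    ComponentDef,
    ConstantRef,
    Cooperation,
    CPPModel,
    Instance,
    ModelSemanticsError,
    Prefix,
    Replication,
    SystemExpr,
    system_alphabet,
    unparse,
)

logger = logging.getLogger("cpepa")

__all__ = [
    "DepartmentSpec",
    "ResourceSpec",
    "RoutingSpec",
    "ActivityTable",
    "PathwayConfig",
    "estimate_routing",
    "build_patient_chain",
    "build_resource_pairs",
    "build_model",
    "derive_resources",
    "stroke_config",
    "stroke_model",
    "simple_pathway_model",
    "load_config",
    "to_text",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class DepartmentSpec:
    """One pathway step: a care activity with an optional resource pool.

    ``copies=None`` means the resource is effectively unlimited and no
    resource component is generated for it (e.g. ambulances).  With
    ``waiting_room=True`` the department gets an explicit waiting room
    (one room per patient) and a coupling action handing waiting
    patients to the resource; otherwise a finite resource is seized
    directly by this department's activity and released by
    ``release_activity`` (defaulting to the next department's activity).
    """

    name: str
    activity: str
    duration_h: Optional[float] = None
    rate: Optional[float] = None  # 1/day; defaults to 24 / duration_h
    resource: Optional[str] = None
    copies: Optional[int] = None
    waiting_room: bool = False
    coupling: Optional[str] = None  # wait-action label
    release_activity: Optional[str] = None

    def service_rate(self) -> float:
        if self.rate is not None:
            return float(self.rate)
        if self.duration_h is None:
            raise ModelSemanticsError(
                f"department {self.name!r} needs a rate or a duration"
            )
        if self.duration_h <= 0:
            raise ModelSemanticsError(
                f"department {self.name!r} has nonpositive duration"
            )
        return HOURS_PER_DAY / self.duration_h


@dataclass(frozen=True)
class ResourceSpec:
    """An idle/busy pair: seized by one action, released by another."""

    name: str
    copies: int
    seize: str
    seize_rate: float
    release: str
    release_rate: float

    def __post_init__(self):
        if self.copies < 1:
            raise ModelSemanticsError(f"resource {self.name!r} needs >= 1 copies")


@dataclass(frozen=True)
class RoutingSpec:
    """A probabilistic branch out of a department.

    ``probability`` scales the branch's activity rate (rho * r); the
    main continuation keeps (1 - sum of branch probabilities).
    """

    department: str
    target: str  # a department name or "home"
    probability: float
    activity: Optional[str] = None  # defaults to <department activity>_referral

    def __post_init__(self):
        if not (0 < self.probability < 1):
            raise ModelSemanticsError(
                f"branch probability must lie in (0, 1), got {self.probability}"
            )


@dataclass(frozen=True)
class ActivityTable:
    """Annual activity counts used to estimate routing probabilities."""

    beds: int = 20
    stroke_admissions: int = 116
    mimic_admissions: int = 27
    tia_admissions: int = 15
    direct_admissions: int = 156

    @property
    def total_presentations(self) -> int:
        return self.stroke_admissions + self.mimic_admissions + self.tia_admissions


def estimate_routing(table: ActivityTable) -> dict[str, int]:
    """Whole-percent referral probabilities from annual activity counts.

    Mimic patients leave the pathway after initial assessment; TIA
    patients leave after the scan.  Returned as percentages, e.g.
    ``{"assessment_referral_pct": 17, "scan_referral_pct": 10}``.
    """
    assess_pct = round(100 * table.mimic_admissions / table.total_presentations)
    remaining = table.stroke_admissions + table.mimic_admissions
    scan_pct = round(100 * table.tia_admissions / remaining)
    return {
        "assessment_referral_pct": int(assess_pct),
        "scan_referral_pct": int(scan_pct),
    }


@dataclass
class PathwayConfig:
    """A full pathway: departments in visiting order plus population data.

    Patients enter through an admission activity at ``r_income`` per
    patient per day and cycle back home after the last department.
    ``num_wait_rooms`` (default: one per patient) sizes every waiting
    room; it must not be smaller than the patient population, or
    admissions could deadlock behind a full room.
    """

    departments: list = field(default_factory=list)
    num_patients: int = 1000
    r_income: float = 0.004
    admission_activity: str = "have_stroke"
    r_wait: float = 1000.0
    num_wait_rooms: Optional[int] = None
    routing: list = field(default_factory=list)
    patient_prefix: str = "Patient"
    home_place: str = "Home"

    def __post_init__(self):
        rooms = self.num_wait_rooms
        if rooms is not None and rooms < self.num_patients:
            raise ModelSemanticsError(
                f"{rooms} waiting rooms cannot hold {self.num_patients} patients; "
                "waiting rooms must be at least as numerous as patients"
            )
        names = [d.name for d in self.departments]
        if len(names) != len(set(names)):
            raise ModelSemanticsError("duplicate department names")

    @property
    def wait_rooms(self) -> int:
        return self.num_wait_rooms if self.num_wait_rooms is not None else self.num_patients


# ---------------------------------------------------------------------------
# Component construction
# ---------------------------------------------------------------------------


def _patient_place(config: PathwayConfig, place: str) -> str:
    return f"{config.patient_prefix}_{place}"


def build_patient_chain(config: PathwayConfig) -> dict[str, ComponentDef]:
    """The cyclic patient component: Home -> departments -> Home.

    Each routing branch becomes an extra prefix with a rho-scaled rate;
    the main continuation is scaled by the residual probability.
    """
    defs: dict[str, ComponentDef] = {}
    places = [config.home_place] + [d.name for d in config.departments]
    next_place = {
        places[i]: places[i + 1] if i + 1 < len(places) else config.home_place
        for i in range(len(places))
    }
    branches: dict[str, list[RoutingSpec]] = {}
    for r in config.routing:
        if r.department not in next_place:
            raise ModelSemanticsError(f"routing from unknown department {r.department!r}")
        branches.setdefault(r.department, []).append(r)

    # home
    home_name = _patient_place(config, config.home_place)
    defs[home_name] = ComponentDef(
        home_name,
        Prefix(
            Activity(config.admission_activity, config.r_income),
            ConstantRef(_patient_place(config, next_place[config.home_place])),
        ),
        kind="state",
    )

    for dept in config.departments:
        rate = dept.service_rate()
        place_name = _patient_place(config, dept.name)
        dept_branches = branches.get(dept.name, [])
        rho_total = sum(b.probability for b in dept_branches)
        if rho_total >= 1:
            raise ModelSemanticsError(
                f"branch probabilities out of {dept.name!r} sum to {rho_total} >= 1"
            )
        main_target = _patient_place(config, next_place[dept.name])
        if dept_branches:
            main_weight = 1.0 - rho_total
            body: object = Prefix(
                Activity(dept.activity, main_weight * rate, weight=main_weight),
                ConstantRef(main_target),
            )
            for b in dept_branches:
                target = (
                    config.home_place if b.target.lower() == "home" else b.target
                )
                action = b.activity or f"{dept.activity}_referral"
                body = Choice(
                    body,
                    Prefix(
                        Activity(action, b.probability * rate, weight=b.probability),
                        ConstantRef(_patient_place(config, target)),
                    ),
                )
        else:
            body = Prefix(Activity(dept.activity, rate), ConstantRef(main_target))
        defs[place_name] = ComponentDef(place_name, body, kind="state")
    return defs


def derive_resources(config: PathwayConfig) -> list[ResourceSpec]:
    """Resource idle/busy specifications in cooperation-tree order.

    Queued departments contribute a waiting room (seized by the
    activity that delivers the patient) followed by the resource itself
    (seized through the coupling action, released by the service
    activity).  Held resources are seized by the service activity and
    released by the stated release activity.
    """
    specs: list[ResourceSpec] = []
    activity_rate = {d.name: d.service_rate() for d in config.departments}
    dept_names = [d.name for d in config.departments]
    room_index = 0
    for i, dept in enumerate(config.departments):
        if dept.resource is None or dept.copies is None:
            continue
        rate = dept.service_rate()
        if dept.waiting_room:
            room_index += 1
            coupling = dept.coupling or f"wait_{dept.resource.lower()}"
            # the delivering activity is the previous department's service
            # activity (or the admission for the first department)
            if i == 0:
                deliver, deliver_rate = config.admission_activity, config.r_income
            else:
                prev = config.departments[i - 1]
                deliver, deliver_rate = prev.activity, prev.service_rate()
            specs.append(
                ResourceSpec(
                    f"Wait_room{room_index}",
                    config.wait_rooms,
                    seize=deliver,
                    seize_rate=deliver_rate,
                    release=coupling,
                    release_rate=config.r_wait,
                )
            )
            specs.append(
                ResourceSpec(
                    dept.resource,
                    dept.copies,
                    seize=coupling,
                    seize_rate=config.r_wait,
                    release=dept.activity,
                    release_rate=rate,
                )
            )
        else:
            release = dept.release_activity
            if release is None:
                if i + 1 >= len(config.departments):
                    raise ModelSemanticsError(
                        f"held resource {dept.resource!r} in the last department "
                        "needs an explicit release activity"
                    )
                release = config.departments[i + 1].activity
            release_rate = next(
                (
                    d.service_rate()
                    for d in config.departments
                    if d.activity == release
                ),
                None,
            )
            if release_rate is None:
                raise ModelSemanticsError(
                    f"release activity {release!r} of resource {dept.resource!r} "
                    "is not a department activity"
                )
            specs.append(
                ResourceSpec(
                    dept.resource, dept.copies,
                    seize=dept.activity, seize_rate=rate,
                    release=release, release_rate=release_rate,
                )
            )
    return specs


def build_resource_pairs(specs: Sequence[ResourceSpec]) -> dict[str, ComponentDef]:
    """Idle/busy equations for every resource specification."""
    defs: dict[str, ComponentDef] = {}
    for spec in specs:
        idle, busy = f"{spec.name}_idle", f"{spec.name}_busy"
        defs[idle] = ComponentDef(
            idle,
            Prefix(Activity(spec.seize, spec.seize_rate), ConstantRef(busy)),
            kind="resource",
        )
        defs[busy] = ComponentDef(
            busy,
            Prefix(Activity(spec.release, spec.release_rate), ConstantRef(idle)),
            kind="resource",
        )
    return defs


def build_model(config: PathwayConfig) -> CPPModel:
    """Assemble the closed model: patient replicas against nested resources.

    The cooperation tree is right-nested over the resource pairs in
    pathway order; every synchronisation set is the alphabet
    intersection of the two sides, so each shared activity becomes a
    constraint.
    """
    patient_defs = build_patient_chain(config)
    specs = derive_resources(config)
    resource_defs = build_resource_pairs(specs)
    definitions = {**patient_defs, **resource_defs}

    home_name = _patient_place(config, config.home_place)
    system: SystemExpr = Replication(home_name, config.num_patients)

    def pair_alphabet(spec: ResourceSpec) -> set[str]:
        return {spec.seize, spec.release}

    # fold right: last resource outwards
    if specs:
        tree: SystemExpr = Replication(f"{specs[-1].name}_idle", specs[-1].copies)
        tree_alpha = pair_alphabet(specs[-1])
        for spec in reversed(specs[:-1]):
            sync = pair_alphabet(spec) & tree_alpha
            tree = Cooperation(
                Replication(f"{spec.name}_idle", spec.copies), tree, frozenset(sync)
            )
            tree_alpha |= pair_alphabet(spec)
        patient_alpha = {
            act.action
            for d in patient_defs.values()
            for act, _ in _iter_prefixes_of(d)
        }
        system = Cooperation(system, tree, frozenset(patient_alpha & tree_alpha))

    busy_states = {spec.name: f"{spec.name}_busy" for spec in specs}
    last = config.departments[-1] if config.departments else None
    metadata = {
        "busy_states": busy_states,
        "pathway": {
            "departments": [d.name for d in config.departments],
            "num_patients": config.num_patients,
            "r_income": config.r_income,
        },
    }
    if last is not None:
        metadata["discharge_action"] = last.activity
        metadata["discharge_rate"] = last.service_rate()
        if last.resource is not None and last.copies is not None:
            metadata["final_resource"] = last.resource
    model = CPPModel(definitions, system, metadata=metadata)
    model.validate()
    return model


def _iter_prefixes_of(definition: ComponentDef):
    from .model import iter_prefixes

    yield from iter_prefixes(definition.body)


# ---------------------------------------------------------------------------
# Concrete pathways
# ---------------------------------------------------------------------------


def stroke_config(
    teams: int = 3,
    scanners: int = 3,
    beds: int = 20,
    num_patients: int = 1000,
    r_income: float = 0.004,
    r_wait: float = 1000.0,
) -> PathwayConfig:
    """Configuration of the hyper-acute stroke pathway.

    Patients cycle Home -> LAS (FAST test on ambulance, 1 h) ->
    A&E resuscitation (stroke-team assessment and investigation,
    0.75 h, team seized from the FAST test) -> CT scan (3 h, queued
    scanners) -> treatment in a stroke-unit bed (48 h, queued beds) ->
    Home.  Rates are per day; ``r_income`` is the per-patient stroke
    incidence, so the admission flux is ``num_patients * r_income``
    per day while everyone is at home.
    """
    return PathwayConfig(
        departments=[
            DepartmentSpec(
                "LAS", "do_FAST", duration_h=1.0,
                resource="Stroke_team", copies=teams,
                release_activity="assess_and_investigate",
            ),
            DepartmentSpec("A_E_Resus", "assess_and_investigate", duration_h=0.75),
            DepartmentSpec(
                "CT_scan", "scan", duration_h=3.0,
                resource="Scan", copies=scanners,
                waiting_room=True, coupling="wait_scan",
            ),
            DepartmentSpec(
                "Normal_treat", "treat_HASU", duration_h=48.0,
                resource="Bed", copies=beds,
                waiting_room=True, coupling="wait_bed",
            ),
        ],
        num_patients=num_patients,
        r_income=r_income,
        admission_activity="have_stroke",
        r_wait=r_wait,
    )


def stroke_model(
    teams: int = 3,
    scanners: int = 3,
    beds: int = 20,
    num_patients: int = 1000,
    r_income: float = 0.004,
    r_wait: float = 1000.0,
) -> CPPModel:
    """The hyper-acute stroke pathway model (see :func:`stroke_config`)."""
    return build_model(
        stroke_config(teams, scanners, beds, num_patients, r_income, r_wait)
    )


def simple_pathway_model(
    patients: int = 2,
    rooms: int = 2,
    resources: int = 1,
    beta: float = 1.0,
    alpha: float = 3.0,
    gamma: float = 1000.0,
) -> CPPModel:
    """A one-department queueing pathway used as a worked example.

    A patient moves from place 0 to place 1 at rate ``beta`` (seizing a
    waiting room), the room hands the patient to a treatment resource
    through the fast ``gamma`` coupling, and treatment completes at
    rate ``alpha`` returning the patient to place 0.
    """
    config = PathwayConfig(
        departments=[
            DepartmentSpec(
                "place1", "alpha", rate=alpha,
                resource="Resource", copies=resources,
                waiting_room=True, coupling="gamma",
            ),
        ],
        num_patients=patients,
        r_income=beta,
        admission_activity="beta",
        r_wait=gamma,
        num_wait_rooms=rooms,
        home_place="place0",
    )
    return build_model(config)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def load_config(path) -> PathwayConfig:
    """Load a :class:`PathwayConfig` from a YAML file.

    Schema::

        num_patients: 1000
        r_income: 0.004
        admission_activity: have_stroke
        departments:
          - name: LAS
            activity: do_FAST
            duration_h: 1.0
            resource: Stroke_team
            copies: 3
            release_activity: assess_and_investigate
          - name: CT_scan
            activity: scan
            duration_h: 3.0
            resource: Scan
            copies: 3
            waiting_room: true
        routing:
          - department: A_E_Resus
            target: home
            probability: 0.17
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelSemanticsError("pathway config must be a mapping")
    departments = [DepartmentSpec(**d) for d in raw.get("departments", [])]
    routing = [RoutingSpec(**r) for r in raw.get("routing", [])]
    kwargs = {
        k: raw[k]
        for k in (
            "num_patients",
            "r_income",
            "admission_activity",
            "r_wait",
            "num_wait_rooms",
            "patient_prefix",
            "home_place",
        )
        if k in raw
    }
    return PathwayConfig(departments=departments, routing=routing, **kwargs)


def to_text(model: CPPModel) -> str:
    """Canonical textual form of a built model."""
    return unparse(model)
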