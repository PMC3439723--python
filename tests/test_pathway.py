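"""Pathway builder: routing, component assembly, the stroke model."""

import pytest

from cpepa.ctmc import explore_state_space
from cpepa.model import ModelSemanticsError, iter_prefixes, unparse
from cpepa.pathway import (
    ActivityTable,
    DepartmentSpec,
    PathwayConfig,
    RoutingSpec,
    build_model,
    build_patient_chain,
    build_resource_pairs,
    derive_resources,
    estimate_routing,
    load_config,
    simple_pathway_model,
    stroke_config,
    stroke_model,
)
from cpepa.scenarios import generate_fixture


def test_routing_estimates():
    pct = estimate_routing(ActivityTable())
    assert pct["assessment_referral_pct"] == 17  # 27 / (116 + 15 + 27)
    assert pct["scan_referral_pct"] == 10  # 15 / (116 + 27)


def test_stroke_rates_from_durations():
    config = stroke_config()
    rates = {d.activity: d.service_rate() for d in config.departments}
    assert rates == {
        "do_FAST": pytest.approx(24.0),
        "assess_and_investigate": pytest.approx(32.0),
        "scan": pytest.approx(8.0),
        "treat_HASU": pytest.approx(0.5),
    }


def test_patient_chain_has_five_places():
    defs = build_patient_chain(stroke_config())
    assert set(defs) == {
        "Patient_Home",
        "Patient_LAS",
        "Patient_A_E_Resus",
        "Patient_CT_scan",
        "Patient_Normal_treat",
    }
    # chain is cyclic: last place returns home
    last = defs["Patient_Normal_treat"].body
    assert last.continuation.name == "Patient_Home"
    assert last.activity.rate == pytest.approx(0.5)


def test_stroke_resource_pairs():
    specs = derive_resources(stroke_config())
    assert [s.name for s in specs] == [
        "Stroke_team",
        "Wait_room1",
        "Scan",
        "Wait_room2",
        "Bed",
    ]
    defs = build_resource_pairs(specs)
    assert len(defs) == 10  # idle/busy pair per resource
    # team is seized by the FAST test and released by the assessment
    team_idle = defs["Stroke_team_idle"].body
    assert team_idle.activity.action == "do_FAST"
    team_busy = defs["Stroke_team_busy"].body
    assert team_busy.activity.action == "assess_and_investigate"
    # scanners are reached through the waiting-room coupling
    assert defs["Scan_idle"].body.activity.action == "wait_scan"
    assert defs["Scan_idle"].body.activity.rate == pytest.approx(1000.0)


def test_stroke_model_structure():
    model = stroke_model()
    text = unparse(model)
    assert "Patient_Home[1000]" in text
    assert "Stroke_team_idle[3]" in text
    assert "Bed_idle[20]" in text
    assert model.metadata["discharge_action"] == "treat_HASU"
    assert model.metadata["final_resource"] == "Bed"
    # admission flux at the initial configuration: 1000 x 0.004 = 4/day
    from cpepa.model import apparent_rate

    assert apparent_rate(model.system, "have_stroke", model) == pytest.approx(4.0)


def test_branching_rates_conserved():
    config = PathwayConfig(
        departments=[
            DepartmentSpec("assess", "assess_act", rate=32.0),
            DepartmentSpec("treat", "treat_act", rate=0.5),
        ],
        num_patients=2,
        r_income=1.0,
        routing=[RoutingSpec("assess", "home", 0.17)],
    )
    defs = build_patient_chain(config)
    prefixes = list(iter_prefixes(defs["Patient_assess"].body))
    total = sum(act.rate for act, _ in prefixes)
    assert total == pytest.approx(32.0)
    weights = sorted(act.weight for act, _ in prefixes)
    assert weights == [pytest.approx(0.17), pytest.approx(0.83)]
    referral = next(act for act, tgt in prefixes if tgt == "Patient_Home")
    assert referral.action == "assess_act_referral"


def test_excess_branch_probability_rejected():
    config = PathwayConfig(
        departments=[DepartmentSpec("d", "a", rate=1.0)],
        num_patients=1,
        routing=[RoutingSpec("d", "home", 0.6), RoutingSpec("d", "home", 0.6)],
    )
    with pytest.raises(ModelSemanticsError):
        build_patient_chain(config)


def test_too_few_waiting_rooms_rejected():
    with pytest.raises(ModelSemanticsError):
        PathwayConfig(
            departments=[DepartmentSpec("d", "a", rate=1.0)],
            num_patients=5,
            num_wait_rooms=3,
        )


def test_simple_pathway_assembles_to_ten_states():
    ts = explore_state_space(simple_pathway_model())
    assert ts.n_states == 10


def test_generated_configs_validate():
    for seed in range(50):
        model = build_model(generate_fixture(seed))
        model.validate()


def test_yaml_roundtrip(tmp_path):
    text = """
num_patients: 4
r_income: 0.5
admission_activity: arrive
departments:
  - name: triage
    activity: see
    duration_h: 2.0
    resource: Nurse
    copies: 2
    waiting_room: true
"""
    path = tmp_path / "config.yaml"
    path.write_text(text)
    config = load_config(path)
    assert config.num_patients == 4
    assert config.departments[0].service_rate() == pytest.approx(12.0)
    model = build_model(config)
    model.validate()


def test_held_resource_needs_release():
    config = PathwayConfig(
        departments=[DepartmentSpec("d", "a", rate=1.0, resource="R", copies=1)],
        num_patients=1,
    )
    with pytest.raises(ModelSemanticsError):
        derive_resources(config)
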