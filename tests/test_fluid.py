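"""Fluid approximation: ODE derivation, integration, probes, passage time."""

import numpy as np
import pytest

from cpepa.ctmc import explore_state_space, sample_counts
from cpepa.fluid import (
    PROBE_NOT_FINISHED,
    attach_probe,
    derive_odes,
    fluid_steady_state,
    integrate,
    passage_time_cdf,
    probed_name,
)
from cpepa.model import ModelSemanticsError, parse_model
from cpepa.pathway import (
    DepartmentSpec,
    PathwayConfig,
    build_model,
    simple_pathway_model,
    stroke_model,
)


def test_six_equations_in_min_form(simple_model):
    odes = derive_odes(simple_model)
    text = odes.equations_text()
    lines = text.strip().splitlines()
    assert len(lines) == 6
    assert (
        "N(Patient_place0)' = -1*min(N(Patient_place0),N(Wait_room1_idle)) "
        "+3*min(N(Patient_place1),N(Resource_busy))" in text
    )
    assert "1000*min(N(Wait_room1_busy),N(Resource_idle))" in text


def test_initial_conditions(simple_model):
    odes = derive_odes(simple_model)
    assert odes.y0.tolist() == [2.0, 0.0, 2.0, 0.0, 1.0, 0.0]


def test_compiled_rhs_matches_reference(simple_model):
    odes = derive_odes(stroke_model(2, 2, 5, num_patients=10))
    rng = np.random.default_rng(3)
    for _ in range(10):
        y = np.abs(rng.normal(2.0, 1.5, odes.n_vars))
        assert np.abs(odes.rhs(0.0, y) - odes.rhs_reference(0.0, y)).max() < 1e-11


def test_conservation_along_trajectory(simple_model):
    odes = derive_odes(simple_model)
    traj = integrate(odes, 10.0, grid=np.linspace(0, 10, 101))
    assert traj.conservation_error() < 1e-8


def test_drift_at_zero_matches_ctmc_expected_drift(fixture_models):
    # expected CTMC drift from the initial state = sum of rate * count change
    for seed, _cfg, model, ts in fixture_models:
        odes = derive_odes(model)
        drift = odes.rhs(0.0, odes.y0)
        expected = np.zeros_like(drift)
        var_offset = {}
        acc = 0
        for g in ts.groups:
            var_offset[g.name] = acc
            acc += len(g.local_states)

        def counts(state):
            v = np.zeros(acc)
            for g in ts.groups:
                for val in state[g.slice]:
                    v[var_offset[g.name] + val] += 1
            return v

        c0 = counts(ts.states[ts.initial])
        for s, t, _a, r in zip(
            ts.transitions_src, ts.transitions_tgt, ts.transitions_action, ts.transitions_rate
        ):
            if int(s) == ts.initial:
                expected += float(r) * (counts(ts.states[int(t)]) - c0)
        assert np.abs(drift - expected).max() < 1e-9, f"seed {seed}"


def test_monte_carlo_tracks_fluid(simple_model):
    # scaled-up population: 6 patients, 6 rooms, 3 resources
    model = simple_pathway_model(patients=6, rooms=6, resources=3)
    odes = derive_odes(model)
    checkpoints = [0.25, 0.5, 1.0, 2.0, 4.0]
    traj = integrate(odes, 4.0, grid=checkpoints)
    ts = explore_state_space(model, max_states=200_000)
    rng = np.random.default_rng(11)
    n_paths = 400
    means = sample_counts(ts, checkpoints, n_paths, rng)
    # compare patient place-1 counts within 3 standard errors (+ fluid bias margin)
    for ci in range(len(checkpoints)):
        mc = means[ci][1]
        fl = traj.y[1][ci]
        se = np.sqrt(max(mc, 1.0)) / np.sqrt(n_paths)
        assert abs(mc - fl) < 3 * se + 0.4, (checkpoints[ci], mc, fl)


def test_fluid_steady_state_converges(simple_model):
    ss = fluid_steady_state(derive_odes(simple_model))
    assert ss.converged
    assert ss.residual < 1e-6
    # fixed point respects conservation
    assert ss.counts[:2].sum() == pytest.approx(2.0, abs=1e-6)


def test_probe_does_not_perturb_dynamics(simple_model):
    odes = derive_odes(simple_model)
    traj = integrate(odes, 5.0, grid=np.linspace(0, 5, 51))
    probed = attach_probe(simple_model, "Patient_place0", "alpha")
    podes = derive_odes(probed)
    ptraj = integrate(podes, 5.0, grid=np.linspace(0, 5, 51))
    # total count in place1 (NotFinished + Finished) matches the unprobed run
    idx = [
        i
        for i, n in enumerate(podes.var_names)
        if n.startswith("Patient_place1")
    ]
    combined = ptraj.y[idx].sum(axis=0)
    assert np.abs(combined - traj.y[1]).max() < 1e-7


def test_probe_requires_reachable_trigger(simple_model):
    with pytest.raises(ModelSemanticsError):
        attach_probe(simple_model, "Patient_place0", "no_such_action")


def test_single_stage_passage_matches_closed_form():
    config = PathwayConfig(
        departments=[DepartmentSpec("d", "serve", rate=2.0)],
        num_patients=1,
        r_income=1.5,
        admission_activity="adm",
    )
    model = build_model(config)
    probed = attach_probe(model, "Patient_Home", "adm")
    grid = np.linspace(0.0, 4.0, 41)
    cdf = passage_time_cdf(probed, grid)
    for t in grid:
        assert cdf(t) == pytest.approx(1.0 - np.exp(-1.5 * t), abs=1e-3)


def test_cdf_monotone_bounded(simple_model):
    probed = attach_probe(simple_model, "Patient_place0", "alpha")
    grid = np.linspace(0.0, 6.0, 61)
    cdf = passage_time_cdf(probed, grid)
    assert cdf.values[0] == pytest.approx(0.0, abs=1e-9)
    assert np.all(np.diff(cdf.values) >= -1e-12)
    assert np.all((cdf.values >= 0) & (cdf.values <= 1))


def test_passage_requires_probe(simple_model):
    with pytest.raises(ModelSemanticsError):
        passage_time_cdf(simple_model, [0.0, 1.0])


def test_probed_names():
    assert probed_name("Patient_Home", PROBE_NOT_FINISHED) == "Patient_Home__NotFinished"
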