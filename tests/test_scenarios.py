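"""Scenario drivers, fixture generator, and the command-line interface."""

import json
from dataclasses import replace

import numpy as np
import pytest

from cpepa.ctmc import build_generator, explore_state_space, solve_steady_state
from cpepa.performance import throughput
from cpepa.pathway import DepartmentSpec, PathwayConfig, build_model
from cpepa.scenarios import (
    generate_fixture,
    scenario_max_input,
    scenario_passage_time,
    scenario_resource_sweep,
    serialize_config,
    solve_throughput,
)


def test_fixture_determinism():
    for seed in (0, 5, 17):
        a = serialize_config(generate_fixture(seed))
        b = serialize_config(generate_fixture(seed))
        assert a == b


def test_fixtures_are_irreducible(fixture_models):
    for seed, _cfg, _model, ts in fixture_models:
        pi = solve_steady_state(build_generator(ts))  # raises if reducible
        assert pi.pi.sum() == pytest.approx(1.0)


def test_solver_selection_small_model_uses_ctmc():
    config = PathwayConfig(
        departments=[
            DepartmentSpec("d", "serve", rate=2.0, resource="R", copies=1, waiting_room=True)
        ],
        num_patients=2,
        r_income=1.0,
        admission_activity="admit",
        r_wait=100.0,
    )
    value, method, converged = solve_throughput(build_model(config))
    assert method == "ctmc" and converged
    # cross-check against a direct full-chain solve
    model = build_model(config)
    ts = explore_state_space(model)
    pi = solve_steady_state(build_generator(ts))
    exact = throughput(pi, ts, "serve", 2.0, "R")
    assert value == pytest.approx(exact, rel=1e-9)


def test_fluid_matches_ctmc_at_scale():
    # scaling the population x100 shrinks the fluid-vs-CTMC gap below 10%
    base = PathwayConfig(
        departments=[
            DepartmentSpec("d", "serve", rate=3.0, resource="R", copies=2, waiting_room=True)
        ],
        num_patients=3,
        r_income=0.8,
        admission_activity="admit",
        r_wait=100.0,
    )
    model = build_model(base)
    ts = explore_state_space(model)
    pi = solve_steady_state(build_generator(ts))
    small_exact = throughput(pi, ts, "serve", 3.0, "R")

    big = replace(
        base,
        num_patients=300,
        departments=[replace(base.departments[0], copies=200)],
    )
    from cpepa.fluid import derive_odes, fluid_steady_state

    ss = fluid_steady_state(derive_odes(build_model(big)))
    fluid_big = 3.0 * ss["R_busy"]
    assert fluid_big / 100.0 == pytest.approx(small_exact, rel=0.10)


def test_sweep_monotone_in_resources():
    config = PathwayConfig(
        departments=[
            DepartmentSpec("d", "serve", rate=1.0, resource="R", copies=1, waiting_room=True)
        ],
        num_patients=4,
        r_income=1.0,
        admission_activity="admit",
        r_wait=100.0,
    )
    result = scenario_resource_sweep(config, {"R": [1, 2, 4]})
    tps = result.grid.sort_values("R")["throughput"].to_numpy()
    assert np.all(np.diff(tps) >= -1e-6)
    assert result.optimal[0] in (1, 2, 4)


def test_sweep_optimal_is_minimal():
    # two resources where one is never the bottleneck: the sweep must pick
    # the smallest allocation within 1% of the maximum
    config = PathwayConfig(
        departments=[
            DepartmentSpec("a", "first", rate=50.0, resource="Fast", copies=1, waiting_room=True),
            DepartmentSpec("b", "second", rate=1.0, resource="Slow", copies=1, waiting_room=True),
        ],
        num_patients=3,
        r_income=2.0,
        admission_activity="admit",
        r_wait=100.0,
    )
    result = scenario_resource_sweep(config, {"Fast": [1, 2], "Slow": [3]})
    assert result.optimal == (1, 3)


def test_passage_time_zero_at_origin_and_monotone():
    config = PathwayConfig(
        departments=[DepartmentSpec("d", "serve", rate=2.0)],
        num_patients=1,
        r_income=1.0,
        admission_activity="admit",
    )
    cdf = scenario_passage_time(config, np.linspace(0, 3, 31))
    assert cdf(0.0) == pytest.approx(0.0, abs=1e-9)
    assert np.all(np.diff(cdf.values) >= -1e-12)
    # single exponential stage at rate 2
    assert cdf(1.0) == pytest.approx(1 - np.exp(-2.0), abs=1e-3)


def test_max_input_monotone_and_bounded():
    config = PathwayConfig(
        departments=[
            DepartmentSpec("d", "serve", rate=1.0, resource="R", copies=2, waiting_room=True)
        ],
        num_patients=50,
        r_income=0.01,
        admission_activity="admit",
        r_wait=100.0,
    )
    curve = scenario_max_input(config, [0.5, 1.0, 2.0, 4.0, 8.0])
    assert np.all(np.diff(curve.throughputs) >= -1e-6)
    assert curve.capacity_bound == pytest.approx(2.0)
    assert curve.throughputs.max() <= curve.capacity_bound + 1e-6


# -- CLI -------------------------------------------------------------------


@pytest.fixture()
def runner():
    from click.testing import CliRunner

    return CliRunner()


def _small_config_yaml(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        """
num_patients: 2
r_income: 1.0
admission_activity: admit
r_wait: 100.0
departments:
  - name: d
    activity: serve
    rate: 2.0
    resource: R
    copies: 1
    waiting_room: true
"""
    )
    return path


def test_cli_solve(runner, tmp_path):
    from cpepa.cli import main

    cfg = _small_config_yaml(tmp_path)
    out = tmp_path / "out"
    result = runner.invoke(main, ["solve", "--config", str(cfg), "--out", str(out)])
    assert result.exit_code == 0, result.output
    payload = json.loads((out / "solve.json").read_text())
    assert payload["throughput_per_day"] > 0


def test_cli_statespace_and_fixture(runner, tmp_path):
    from cpepa.cli import main

    cfg = _small_config_yaml(tmp_path)
    out = tmp_path / "out"
    result = runner.invoke(main, ["statespace", "--config", str(cfg), "--out", str(out)])
    assert result.exit_code == 0, result.output
    assert (out / "edges.csv").exists()
    assert (out / "statespace.dot").read_text().startswith("digraph")
    assert (out / "generator.mtx").exists()

    result = runner.invoke(main, ["fixture", "--seed", "4", "--out", str(out)])
    assert result.exit_code == 0, result.output
    assert (out / "fixture_4.yaml").exists()


def test_cli_sweep_and_maxinput(runner, tmp_path):
    from cpepa.cli import main

    cfg = _small_config_yaml(tmp_path)
    out = tmp_path / "out"
    result = runner.invoke(
        main,
        ["sweep", "--config", str(cfg), "--out", str(out), "--ranges", '{"R": [1, 2]}'],
    )
    assert result.exit_code == 0, result.output
    summary = json.loads((out / "sweep.json").read_text())
    assert summary["optimal"][0] in (1, 2)

    result = runner.invoke(
        main,
        ["maxinput", "--config", str(cfg), "--out", str(out), "--inputs", "0.5,1,2"],
    )
    assert result.exit_code == 0, result.output
    assert (out / "saturation.csv").exists()


def test_cli_passage(runner, tmp_path):
    from cpepa.cli import main

    cfg = _small_config_yaml(tmp_path)
    out = tmp_path / "out"
    result = runner.invoke(
        main, ["passage", "--config", str(cfg), "--out", str(out), "--horizon", "2"]
    )
    assert result.exit_code == 0, result.output
    payload = json.loads((out / "passage.json").read_text())
    assert 0 <= payload["cdf_at_1_day"] <= 1


def test_cli_validation_exit_code(runner, tmp_path):
    from cpepa.cli import main

    bad = tmp_path / "bad.yaml"
    bad.write_text("num_patients: 5\nnum_wait_rooms: 1\ndepartments: []\n")
    result = runner.invoke(main, ["solve", "--config", str(bad), "--out", str(tmp_path)])
    assert result.exit_code == 2
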