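"""CTMC derivation, generator, steady state, aggregation."""

import numpy as np
import pytest

from cpepa import (
    ReducibleChainError,
    aggregate,
    build_generator,
    explore_state_space,
    solve_steady_state,
)
from cpepa.ctmc import StateSpaceError, sample_occupancy
from cpepa.model import parse_model
from cpepa.performance import resource_utilisation, throughput

from conftest import engine_edges, naive_explore


def test_two_state_chain_generator_and_steady_state():
    m = parse_model("S1 = (go, 7).S2;\nS2 = (back, 6).S1;\nsystem S1;")
    ts = explore_state_space(m)
    Q = build_generator(ts).to_dense()
    assert np.allclose(Q, [[-7.0, 7.0], [6.0, -6.0]])
    pi = solve_steady_state(Q)
    assert np.round(pi.pi, 2).tolist() == [0.46, 0.54]


def test_single_state_chain():
    m = parse_model("P = (a, 1).P;\nsystem P;")
    ts = explore_state_space(m)
    assert ts.n_states == 1
    pi = solve_steady_state(build_generator(ts))
    assert pi.pi.tolist() == [1.0]


def test_simple_pathway_ten_states(simple_ts):
    assert simple_ts.n_states == 10


def test_simple_pathway_leading_probability(simple_pi, simple_ts):
    assert simple_pi.pi[simple_ts.initial] == pytest.approx(0.5284, abs=5e-5)


def test_generator_rows_sum_to_zero(fixture_models):
    for _seed, _cfg, _m, ts in fixture_models:
        Q = build_generator(ts).Q
        rows = np.asarray(Q.sum(axis=1)).ravel()
        assert np.abs(rows).max() < 1e-9
        off = Q.copy()
        off.setdiag(0)
        assert off.data.size == 0 or off.data.min() >= 0


def test_flux_balance_per_state(fixture_models):
    # total probability flux into each state equals flux out (global balance)
    for _seed, _cfg, _m, ts in fixture_models:
        Q = build_generator(ts)
        pi = solve_steady_state(Q)
        assert np.abs(pi.pi @ Q.Q).max() < 1e-9


def test_engine_matches_reference_semantics(fixture_models):
    for seed, _cfg, model, ts in fixture_models:
        if ts.n_states > 3000:
            continue
        ref_states, ref_edges = naive_explore(model)
        got_states, got_edges = engine_edges(ts)
        assert got_states == ref_states, f"seed {seed}: state sets differ"
        assert set(got_edges) == set(ref_edges), f"seed {seed}: edge sets differ"
        for key, rate in ref_edges.items():
            assert got_edges[key] == pytest.approx(rate, rel=1e-9), f"seed {seed}: {key}"


def test_reference_semantics_on_simple_model(simple_model, simple_ts):
    ref_states, ref_edges = naive_explore(simple_model)
    got_states, got_edges = engine_edges(simple_ts)
    assert got_states == ref_states
    for key, rate in ref_edges.items():
        assert got_edges[key] == pytest.approx(rate, rel=1e-9)


def test_exploration_is_deterministic(simple_model):
    a = explore_state_space(simple_model)
    b = explore_state_space(simple_model)
    assert a.states == b.states
    assert a.transitions_src.tolist() == b.transitions_src.tolist()
    assert a.transitions_tgt.tolist() == b.transitions_tgt.tolist()


def test_state_budget_enforced(simple_model):
    with pytest.raises(StateSpaceError):
        explore_state_space(simple_model, max_states=5)


def test_reducible_chain_detected():
    m = parse_model("A = (fall, 1).B;\nB = (stay, 2).B;\nsystem A;")
    ts = explore_state_space(m)
    with pytest.raises(ReducibleChainError):
        solve_steady_state(build_generator(ts))


def test_occupancy_simulation_tracks_pi(simple_ts, simple_pi):
    rng = np.random.default_rng(7)
    occ = sample_occupancy(simple_ts, 40_000, rng)
    # loose Monte-Carlo agreement on the dominant states
    assert np.abs(occ - simple_pi.pi).max() < 0.02


# -- aggregation -----------------------------------------------------------


def test_aggregation_to_five_classes(simple_agg):
    assert simple_agg.n_classes == 5
    assert simple_agg.member_counts.sum() == 10


def test_aggregated_steady_state(simple_agg):
    pi = solve_steady_state(build_generator(simple_agg.lumped))
    assert max(pi.pi) == pytest.approx(0.5284, abs=5e-5)


def test_aggregation_projection_consistency(simple_agg, simple_pi):
    # lumped chain solved directly == full solution summed over classes
    lumped_pi = solve_steady_state(build_generator(simple_agg.lumped))
    projected = simple_agg.project(simple_pi.pi)
    assert np.abs(lumped_pi.pi - projected).max() < 1e-9


def test_aggregation_identity_when_no_replicas():
    m = parse_model("S1 = (go, 7).S2;\nS2 = (back, 6).S1;\nsystem S1;")
    ts = explore_state_space(m)
    agg = aggregate(ts)
    assert agg.n_classes == ts.n_states


def test_aggregation_preserves_measures(fixture_models):
    for _seed, cfg, model, ts in fixture_models:
        meta = model.metadata
        final = meta.get("final_resource")
        if final is None or ts.n_states > 20_000:
            continue
        pi = solve_steady_state(build_generator(ts))
        agg = aggregate(ts)
        pia = solve_steady_state(build_generator(agg.lumped))
        assert resource_utilisation(pia, agg.lumped, final) == pytest.approx(
            resource_utilisation(pi, ts, final), abs=1e-9
        )
        assert throughput(
            pia, agg.lumped, meta["discharge_action"], meta["discharge_rate"], final
        ) == pytest.approx(
            throughput(pi, ts, meta["discharge_action"], meta["discharge_rate"], final),
            abs=1e-9,
        )


def test_aggregation_lumpability_check_passes(fixture_models):
    for _seed, _cfg, _m, ts in fixture_models:
        if ts.n_states > 5_000:
            continue
        aggregate(ts, check_lumpability=True)


def test_exports(simple_ts, tmp_path):
    df = simple_ts.to_edge_dataframe()
    assert set(df.columns) == {"source", "target", "action", "rate"}
    assert len(df) == simple_ts.n_transitions
    dot = simple_ts.to_dot()
    assert dot.startswith("digraph") and "->" in dot
    gen = build_generator(simple_ts)
    gen.to_mtx(tmp_path / "q.mtx")
    from scipy.io import mmread

    back = mmread(tmp_path / "q.mtx")
    assert np.allclose(back.toarray(), gen.to_dense())
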