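# cpepa — clinical pathway performance analysis with stochastic process algebra

`cpepa` is a Python implementation of CPP, a clinical-pathway dialect of the
PEPA stochastic process algebra.  Pathways (patients moving through hospital
departments, seizing and releasing shared resources such as clinical teams,
scanners and beds) are written as small process-algebra models.  The package
derives the underlying continuous-time Markov chain (CTMC), solves it exactly
where feasible, aggregates it by a counting abstraction when the state space
explodes, switches to a fluid (mean-field ODE) approximation for large
populations, and computes passage-time distributions with stochastic probes.
A stroke-unit pathway is included as a worked case study, together with three
scenario drivers: resource optimisation, passage-time estimation and
maximum-input estimation.

## The language in one minute

A model is a set of sequential component definitions and a system equation.
Each component performs timed activities `(action, rate)` with exponentially
distributed durations; components run in parallel and synchronise on shared
actions, at the minimum of their apparent rates (bounded-capacity semantics):

```text
Patient_place0 = (beta, 1).Patient_place1;
Patient_place1 = (alpha, 3).Patient_place0;
Wait_room1_idle = (beta, 1).Wait_room1_busy;
Wait_room1_busy = (gamma, 1000).Wait_room1_idle;
Resource_idle = (gamma, 1000).Resource_busy;
Resource_busy = (alpha, 3).Resource_idle;
system Patient_place0[2] <alpha, beta> (Wait_room1_idle[2] <gamma> Resource_idle[1]);
```

Two patients cycle between home (`place0`) and a treatment place (`place1`);
admission (`beta`) seizes a waiting room, a fast coupling activity (`gamma`)
moves the patient from the waiting room to the single resource, and the
service activity (`alpha`) releases it.  `P[n]` replicates a component,
`<a, b>` is cooperation on the listed actions, `||` is pure interleaving.

## Worked example

```python
from cpepa import (simple_pathway_model, explore_state_space,
                   build_generator, solve_steady_state)
from cpepa.performance import resource_utilisation, throughput

model = simple_pathway_model()          # the model printed above
ts = explore_state_space(model)         # 10 reachable global states
pi = solve_steady_state(build_generator(ts))
print(ts.n_states)                                          # 10
print(round(resource_utilisation(pi, ts, "Resource"), 4))   # 0.4702
print(round(throughput(pi, ts, "alpha", 3.0, "Resource"), 4))  # 1.4105
```

Utilisation is the expected number of busy resource copies divided by the
total; throughput is the discharge rate times the expected busy count
(1.4105 patients/day here).  The same model aggregates to 5 count-vector
classes (`cpepa.aggregate`), with identical measures, and at 8 patients /
8 waiting rooms / 3 resources the full chain has 75 582 states — the
motivation for aggregation and the fluid approximation.

## The stroke pathway

`cpepa.pathway.stroke_config()` builds a four-department acute stroke
pathway: FAST test by an ambulance crew holding a stroke team (1 h),
assessment in resuscitation (0.75 h, 17 % referred out), CT scan behind a
waiting-room queue (3 h, 10 % referred out), and hyper-acute treatment in a
bed (48 h).  1000 potential patients have strokes at 0.004/day each
(4 patients/day of demand); 3 teams, 3 scanners and 20 beds by default.

Scenario drivers (also exposed by the CLI):

```python
from cpepa.pathway import stroke_config
from cpepa.scenarios import (scenario_resource_sweep, scenario_passage_time,
                             scenario_max_input)
import numpy as np

sweep = scenario_resource_sweep(stroke_config(),
    {"Stroke_team": [1, 2, 3], "Scan": [1, 2, 3], "Bed": [4, 6, 8, 10, 12, 16, 20]})
sweep.optimal                 # (1, 1, 8): smallest set within 1% of max throughput
sweep.max_throughput          # 3.9651 patients/day at 4/day demand

cdf = scenario_passage_time(stroke_config(1, 1, 8), np.linspace(0, 3, 301))
cdf(1.0), cdf(2.5)            # 0.3282, 0.6826  (admission-to-discharge CDF)

curve = scenario_max_input(stroke_config(), [1, 2, 4, 6, 8, 10, 12, 16, 20])
curve.throughput_at(10.0)     # 9.7847 — saturation: 20 beds x 0.5/day caps at 10
```

## Command-line interface

```bash
cpepa solve      --out out/                 # utilisations + throughput (stroke default)
cpepa sweep      --out out/                 # resource sweep, sweep.csv + sweep.json
cpepa passage    --out out/ --horizon 3     # passage-time CDF
cpepa maxinput   --out out/ --inputs 1,4,10 # saturation curve
cpepa statespace --config cfg.yaml --out out/  # edges.csv, DOT graph, generator.mtx
cpepa fixture    --seed 7 --out out/        # random valid pathway config (YAML + model text)
```

`--config` accepts a YAML pathway description (see `cpepa fixture` output or
`tests/test_pathway.py::test_yaml_roundtrip` for the schema); without it the
stroke pathway is used.  Exit code 2 signals a validation error, 3 a solver
failure.

## Layout

- `src/cpepa/model.py` — language AST, parser, printer, structured semantics
- `src/cpepa/ctmc.py` — state-space exploration, generator, steady state, aggregation
- `src/cpepa/performance.py` — utilisation, throughput, action fluxes
- `src/cpepa/fluid.py` — fluid ODEs, steady state, probes, passage-time CDFs
- `src/cpepa/pathway.py` — pathway builder, stroke model, YAML configs
- `src/cpepa/scenarios.py` — scenario drivers, solver selection, fixture generator
- `src/cpepa/cli.py` — `cpepa` command
- `docs/methods.md` — models, assumptions, numerical methods, limitations
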