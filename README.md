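# territorps

A stochastic lattice Monte-Carlo simulator for a three-species cyclic
("rock–paper–scissors") game in which intraspecific competition is
sensitive to territorial identity, plus the observables and experiment
harness needed to study it quantitatively.

## Model

An `L x L` periodic square lattice (von Neumann neighborhoods) holds
individuals of species A, B, C or vacancies. The lattice is split into a
top and a bottom territory; each individual carries a heritable *genus*
tag (1 = seeded on top, 2 = bottom). Per generation, `N = L*L` random
pair-event attempts occur; for an actor of species `i` the event type is
drawn with normalized probabilities over

- interspecific predation (rate `p1`): A beats B beats C beats A, the
  loser's site becomes empty;
- intraspecific competition (rate `k_i * p2`): same species, and — in the
  default *territorial* mode — different genus; one of the two dies with
  probability 1/2 (*traditional* mode drops the genus condition);
- reproduction (rate `r`): into an empty neighbor, offspring inherits the
  parent's genus;
- migration (rate `m = 2*M*N`): unconditional swap with the neighbor.

A reaction whose precondition fails still consumes the attempt.

Observables include survival-state classification, two first-crossing
extinction-time definitions (every species loses a genus / two species
lost entirely), and the interface-width statistic `W` = mean over columns
of the interpenetration depth of the two territory classes near the
boundary (computed over the central third of rows by default).

## CLI

```
territorps run configs/desk_run_low_mobility.yaml --out-dir runs/demo \
    --snapshots 500,1000
territorps analyze runs/demo/snapshot_1000.npz --out-dir runs/demo
territorps extinction runs/demo/densities.csv --definition low_mobility \
    --censor-at 2000
territorps sweep configs/desk_sweep_width.yaml --out-dir sweeps/width --plot
```

`configs/` ships desk-scale sweeps (minutes) and the full published
protocol at L = 300 (`paper_scale_*`, hours to days — not CI material).

## Library sketch

```python
from territorps import (SimulationConfig, run_simulation, summarize,
                        interface_width, extinction_time)

cfg = SimulationConfig(L=100, M=1e-5, T_max=2000, seed=7).with_k(5.0)
traj = run_simulation(cfg)                      # numba kernel
print(summarize(traj.final_state).state_label)  # e.g. full_coexistence
print(interface_width(traj.final_state).W)
```

Experiment helpers (`SweepSpec`, `sweep_extinction_vs_k`,
`sweep_traditional_vs_territorial`, `sweep_width_vs_k`,
`phase_scan_mobility`) run replicated seeded sweeps and aggregate means
with standard errors; censored extinction times enter means at the
censoring value and are counted separately.

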