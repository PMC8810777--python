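# Shipped run and sweep configurations

`desk_*` files run in minutes on a single CPU and mirror the reduced-scale
protocols used by the acceptance tests.

`paper_scale_*` files express the full published protocol (L = 300, run
lengths up to 810,000 generations, 30 replicates). **They are NOT desk
scale** — a single low-mobility extinction replicate at L = 300 takes hours,
and a full sweep takes days on one CPU. They are provided so the full
protocol is explicit and runnable on a cluster, and are not part of CI.

Run them with:

    territorps run configs/desk_run_low_mobility.yaml --out-dir runs/demo
    territorps sweep configs/desk_sweep_extinction.yaml --out-dir sweeps/demo
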