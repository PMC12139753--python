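# fclsim

Particle-based simulation and cluster statistics of flat clathrin lattice
(FCL) assembly on a membrane patch.

Rigid three-legged clathrin particles diffuse in a cubic cytosol volume
above a membrane plane populated by mobile AP-2 adaptors. Clathrin binds
adaptors (recruitment to the membrane) and other clathrins (head-to-head
leg bonds, 5 nm apart, coplanar), forming flat hexagonal lattices. All
binding is reversible; assembled complexes diffuse as rigid units with
size-dependent coefficients. The package also ships the cluster-dynamics
statistics used to characterise such systems (cluster number, padded-hull
cluster areas, settling time t_c, modal "most possible pattern", dwelling
times, neighbor counts), parameter-sweep drivers with replicates and
t-tests, and a growth-factor stimulus protocol with time-varying kinetic
parameters and reversal.

## Layout

| module | contents |
| --- | --- |
| `fclsim.model_core` | domain types, rigid-body site geometry, binding transforms, overlap tests, boundaries |
| `fclsim.simulator` | per-timestep engine: dissociation → association → diffusion; contact-scheme rate calibration; cluster diffusion formula |
| `fclsim.analysis` | cluster identification, areas, t_c, modal pattern, dwell statistics, neighbor counts, box-plot summaries, t-tests |
| `fclsim.protocols` | initial states, desk-scale preset, sweeps, stimulus schedules, well-mixed validation harness |
| `fclsim.synthetic_data` | Markov-chain traces, bonded-patch fixtures and point patterns with known ground truth |
| `fclsim.config` / `fclsim.io_cli` / `fclsim.cli` | YAML config schema with documented defaults, CSV trajectory persistence, run manifests, CLI |

## CLI

```bash
clathrin-sim simulate --config model.yaml --seed 1 --out run/
clathrin-sim analyze  --trajectory run/ --out metrics.json
clathrin-sim analyze  --centroids fcl_table.csv --out stats.json
clathrin-sim sweep    --variable ap2_number --values 4,16,100 --out sweep/
clathrin-sim egf      --combination ap2_k_d --out egf/
clathrin-sim validate --k-on 5 --k-off 13 --out val.json
clathrin-sim synth    --kind trace --out trace.csv
```

An empty config file yields the documented defaults (`fclsim.config.
DEFAULTS_PROVENANCE` records which values are printed constants vs
repository choices). All randomness flows from the single config seed;
identical seed + config reproduces trajectories bit for bit.

## Units and conventions

Internal coordinates are nm (z up from the membrane plane z = 0), time in
seconds, bimolecular rates in uM^-1 s^-1, diffusion in um^2/s, areas
reported in um^2. Orientations are unit quaternions; membrane-bound
molecules keep their plane parallel to the membrane.

## Scaled-down preset

`fclsim.protocols.desk_preset()` is the desk-scale configuration used by
the test suite: 0.5 um box, copy numbers scaled with the box, a larger
timestep (the engine warns when per-step reaction probabilities exceed
0.1) and seconds of simulated time. It preserves the qualitative regime
(recruitment saturation before cluster-statistics are read off) rather
than the original clock.

Known limitation: in the binding-rate trend test
(`test_k_sweep_directions`) only the cluster-count direction is robust at
desk scale; the size/dwell directions sit inside replicate noise at an
affordable replicate count, and the test intentionally keeps the full
three-direction assertion rather than weakening it, so it can fail. The
diffusion-coefficient sweep demonstrates all three directions with wide
margins.
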