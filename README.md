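# gqm

A seedable stochastic simulator of clonal B-cell homeostasis on the
antigen-concentration × affinity plane. Clonal populations live in discrete
niches (bone marrow, blood, follicle, germinal center, memory sites), engage
antigen by two-component mass-action equilibrium, and die, rest, divide,
edit their receptor, class-switch or hypermutate so as to keep receptor
saturation near 50% — the "comfort zone" where free antigen ≈ K_D.

## Layout

| module | what it does |
| --- | --- |
| `gqm.binding` | closed-form equilibrium binding, occupancy, engagement-zone classification |
| `gqm.agents` | clone state, fate decisions, division, receptor editing, isotype switch, SHM |
| `gqm.niches` | antigen panels, depletable vs. inexhaustible pool dynamics, panel TSV I/O |
| `gqm.gc` | germinal-center capture → division → mutation → selection loop, immunization schedules |
| `gqm.config` / `gqm.engine` / `gqm.output` / `gqm.cli` | YAML config, discrete-time scheduler, CSV/JSON/TSV outputs, CLI |

## CLI

```sh
# full multi-niche run: trajectory.csv, summary.json, phase_map.tsv
gqm simulate --config examples/config.yaml --seed 42 --out out/

# engagement-class grid over the working range [1e-14, 1e-3] M
gqm phase-map --band 0.5 --grid 23 --out out/phase_map.tsv

# repeated-immunization ensemble (3 doses by default, K seeds)
gqm gc --seeds 30 --seed 1 --out out/gc/
```

Configuration is YAML (`schema_version: 1`); every default is materialized
at load time and unknown keys are errors. See `examples/config.yaml` for a
fully commented file. Exit code is 0 on success, 2 on validation errors;
logs go to stderr.

Identical config + seed ⇒ byte-identical output files. All floats are
serialized with 9 significant digits so replays can be diffed directly.

## Notes

- Working range for both axes is [1e-14, 1e-3] M; K_D values outside it
  warn rather than error.
- The blood niche is inexhaustible by contract: replenished species hold a
  fixed concentration no matter the paratope load.
- Avidity/multivalency, binding kinetics, and intracellular signaling are
  deliberately out of scope; concentrations are of epitope and paratope.
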