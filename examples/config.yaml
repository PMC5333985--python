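# gqm simulation configuration, schema_version 1.
# Every key shown here is optional; omitted keys take these defaults.
schema_version: 1

seed: 42
n_steps: 100
second_signal: false          # T-cell help / danger-signal gate

band:                         # engagement zones on log10([Ag]/K_D)
  delta_comfort: 0.5          # comfort half-width, log10 units
  theta_neglect: 0.01         # occupancy below which cells are neglected
  theta_saturated: 0.99       # occupancy above which cells are saturated

shm:                          # somatic hypermutation (trichotomy sums to 1)
  p_lethal: 0.3
  p_del: 0.5
  p_beneficial: 0.2
  p_heavy: 0.6                # chance the heavy chain takes the mutation
  sigma_step: 0.4             # half-normal step scale, log10(kd) units
  cap_h: 30                   # hard per-chain mutation caps
  cap_l: 20
  kd_min: 2.0e-12             # matured-affinity floor (hard clamp)
  kd_max: 1.0e-3

germline:                     # log-uniform kd range of new receptors
  kd_low: 1.0e-10
  kd_high: 1.0e-6

cells:
  bcr_per_cell: 1.0e5         # paratopes per cell
  edit_attempts: 3            # receptor-editing budget
  population_cap: 1048576     # max cells per clone (2^20)
  delta_b1: 1.5               # log-ratio band separating B1 from strong activation
  switch_gain: 10.0           # apparent-affinity gain on class switch
  p_b1_divide: 0.1            # per-step division probability of banded B1 cells

blood:                        # inexhaustible niche, fixed concentrations
  volume: 5.0                 # liters
  n_species: 8
  conc_low: 1.0e-12
  conc_high: 1.0e-3

bone_marrow:                  # depletable mirror of the blood panel
  volume: 1.0e-6
  display_efficiency: 0.1     # fraction of blood concentration displayed

follicle:
  volume: 1.0e-6
  display_efficiency: 0.1

memory_niche:
  volume: 1.0e-6
  display_efficiency: 0.1

gc:                           # germinal-center / immunization schedule
  volume: 1.0e-9
  dose_conc: 1.0e-8           # molar antigen per dose
  n_cycles: 12                # max light/dark-zone cycles per dose
  n_doses: 3
  n_founders: 20
  alpha: 4.0                  # divisions per reference capture
  div_cap: 6
  f_present: 0.5              # pool fraction presented per cycle
  pool_decay: 0.10            # per-cycle antibody-clearance placeholder
  residual_frac: 0.01         # pool fraction defining "last antigen"
  stochastic_capture: false

founders:
  n_clones: 20
  stage: SMALL_PRE_BII

kd_working_min: 1.0e-14       # working range for both map axes, molar
kd_working_max: 1.0e-3
panel_file: null              # optional TSV: ag_id, concentration_molar, replenished
output_dir: out
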