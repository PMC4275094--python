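# Example pipeline configuration: simulate a two-block NC II experiment
# (4 sires x 2 dams per block, 2 temperature x 3 pH levels, 3 replicate
# jars) and run every analysis stage.  The variance components and
# treatment effects below are illustrative round numbers on the percent
# scale, not estimates from any dataset.
design:
  n_blocks: 2
  sires_per_block: 4
  dams_per_block: 2
  env_factors: [[temperature, 2], [ph, 3]]
  n_replicates: 3
  embryos_scored_range: [30, 50]
variance_components:
  block: 5.0
  sire: 15.0
  dam: 10.0
  sire_dam: 10.0
  sire_temperature: 8.0
  sire_ph: 5.0
  sire_temperature_ph: 4.0
  dam_temperature: 5.0
  dam_ph: 4.0
  dam_temperature_ph: 3.0
  sire_dam_temperature: 4.0
  sire_dam_ph: 4.0
  sire_dam_temperature_ph: 4.0
  residual: 100.0
fixed_effects:
  mu: 63.5               # control-condition mean percent
  temperature: [-3.0, 3.0]
  ph: [6.0, 1.0, -7.0]
traits: [fertilization, gastrulation]
rho_stage: 0.6
response_model: gaussian-percent
n_perm: 9999
seed: 1
outdir: ncii_out
stages: [simulate, anova, varcomp, heritability, stagelink]
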