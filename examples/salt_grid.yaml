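# Full condition grid: four charged homo-polypeptides plus the neutral
# control, NaCl-like (1:1) series at 0 / 0.125 / 0.25 M and a MgCl2-like
# (2:1) series at 0.125 / 0.25 M, five replicates each.
#
#   polyion report --config examples/salt_grid.yaml
#
# Sweep counts here are desk-scale (the grid has 125 runs; expect hours on
# one CPU at these settings — reduce replicates or sweeps for a quick look).
systems:
  - {name: polyD, chain: polyD}
  - {name: polyE, chain: polyE}
  - {name: polyK, chain: polyK}
  - {name: polyR, chain: polyR}
  - {name: polyGS, chain: polyGS}
conditions:
  - {name: "0M", concentration: 0.0, cation_valence: 1}
  - {name: "0.125M_1to1", concentration: 0.125, cation_valence: 1}
  - {name: "0.25M_1to1", concentration: 0.25, cation_valence: 1}
  - {name: "0.125M_2to1", concentration: 0.125, cation_valence: 2}
  - {name: "0.25M_2to1", concentration: 0.25, cation_valence: 2}
analyses: [rg, flory, tau, ions, pca]
mc:
  n_sweeps: 50000
  equilibration_sweeps: 10000
  sample_interval: 50
box_edge: 75.0
seed: 1
replicates: 5
outdir: polyion_grid_out
analysis_options:
  flory: {fit_range: [2, 15]}
  ions: {cutoff: 4.0, species: counterions}
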