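# End-to-end demo run on synthetic data: phenoscreen run --config configs/demo.yaml
outdir: results/demo_run
seed: 1
n_essential: 60
n_nonessential: 40
n_controls: 24
doublings: 15.0
read_depth: 500000
n_wells: 48
n_wt_wells: 16
window: 5
sample_interval: 8.5
n_morph_strains: 4
n_cells_per_strain: 120
min_width: 0.6
max_width: 2.0
min_cells: 100
k_sd: 3.0
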