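# Example scenario: Auger-like point source 1 nm from the canonical 41-BP
# atomic B-DNA model, full physics + chemistry chain.
model:
  kind: high_res
  n_bp: 41
  rise: 0.34
  twist: 36.0
  bounding_diameter: 2.4
  bounding_height: 14.3

spectrum_path: spectrum_synthetic.csv

placement:
  mode: at_distance        # or at_bp with bp_index (covalent labeling)
  distance_nm: 1.0

physics:
  cutoff_energy_ev: 10.0   # sub-cutoff electrons deposit locally

chemistry:
  enabled: true            # false emulates a DMSO scavenger environment
  t_end_s: 1.0e-6
  n_steps: 100

scoring:
  direct_threshold_ev: 10.0
  simple_model_threshold_ev: 17.5
  d_dsb: 10

n_decays: 1000
seed: 1
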