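# Bundled synthetic study: 500 plots, four biomes, all stages enabled.
seed: 1
output_dir: runs
synthetic:
  n_plots: 500
  n_species: 120
  beta_port: -0.8
  beta_div: -0.8
  gamma_T2: -1.0
buffer_km: 250.0
cv:
  n_repeats: 60
rf:
  enabled: true
  n_estimators: 500
  n_simulations: 25
  shap_rows: 150
sensitivity:
  n_plots: 800
  c: -0.05
  noise_sd: 0.05
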