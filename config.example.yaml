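# Example pipeline configuration (mmconn run --config config.example.yaml)
# Omitted keys fall back to the package defaults shown here.
seed: 0
rho: 0.05        # retained edge fraction (top-5% proportional threshold)
n_null: 100      # degree-preserving nulls for sigma / rich-club
n_perm: 1000     # label permutations for SCN group inference
generator:
  n_patient: 15
  n_control: 14
  interhemispheric_deficit: 0.15   # delta planted on motor/premotor edges
  coupling_rho_sf: 0.25            # planted structure-function coupling
  clinical_rho: -0.70              # planted metric-clinical Spearman
  t_rest: 300
  t_task: 600
  tr_seconds: 2.5
  block_seconds: 30.0
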