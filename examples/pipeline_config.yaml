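# Demo configuration for `erlurbi run` / erlurbi.pipeline.run_pipeline.
# Sizes are reduced for a quick end-to-end demonstration; raise n_patients,
# n_boot (250) and n_sim for production-scale runs.
out_dir: scratch/pipeline_demo
n_patients: 300
seed: 1
profile: atlantis_experimental
lrb_dose: 2.0
dox_dose: 40.0
counterfactual_lrb_dose: 3.2
n_boot: 25
n_vpc_replicates: 50
n_sim: 50
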