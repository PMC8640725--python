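# Demo pipeline configuration: simulate a 2,000-patient synthetic cohort
# and run every analysis stage on it.
output_dir: out
seed: 1
simulate: true
n_patients: 2000
suppress_below: null
exposures: [sex]
mcf_stratifiers: [baseline_ltc, sex]
chain_by: null
msm_mode: exact
reference_covariates: {age_40_59: 1.0}
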