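# Design 1: fixed Bayesian design. Equal 1:1:1:1 allocation throughout,
# no interim analyses; success assessed only at the final analysis
# (Pr(best intervention beats control by 8 FAOS points) > 0.5).
schema_version: 1
design: 1
scenario: "Null"          # quote "Null" so YAML keeps it a string
n_replicates: 1000
base_seed: 1
n_draws: 5000
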