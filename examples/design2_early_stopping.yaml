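# Design 2: equal allocation with early stopping only. Efficacy/futility
# checks at 200, 400 and 600 patients due (boundaries 0.75/0.70/0.60 on the
# MCID probability plus a 0.9 best-arm gate; futility below 0.05).
schema_version: 1
design: 2
scenario: "One works, 10 more"
n_replicates: 1000
base_seed: 1
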