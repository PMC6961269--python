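# Design 6: no designated control; all four arms randomised by probability
# of being the best arm. Early stopping ladder 0.975/0.95/0.925, futility
# below 0.1, final success when the best arm's probability exceeds 0.9.
schema_version: 1
design: 6
scenario: "One works, 5 more"
n_replicates: 1000
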