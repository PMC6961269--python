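# Design 5: RAR with the control fixed at 40% allocation; interventions
# share the remaining 60% proportionally to damped best-arm probabilities.
schema_version: 1
design: 5
scenario: "One works, 5 more"
n_replicates: 1000
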