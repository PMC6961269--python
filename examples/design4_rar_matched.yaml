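# Design 4: response-adaptive randomisation every 50 patients due with
# gamma = 0.6 damping; control allocation matched to the best intervention.
# The design block below shows how preset fields can be overridden.
schema_version: 1
design:
  design_id: 4
  gamma: 0.6                  # damping exponent on best-arm probabilities
  suspension_threshold: 0.1   # arms below this allocation are suspended
n_replicates: 1000
scenario: "Better, Best"
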