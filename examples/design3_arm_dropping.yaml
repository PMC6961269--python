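# Design 3: permanent arm dropping assessed every 50 patients due; an
# intervention is dropped when its probability of being the best
# intervention falls below 0.10; survivors (control included) share equally.
schema_version: 1
design: 3
scenario: "One worse, others work"
n_replicates: 1000
base_seed: 1
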