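# Batch form: every design crossed with every scenario (42 cells).
schema_version: 1
designs: [1, 2, 3, 4, 5, 6]
scenarios: ["Null", "One works, 10 more", "One works, 5 more", "Better, Best",
            "One worse, others work", "All work, two similar", "All inferior"]
n_replicates: 1000
base_seed: 1
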