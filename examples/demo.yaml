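geometry: {ht_rel: 0.0}
flow: {re: 1.0, mode: steady}
numerics: {tier: coarse}
outputs: {dir: runs/demo}
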