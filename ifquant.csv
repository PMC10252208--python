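percent_MAP2,percent_SMI32,percent_smi32_in_map2
77.5,55.0,54.83870967741935
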