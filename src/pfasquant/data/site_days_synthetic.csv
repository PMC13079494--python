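day_id,flow,population
1,228900000,900000
2,228900000,900000
3,228900000,900000
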