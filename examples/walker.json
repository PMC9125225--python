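{
 "example": {"name": "walker", "seed": 0},
 "time": {"n_grid": 61}
}
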