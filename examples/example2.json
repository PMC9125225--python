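{
 "example": {"name": "example2", "seed": 0, "relax_time": 30.0},
 "time": {"n_grid": 301}
}
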