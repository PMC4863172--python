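{
  "name": "ANT-6",
  "states": ["S3", "S3+1", "S2+2", "S1+3"],
  "transitions": [
    {"from": "S3", "to": "S3+1", "k0_ns_inv": 73.9, "d": 0.014, "delta_E_sign": "near-zero"},
    {"from": "S3+1", "to": "S2+2", "k0_ns_inv": 6.1, "d": 0.1, "delta_E_sign": "positive"},
    {"from": "S2+2", "to": "S1+3", "k0_ns_inv": 234.3, "d": 0.023, "delta_E_sign": "near-zero"},
    {"from": "S1+3", "to": "S3", "k0_ns_inv": 7151.1, "d": -0.025, "delta_E_sign": "negative"}
  ],
  "permeation_transition": {"from": "S1+3", "to": "S3"},
  "backward_transitions": []
}
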