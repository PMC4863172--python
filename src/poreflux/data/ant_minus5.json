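{
  "name": "ANT-5",
  "states": ["S2", "S2+1", "S3", "S1+2"],
  "transitions": [
    {"from": "S2", "to": "S2+1", "k0_ns_inv": 8.5, "d": -0.079, "delta_E_sign": "negative"},
    {"from": "S2+1", "to": "S3", "k0_ns_inv": 2230.6, "d": 0.009, "delta_E_sign": "near-zero"},
    {"from": "S3", "to": "S1+2", "k0_ns_inv": 49.1, "d": 0.074, "delta_E_sign": "positive"},
    {"from": "S1+2", "to": "S2", "k0_ns_inv": 93.0, "d": 0.073, "delta_E_sign": "positive"}
  ],
  "permeation_transition": {"from": "S1+2", "to": "S2"},
  "backward_transitions": []
}
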